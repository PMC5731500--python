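"""Multi-gene DNA alignment I/O, 5-letter encoding and full-site compression.

Sequences are encoded over the alphabet {A, C, G, T, unknown} -> {0..4}.
Everything that is not an unambiguous base (gaps, N, IUPAC ambiguity codes)
collapses to the single unknown code 4, which contributes a row of ones to
the pruning recursion (i.e. is marginalized out).  U is treated as T.

Full-site compression is the classic baseline: duplicate alignment columns
are collapsed and carry an integer multiplicity, so the per-column log
likelihood is simply multiplied by its count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import AlignIO, SeqIO

__all__ = [
    "GeneAlignment",
    "EncodedGene",
    "read_alignments",
    "write_fasta",
    "encode_gene",
    "full_site_compress",
    "UNKNOWN",
]

UNKNOWN = 4

# byte -> code lookup; default everything to unknown
_CODE_TABLE = np.full(256, UNKNOWN, dtype=np.uint8)
_CODE_TABLE[np.frombuffer(b"Aa", dtype=np.uint8)] = 0
_CODE_TABLE[np.frombuffer(b"Cc", dtype=np.uint8)] = 1
_CODE_TABLE[np.frombuffer(b"Gg", dtype=np.uint8)] = 2
_CODE_TABLE[np.frombuffer(b"TtUu", dtype=np.uint8)] = 3


@dataclass
class GeneAlignment:
    name: str
    taxa: list[str]
    seqs: list[str]

    def __post_init__(self):
        if not self.seqs:
            raise ValueError(f"gene {self.name!r}: empty alignment")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValueError(f"gene {self.name!r}: ragged rows {sorted(lengths)}")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError(f"gene {self.name!r}: duplicate taxa")

    @property
    def length(self) -> int:
        return len(self.seqs[0])


@dataclass
class EncodedGene:
    """Integer-coded gene, rows in tree leaf order, columns full-site compressed.

    ``codes`` holds only the retained (unique) columns; ``site_weights[j]``
    is the multiplicity of retained column j in the original alignment and
    ``kept_sites[j]`` its first-occurrence index.  ``present`` flags which
    tree leaves actually carry data in this gene.
    """

    name: str
    codes: np.ndarray            # (n_tree_leaves, n_kept) uint8 in {0..4}
    site_weights: np.ndarray     # (n_kept,) int64
    kept_sites: np.ndarray       # (n_kept,) int64
    length: int                  # original site count s
    present: np.ndarray          # (n_tree_leaves,) bool

    @property
    def n_kept(self) -> int:
        return self.codes.shape[1]

    def empirical_frequencies(self) -> np.ndarray:
        """Observed A,C,G,T frequencies over known cells (weighted)."""
        counts = np.zeros(4)
        for b in range(4):
            counts[b] = ((self.codes == b) * self.site_weights).sum()
        if counts.sum() == 0:
            return np.full(4, 0.25)
        return counts / counts.sum()


def read_alignments(paths, fmt: str = "fasta") -> list[GeneAlignment]:
    """Read one alignment per file; ``fmt`` is 'fasta' or 'phylip'.

    PHYLIP files are read as sequential, falling back to relaxed naming.
    """
    genes = []
    for path in paths:
        path = Path(path)
        if fmt == "fasta":
            records = list(SeqIO.parse(str(path), "fasta"))
            if not records:
                raise ValueError(f"{path}: no sequences found")
            taxa = [r.id for r in records]
            seqs = [str(r.seq) for r in records]
        elif fmt == "phylip":
            try:
                aln = AlignIO.read(str(path), "phylip-sequential")
            except ValueError:
                aln = AlignIO.read(str(path), "phylip-relaxed")
            taxa = [r.id for r in aln]
            seqs = [str(r.seq) for r in aln]
        else:
            raise ValueError(f"unknown alignment format {fmt!r}")
        genes.append(GeneAlignment(name=path.stem, taxa=taxa, seqs=seqs))
    return genes


def write_fasta(aln: GeneAlignment, path) -> None:
    with open(path, "w") as fh:
        for taxon, seq in zip(aln.taxa, aln.seqs):
            fh.write(f">{taxon}\n{seq}\n")


def encode_gene(aln: GeneAlignment, tree_leaves: list[str]) -> EncodedGene:
    """Encode to codes 0..4 with rows ordered by the tree's leaf order.

    Tree leaves missing from the gene get all-unknown rows (probability-one
    rows in the pruning recursion), so one topology and one compression
    layout serve every gene.
    """
    index = {t: i for i, t in enumerate(tree_leaves)}
    unknown_extra = [t for t in aln.taxa if t not in index]
    if unknown_extra:
        raise ValueError(
            f"gene {aln.name!r}: taxa not in tree: {unknown_extra}"
        )
    s = aln.length
    codes = np.full((len(tree_leaves), s), UNKNOWN, dtype=np.uint8)
    present = np.zeros(len(tree_leaves), dtype=bool)
    for taxon, seq in zip(aln.taxa, aln.seqs):
        row = index[taxon]
        codes[row] = _CODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        present[row] = True
    enc = EncodedGene(
        name=aln.name,
        codes=codes,
        site_weights=np.ones(s, dtype=np.int64),
        kept_sites=np.arange(s, dtype=np.int64),
        length=s,
        present=present,
    )
    return full_site_compress(enc)


def full_site_compress(enc: EncodedGene) -> EncodedGene:
    """Collapse duplicate columns, keeping first occurrences in order.

    The weight of a retained column is the number of original columns
    (weighted, if already compressed) sharing its pattern.
    """
    cols = enc.codes.T
    _, first, inverse = np.unique(cols, axis=0, return_index=True, return_inverse=True)
    # reorder unique groups by first occurrence
    order = np.argsort(first, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    inverse = rank[inverse]
    kept = first[order]
    weights = np.zeros(len(kept), dtype=np.int64)
    np.add.at(weights, inverse, enc.site_weights)
    return EncodedGene(
        name=enc.name,
        codes=enc.codes[:, kept],
        site_weights=weights,
        kept_sites=enc.kept_sites[kept],
        length=enc.length,
        present=enc.present,
    )
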