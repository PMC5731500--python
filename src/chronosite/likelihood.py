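"""Exact phylogenetic likelihood with subtree site compression.

Classic full-site compression deduplicates whole alignment columns.  With a
fixed topology one can go further: at every inner node, only the distinct
projections of the columns onto that node's leaf set need a partial
likelihood.  Each inner node therefore carries a site lookup table whose
rows are its unique subtree patterns; a row stores, for each child, either
the child's leaf code (an index into the child's TPM) or the row index of
the child's own unique pattern.  The root additionally carries a repeat
count per row, aggregating the full-site-compression weights of all columns
mapping to that root pattern.

Pattern tables depend only on the data and the topology, so they are built
once and never touched during MCMC; age and rate proposals only refresh the
TPMs of the affected branches and the partial likelihood vectors on the
path from the changed node to the root.

During construction the per-node pattern hash is realized as a vectorized
unique-key pass; after the build only the lookup tables and row counts are
retained (the hashes are never queried again), trading the memory of the
hash for nothing.

A plain column-by-column Felsenstein pruning implementation is provided as
the independent oracle; the two must agree to floating-point accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .alignments import EncodedGene, UNKNOWN
from .substitution import HKYModel
from .tree import SpeciesTree

__all__ = [
    "NodeCompression",
    "GeneCompression",
    "build_compression",
    "GeneLikelihoodEngine",
    "gene_log_likelihood",
    "plain_pruning_log_likelihood",
]

# rescale a (pattern, category) partial when its max drops below this
_SCALE_THRESHOLD = 1e-100


@dataclass
class NodeCompression:
    """Site lookup table of one inner node.

    ``left_index``/``right_index`` give, per unique subtree pattern, the
    child TPM row (leaf child: the leaf's code) or the child's pattern row
    (inner child).  ``col_to_row`` maps every retained alignment column to
    its pattern row — the materialized result of the hash-table queries.
    """

    left_index: np.ndarray
    right_index: np.ndarray
    col_to_row: np.ndarray
    repeat_count: np.ndarray | None = None  # root only

    @property
    def n_patterns(self) -> int:
        return len(self.left_index)


class GeneCompression:
    def __init__(self, tables: dict[int, NodeCompression], root_id: int):
        self.tables = tables
        self.root_id = root_id

    @property
    def root(self) -> NodeCompression:
        return self.tables[self.root_id]

    def n_patterns(self, node_id: int) -> int:
        return self.tables[node_id].n_patterns

    def total_rows(self) -> int:
        """Total likelihood-vector positions across all inner nodes."""
        return sum(t.n_patterns for t in self.tables.values())


def build_compression(tree: SpeciesTree, enc: EncodedGene) -> GeneCompression:
    """Build every inner node's site lookup table bottom-up.

    For each inner node the per-column key is the pair (left child row,
    right child row); because child rows are in bijection with the child
    subtree patterns, the pair uniquely identifies the concatenated leaf-code
    key of the full subtree.  First occurrences define the row order.
    """
    tables: dict[int, NodeCompression] = {}
    for nid in tree.postorder():
        node = tree.nodes[nid]
        if node.is_leaf:
            continue
        child_vals = []
        for cid in node.children:
            child = tree.nodes[cid]
            if child.is_leaf:
                child_vals.append(enc.codes[tree.leaf_index[child.label]].astype(np.int64))
            else:
                child_vals.append(tables[cid].col_to_row)
        left, right = child_vals
        width = int(right.max()) + 1 if len(right) else 1
        keys = left * width + right
        _, first, inverse = np.unique(keys, return_index=True, return_inverse=True)
        order = np.argsort(first, kind="stable")
        rank = np.empty_like(order)
        rank[order] = np.arange(len(order))
        inverse = rank[inverse]
        first = first[order]
        tab = NodeCompression(
            left_index=left[first].copy(),
            right_index=right[first].copy(),
            col_to_row=inverse,
        )
        if nid == tree.root_id:
            repeat = np.zeros(tab.n_patterns, dtype=np.int64)
            np.add.at(repeat, inverse, enc.site_weights)
            tab.repeat_count = repeat
        tables[nid] = tab
    return GeneCompression(tables, tree.root_id)


def _leaf_contrib_table(P: np.ndarray) -> np.ndarray:
    """Per-code child contribution for a leaf: shape (5, K, 4).

    Code y in {0..3} selects column y of each category TPM; the unknown
    code marginalizes the leaf state, contributing ones.
    """
    K = P.shape[0]
    table = np.empty((5, K, 4))
    table[:4] = P.transpose(2, 0, 1)
    table[UNKNOWN] = 1.0
    return table


class GeneLikelihoodEngine:
    """Incremental compressed likelihood for one gene on the shared tree.

    Reads node ages live from the tree.  ``propose_*`` methods recompute the
    minimal set of TPMs and partials, keeping an undo log so a rejected MCMC
    move is restored exactly; ``commit`` drops the log.
    """

    def __init__(
        self,
        tree: SpeciesTree,
        enc: EncodedGene,
        model: HKYModel,
        branch_rates: dict[int, float] | None = None,
    ):
        self.tree = tree
        self.enc = enc
        self.model = model
        if branch_rates is None:
            branch_rates = {
                n.id: 1.0 for n in tree.nodes if n.parent is not None
            }
        self.branch_rates = dict(branch_rates)
        self.comp = build_compression(tree, enc)
        self.tpms: dict[int, np.ndarray] = {}
        self.partials: dict[int, np.ndarray] = {}
        self.scale_log: dict[int, np.ndarray] = {}
        self.log_likelihood: float = np.nan
        self._undo: dict | None = None
        self.n_partial_recomputes = 0
        self.full_recompute()

    # -- core computations --------------------------------------------------

    def _branch_tpm(self, child_id: int) -> np.ndarray:
        node = self.tree.nodes[child_id]
        duration = self.tree.nodes[node.parent].age - node.age
        if duration < 0:
            raise ValueError(f"negative duration above node {child_id}")
        return self.model.category_tpms(duration * self.branch_rates[child_id])

    def _compute_partial(self, nid: int) -> None:
        tab = self.comp.tables[nid]
        node = self.tree.nodes[nid]
        K = len(self.model.category_rates)
        partial = np.ones((tab.n_patterns, K, 4))
        scale = np.zeros((tab.n_patterns, K))
        for cid, rows in zip(node.children, (tab.left_index, tab.right_index)):
            child = self.tree.nodes[cid]
            P = self.tpms[cid]
            if child.is_leaf:
                partial *= _leaf_contrib_table(P)[rows]
            else:
                Lc = self.partials[cid][rows]
                # batched (K,r,4) @ (K,4,4)^T == sum_y P[k,x,y] Lc[r,k,y]
                partial *= np.matmul(
                    Lc.transpose(1, 0, 2), P.transpose(0, 2, 1)
                ).transpose(1, 0, 2)
                scale += self.scale_log[cid][rows]
        m = partial.max(axis=2)
        mask = (m > 0) & (m < _SCALE_THRESHOLD)
        if mask.any():
            partial[mask] /= m[mask][:, None]
            scale[mask] += np.log(m[mask])
        self.partials[nid] = partial
        self.scale_log[nid] = scale
        self.n_partial_recomputes += 1

    def _root_log_likelihood(self) -> float:
        tab = self.comp.root
        L = self.partials[self.comp.root_id]
        scale = self.scale_log[self.comp.root_id]
        K = L.shape[1]
        a = L @ self.model.pi  # (rows, K)
        with np.errstate(divide="ignore"):
            if not scale.any():
                log_site = np.log(a.mean(axis=1))
            else:
                log_site = logsumexp(np.log(a) + scale, axis=1) - np.log(K)
        return float(tab.repeat_count @ log_site)

    def full_recompute(self) -> float:
        for node in self.tree.nodes:
            if node.parent is not None:
                self.tpms[node.id] = self._branch_tpm(node.id)
        for nid in self.tree.postorder():
            if not self.tree.nodes[nid].is_leaf:
                self._compute_partial(nid)
        self.log_likelihood = self._root_log_likelihood()
        return self.log_likelihood

    # -- incremental updates ------------------------------------------------

    def _begin(self) -> dict:
        if self._undo is not None:
            raise RuntimeError("uncommitted proposal pending")
        undo = {
            "tpms": {},
            "partials": {},
            "scale": {},
            "loglik": self.log_likelihood,
            "rates": {},
            "model": None,
        }
        self._undo = undo
        return undo

    def _refresh(self, branch_ids, dirty_start: int) -> float:
        """Recompute TPMs of ``branch_ids`` and partials from ``dirty_start`` up."""
        undo = self._undo
        for bid in branch_ids:
            undo["tpms"].setdefault(bid, self.tpms[bid])
            self.tpms[bid] = self._branch_tpm(bid)
        nid: int | None = dirty_start
        while nid is not None:
            if not self.tree.nodes[nid].is_leaf:
                undo["partials"].setdefault(nid, self.partials[nid])
                undo["scale"].setdefault(nid, self.scale_log[nid])
                self._compute_partial(nid)
            nid = self.tree.nodes[nid].parent
        self.log_likelihood = self._root_log_likelihood()
        return self.log_likelihood

    def propose_age_change(self, node_id: int) -> float:
        """Tree age of ``node_id`` has been updated; refresh the root path.

        Affected TPMs: the node's two child branches and (unless root) its
        parent branch.  Affected partials: the node and its ancestors.
        """
        self._begin()
        node = self.tree.nodes[node_id]
        branches = list(node.children)
        if node.parent is not None:
            branches.append(node_id)
        return self._refresh(branches, node_id)

    def propose_rate_change(self, child_id: int, new_rate: float) -> float:
        self._begin()
        self._undo["rates"][child_id] = self.branch_rates[child_id]
        self.branch_rates[child_id] = new_rate
        parent = self.tree.nodes[child_id].parent
        return self._refresh([child_id], parent)

    def propose_model_change(self, model: HKYModel) -> float:
        """Replace kappa/pi/alpha: everything is recomputed (snapshotted)."""
        undo = self._begin()
        undo["model"] = self.model
        undo["tpms"] = self.tpms
        undo["partials"] = self.partials
        undo["scale"] = self.scale_log
        self.model = model
        self.tpms = {}
        self.partials = {}
        self.scale_log = {}
        return self.full_recompute()

    def revert(self) -> None:
        undo = self._undo
        if undo is None:
            raise RuntimeError("nothing to revert")
        if undo["model"] is not None:
            self.model = undo["model"]
            self.tpms = undo["tpms"]
            self.partials = undo["partials"]
            self.scale_log = undo["scale"]
        else:
            self.tpms.update(undo["tpms"])
            self.partials.update(undo["partials"])
            self.scale_log.update(undo["scale"])
        self.branch_rates.update(undo["rates"])
        self.log_likelihood = undo["loglik"]
        self._undo = None

    def commit(self) -> None:
        self._undo = None


def gene_log_likelihood(
    tree: SpeciesTree,
    enc: EncodedGene,
    model: HKYModel,
    branch_rates: dict[int, float] | None = None,
) -> float:
    """One-shot compressed log likelihood (natural log) for a gene."""
    return GeneLikelihoodEngine(tree, enc, model, branch_rates).log_likelihood


def plain_pruning_log_likelihood(
    tree: SpeciesTree,
    enc: EncodedGene,
    model: HKYModel,
    branch_rates: dict[int, float] | None = None,
) -> float:
    """Oracle: standard Felsenstein pruning, column by column.

    Iterates over the full-site-compressed columns only (weights applied at
    the root) but performs no subtree pattern sharing, so it exercises a
    different code path from the compressed engine.
    """
    if branch_rates is None:
        branch_rates = {n.id: 1.0 for n in tree.nodes if n.parent is not None}
    K = len(model.category_rates)
    s = enc.n_kept
    partials: dict[int, np.ndarray] = {}
    scales: dict[int, np.ndarray] = {}
    for nid in tree.postorder():
        node = tree.nodes[nid]
        if node.is_leaf:
            continue
        L = np.ones((s, K, 4))
        sc = np.zeros((s, K))
        for cid in node.children:
            child = tree.nodes[cid]
            duration = node.age - child.age
            P = model.category_tpms(duration * branch_rates[cid])
            if child.is_leaf:
                codes = enc.codes[tree.leaf_index[child.label]]
                L *= _leaf_contrib_table(P)[codes]
            else:
                L *= np.einsum("kxy,sky->skx", P, partials[cid])
                sc += scales[cid]
        m = L.max(axis=2)
        mask = (m > 0) & (m < _SCALE_THRESHOLD)
        if mask.any():
            L[mask] /= m[mask][:, None]
            sc[mask] += np.log(m[mask])
        partials[nid] = L
        scales[nid] = sc
    L = partials[tree.root_id]
    a = L @ model.pi
    with np.errstate(divide="ignore"):
        log_site = logsumexp(np.log(a) + scales[tree.root_id], axis=1) - np.log(K)
    return float(enc.site_weights @ log_site)
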