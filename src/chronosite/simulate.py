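"""Synthetic birth-death trees and HKY+Gamma sequence data.

Emulates the study design the inference targets: birth-death-sampling trees
of 20-200 taxa with contemporaneous tips and root age 1.0, and multi-gene
DNA alignments (10-100 genes of 1,000-10,000 sites) evolved under HKY with
kappa = 2 and 4 discrete gamma rate categories, with independent lognormal
branch rates.

Tree ages are drawn from the same BDS kernel the prior assumes (n-2 i.i.d.
draws from G^{-1}(U), assigned to a random coalescent-style topology), so
prior-only chains and recovery experiments are internally coherent.
Sequence evolution is simulated natively (root states from pi, then
per-branch categorical draws from TPM rows with per-site gamma categories)
rather than shelling out to an external simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignments import GeneAlignment, write_fasta
from .prior import BDSParams, bds_inverse_cdf
from .substitution import HKYModel, HKYParams
from .tree import SpeciesTree, TreeNode, write_newick

__all__ = ["SimConfig", "simulate_tree", "simulate_branch_rates",
           "simulate_alignment", "simulate_dataset", "make_fixture"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults are the protocol's reference point: 20 taxa, 10 genes of 2,000
    sites, HKY kappa=2 with 4 gamma categories (shape 0.5), a moderately
    sampled birth-death regime (lambda=2, mu=1, rho=0.5), and a strict-ish
    independent lognormal clock with mean rate 0.5 substitutions/site/unit
    and log-variance 0.01.  Root age is 1.0 by convention (1 unit = 100 Myr).
    """

    n_taxa: int = 20
    n_genes: int = 10
    n_sites: int = 2000
    kappa: float = 2.0
    alpha: float = 0.5
    n_cats: int = 4
    pi: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    bds: BDSParams = field(default_factory=BDSParams)
    clock_mean: float = 0.5
    clock_sigma2: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 2 or self.n_genes < 1 or self.n_sites < 1:
            raise ValueError("counts must be positive (n_taxa >= 2)")

    def hky_params(self) -> HKYParams:
        return HKYParams(self.kappa, self.pi, self.alpha, self.n_cats)


def simulate_tree(config: SimConfig, rng: np.random.Generator | None = None) -> SpeciesTree:
    """Random topology with BDS-kernel node ages; root age 1.0.

    The n-2 free ages are i.i.d. G^{-1}(uniform); lineages are merged in
    age order, picking the joining pair uniformly at random, with the final
    merge at the root.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_taxa
    nodes = [TreeNode(id=i, label=f"T{i + 1}") for i in range(n)]
    active = list(range(n))
    inner_ages = np.sort(bds_inverse_cdf(rng.uniform(size=n - 2), config.bds, 1.0))
    for age in np.concatenate([inner_ages, [1.0]]):
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        b = active.pop(j)
        a = active.pop(i)
        nid = len(nodes)
        nodes.append(TreeNode(id=nid, children=(a, b), age=float(age)))
        nodes[a].parent = nid
        nodes[b].parent = nid
        active.append(nid)
    return SpeciesTree(nodes, root_id=len(nodes) - 1)


def simulate_branch_rates(
    tree: SpeciesTree, mean: float, sigma2: float, rng: np.random.Generator
) -> dict[int, float]:
    """Independent lognormal branch rates with E[r] = mean."""
    mu_log = np.log(mean) - sigma2 / 2.0
    return {
        node.id: float(rng.lognormal(mu_log, np.sqrt(sigma2)))
        for node in tree.nodes
        if node.parent is not None
    }


def simulate_alignment(
    tree: SpeciesTree,
    branch_rates: dict[int, float],
    model: HKYModel,
    length: int,
    rng: np.random.Generator,
    name: str = "gene",
) -> GeneAlignment:
    """Evolve ``length`` sites down the tree; returns letters in leaf order."""
    K = len(model.category_rates)
    cats = rng.integers(K, size=length)
    states: dict[int, np.ndarray] = {
        tree.root_id: rng.choice(4, size=length, p=model.pi)
    }
    for nid in tree.preorder():
        node = tree.nodes[nid]
        parent_states = states[nid]
        for cid in node.children:
            child = tree.nodes[cid]
            d = (node.age - child.age) * branch_rates[cid]
            tpms = model.category_tpms(d)  # (K, 4, 4)
            # P(child | parent, category) per site, sampled by inverse cdf
            probs = tpms[cats, parent_states]  # (length, 4)
            cum = np.cumsum(probs, axis=1)
            u = rng.uniform(size=length) * cum[:, -1]
            states[cid] = (u[:, None] > cum[:, :-1]).sum(axis=1)
    taxa = [tree.nodes[nid].label for nid in tree.leaf_order]
    seqs = ["".join(_BASES[states[nid]]) for nid in tree.leaf_order]
    return GeneAlignment(name=name, taxa=taxa, seqs=seqs)


def simulate_dataset(config: SimConfig):
    """Tree + per-gene branch rates and alignments, reproducible from seed.

    Returns (tree, alignments, rates) where ``rates[g]`` is the branch-rate
    map used for gene g.
    """
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config, rng)
    model = HKYModel(config.hky_params())
    alignments, rates = [], []
    for g in range(config.n_genes):
        r = simulate_branch_rates(tree, config.clock_mean, config.clock_sigma2, rng)
        aln = simulate_alignment(
            tree, r, model, config.n_sites, rng, name=f"g{g + 1:02d}"
        )
        alignments.append(aln)
        rates.append(r)
    return tree, alignments, rates


def make_fixture(config: SimConfig, outdir) -> dict[str, object]:
    """Write a self-contained fixture: tree, genes, calibrations, truth.

    The calibration config carries the true root age as a tight soft-uniform
    bound (±5%) so the dataset can be dated end to end.  The truth table
    keys internal nodes by their sorted leaf-label sets, which survive
    newick round trips.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree, alignments, rates = simulate_dataset(config)

    tree_path = outdir / "tree.nwk"
    tree_path.write_text(write_newick(tree, with_ages=True) + "\n")

    gene_paths = []
    for aln in alignments:
        path = outdir / f"{aln.name}.fa"
        write_fasta(aln, path)
        gene_paths.append(path)

    root_age = tree.root.age
    calib_path = outdir / "calibrations.cfg"
    all_leaves = ",".join(sorted(tree.leaf_index))
    calib_path.write_text(
        "[calibration]\n"
        f"clade = {all_leaves}\n"
        "type = soft_uniform\n"
        f"min = {0.95 * root_age:.6f}\n"
        f"max = {1.05 * root_age:.6f}\n"
        "tail = 0.025\n"
    )

    truth_path = outdir / "truth_ages.tsv"
    with open(truth_path, "w") as fh:
        fh.write("clade\tage\n")
        for nid in tree.internal_ids():
            clade = ",".join(sorted(tree.leaves_below(nid)))
            fh.write(f"{clade}\t{tree.nodes[nid].age:.10f}\n")

    return {
        "tree": tree_path,
        "genes": gene_paths,
        "calibrations": calib_path,
        "truth": truth_path,
        "species_tree": tree,
        "rates": rates,
    }
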