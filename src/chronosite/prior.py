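"""Birth-death-sampling order-statistics prior on node ages, updated incrementally.

Model
-----
Conditional on the root age t_R and the number of tips n, the ages of the
n-2 non-root internal nodes behave like i.i.d. draws from the BDS kernel
density g(t) on (0, t_R) with cdf G(t).  Fossil-calibrated nodes have their
own (soft-uniform) marginal densities; the density of the remaining ages
conditional on the calibration ages *and their ranks* factorizes into
per-node g terms and, per inter-calibration segment i, a factorial term
h(i) (the count of non-calibration ages in the segment) and a power term
G'(i) (the segment's G-mass raised to that count), normalized by
(n-2-c)!:

    ln f(t_noncal | t_cal) = sum ln g(t_j) + sum ln h(i) - sum ln G'(i)
                             - ln (n-2-c)!

Incremental algorithm
---------------------
The Age Pointer Vector (APV) keeps the n-2 prior nodes sorted by age, so a
node's rank is its index.  Per segment the conditional density vector (CDV)
caches ln h(i) and ln G'(i); the evaluators themselves (first / middle /
last segment variants) are position-static.  A proposed age triggers one of
four transactions:

1. non-calibration node, no calibration rank changes: only its Delta ln g;
2. non-calibration node crossing calibration nodes: additionally the CDV
   entries bordering each crossed calibration are recomputed;
3. calibration node, no rank change: its calibration density and the G'
   entries of its two bordering segments are refreshed — a single new CDF
   evaluation, every other G value being cached;
4. calibration node changing rank: bordering h(i) and G'(i) entries (old
   and new positions) are recomputed.

The APV is repositioned by adjacent swaps; the structures are built once
and only adjusted afterwards.  ``full_log_prior`` recomputes everything
from scratch and doubles as the correctness oracle for the incremental
path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .tree import CalibrationSpec, SpeciesTree

__all__ = [
    "BDSParams",
    "bds_pdf",
    "bds_cdf",
    "bds_inverse_cdf",
    "calibration_logpdf",
    "segment_count",
    "segment_log_h",
    "segment_log_gprime",
    "PriorState",
    "full_log_prior",
]


@dataclass(frozen=True)
class BDSParams:
    """Birth rate lambda, death rate mu, sampling fraction rho."""

    lam: float = 2.0
    mu: float = 1.0
    rho: float = 0.5

    def __post_init__(self):
        if self.lam <= 0 or self.mu < 0 or not (0 < self.rho <= 1):
            raise ValueError("require lam > 0, mu >= 0, 0 < rho <= 1")


_EQUAL_RATE_TOL = 1e-12


def _check_domain(t, t_R):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > t_R):
        raise ValueError(f"age outside [0, {t_R}]")
    return t


def bds_pdf(t, params: BDSParams, t_R: float):
    """Kernel density g(t) of a node age on (0, t_R), conditional on t_R.

    For lam != mu, with r = lam - mu and
    D(t) = rho*lam + (lam*(1-rho) - mu) * exp(-r t):

        g(t) = r^2 exp(-r t) D(t_R) / (D(t)^2 (1 - exp(-r t_R)))

    which is lam * p1(t) / v_t1 in the usual BDS notation.  The lam == mu
    limit has its own closed form.
    """
    t = _check_domain(t, t_R)
    lam, mu, rho = params.lam, params.mu, params.rho
    r = lam - mu
    if abs(r) * t_R < _EQUAL_RATE_TOL:
        a = rho * lam
        return (1 + a * t_R) / (t_R * (1 + a * t) ** 2)
    em = np.exp(-r * t)
    D = -rho * lam * np.expm1(-r * t) + r * em
    em_R = np.exp(-r * t_R)
    D_R = -rho * lam * np.expm1(-r * t_R) + r * em_R
    return r * r * em * D_R / (D * D * (-np.expm1(-r * t_R)))


def bds_cdf(t, params: BDSParams, t_R: float):
    """Cumulative kernel G(t); G(0) = 0 and G(t_R) = 1."""
    t = _check_domain(t, t_R)
    lam, mu, rho = params.lam, params.mu, params.rho
    r = lam - mu
    if abs(r) * t_R < _EQUAL_RATE_TOL:
        a = rho * lam
        return (1 + a * t_R) * t / (t_R * (1 + a * t))
    D = -rho * lam * np.expm1(-r * t) + r * np.exp(-r * t)
    D_R = -rho * lam * np.expm1(-r * t_R) + r * np.exp(-r * t_R)
    return np.expm1(-r * t) * D_R / (np.expm1(-r * t_R) * D)


def bds_inverse_cdf(q, params: BDSParams, t_R: float):
    """Quantile function G^{-1}(q), the sampler behind tree simulation."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0) or np.any(q > 1):
        raise ValueError("quantile outside [0, 1]")
    lam, mu, rho = params.lam, params.mu, params.rho
    r = lam - mu
    if abs(r) * t_R < _EQUAL_RATE_TOL:
        a = rho * lam
        return q * t_R / (1 + a * t_R * (1 - q))
    D_R = -rho * lam * np.expm1(-r * t_R) + r * np.exp(-r * t_R)
    # solve q = (1-u) D_R / ((1 - e^{-r t_R}) (rho lam + b u)) for u = e^{-rt}
    b = lam * (1 - rho) - mu
    A = q * (-np.expm1(-r * t_R)) / D_R
    u = (1 - A * rho * lam) / (1 + A * b)
    return -np.log(u) / r


def calibration_logpdf(spec: CalibrationSpec, t: float) -> float:
    """Log density of a soft-uniform fossil calibration at age ``t``.

    Uniform height h0 = (1 - 2p)/(t_U - t_L) between the bounds; each tail
    is exponential with rate h0/p, continuous at the bound and carrying
    mass p (p = ``tail_prob``).
    """
    p = spec.tail_prob
    h0 = (1.0 - 2.0 * p) / (spec.t_upper - spec.t_lower)
    rate = h0 / p
    if t < spec.t_lower:
        return float(np.log(h0) + rate * (t - spec.t_lower))
    if t > spec.t_upper:
        return float(np.log(h0) - rate * (t - spec.t_upper))
    return float(np.log(h0))


# -- segment evaluators (Conditional Density Function Vector) ---------------


def segment_count(i: int, ranks: list[int], n: int) -> int:
    """Number of non-calibration ages in segment i.

    ``ranks`` are the 1-based APV positions of the c calibration nodes in
    ascending order; segments 0..c are the gaps they cut out of the n-2
    sorted ages.  The counts partition n-2-c.
    """
    c = len(ranks)
    if c == 0:
        return n - 2
    if i == 0:
        return ranks[0] - 1
    if i == c:
        return n - 2 - ranks[-1]
    return ranks[i] - ranks[i - 1] - 1


def segment_log_h(i: int, ranks: list[int], n: int, c: int) -> float:
    """ln h(i): log-factorial of the segment's non-calibration count."""
    k = segment_count(i, ranks, n)
    if k < 0:
        raise ValueError(f"negative segment count at i={i} (ranks {ranks})")
    return float(gammaln(k + 1))


def segment_log_gprime(
    i: int, g_values: list[float], ranks: list[int], n: int, c: int
) -> float:
    """ln G'(i): the segment's G-mass raised to its non-calibration count.

    ``g_values`` are the cached CDF values G(t) of the calibration nodes in
    rank order.  A zero exponent yields 0 regardless of the base; a
    non-positive base with positive exponent signals an inconsistent
    ordering and yields -inf.
    """
    k = segment_count(i, ranks, n)
    if k == 0:
        return 0.0
    if c == 0:
        return 0.0  # base is G(t_R) - G(0) = 1
    if i == 0:
        base = g_values[0]
    elif i == c:
        base = 1.0 - g_values[-1]
    else:
        base = g_values[i] - g_values[i - 1]
    if base <= 0.0:
        return float("-inf")
    return k * float(np.log(base))


# -- prior state ------------------------------------------------------------


class PriorState:
    """APV + CDV caches for one species tree.

    Node ages are mirrored in ``self.ages``; the caller updates the tree
    and then routes the change through :meth:`propose_age_update`, followed
    by :meth:`commit` or :meth:`revert`.
    """

    def __init__(
        self,
        tree: SpeciesTree,
        calibrations: dict[int, CalibrationSpec],
        params: BDSParams,
    ):
        if tree.root_id not in calibrations:
            raise ValueError("root calibration required")
        self.tree = tree
        self.specs = dict(calibrations)
        self.params = params
        self.node_ids = [
            nid for nid in tree.preorder()
            if not tree.nodes[nid].is_leaf and nid != tree.root_id
        ]
        self.is_cal = {nid: nid in self.specs for nid in self.node_ids}
        self.n = tree.n_leaves
        self.c = sum(self.is_cal.values())
        self._pending: dict | None = None
        self.last_cdv_recomputes = 0
        self.transaction_counts = {1: 0, 2: 0, 3: 0, 4: 0, "root": 0}
        self.rebuild()

    # -- construction / full recompute --------------------------------------

    def rebuild(self) -> float:
        """(Re)build the APV, kernel caches and CDV from the tree ages."""
        tree = self.tree
        self.t_R = tree.root.age
        self.ages = {nid: tree.nodes[nid].age for nid in self.node_ids}
        self.order = sorted(self.node_ids, key=lambda nid: (self.ages[nid], nid))
        self.pos = {nid: i for i, nid in enumerate(self.order)}
        self.cals = [nid for nid in self.order if self.is_cal[nid]]
        self.log_g: dict[int, float] = {}
        self.G: dict[int, float] = {}
        self.log_fcal: dict[int, float] = {}
        for nid in self.node_ids:
            if self.is_cal[nid]:
                self.G[nid] = float(bds_cdf(self.ages[nid], self.params, self.t_R))
                self.log_fcal[nid] = calibration_logpdf(self.specs[nid], self.ages[nid])
            else:
                self.log_g[nid] = float(np.log(bds_pdf(self.ages[nid], self.params, self.t_R)))
        self.log_fcal_root = calibration_logpdf(self.specs[self.tree.root_id], self.t_R)
        ranks = self.ranks()
        gvals = [self.G[cid] for cid in self.cals]
        self.cdv_log_h = [
            segment_log_h(i, ranks, self.n, self.c) for i in range(self.c + 1)
        ]
        self.cdv_log_gp = [
            segment_log_gprime(i, gvals, ranks, self.n, self.c)
            for i in range(self.c + 1)
        ]
        self.log_f_cond = (
            sum(self.log_g.values())
            + sum(self.cdv_log_h)
            - sum(self.cdv_log_gp)
            - float(gammaln(self.n - 2 - self.c + 1))
        )
        self.log_fcal_total = sum(self.log_fcal.values()) + self.log_fcal_root
        return self.total_log_prior

    def ranks(self) -> list[int]:
        """1-based APV positions of the calibration nodes, ascending."""
        return [self.pos[cid] + 1 for cid in self.cals]

    @property
    def total_log_prior(self) -> float:
        return self.log_f_cond + self.log_fcal_total

    # -- transactions --------------------------------------------------------

    def _snapshot(self) -> dict:
        return {
            "order": list(self.order),
            "pos": dict(self.pos),
            "cals": list(self.cals),
            "ages": dict(self.ages),
            "t_R": self.t_R,
            "log_g": dict(self.log_g),
            "G": dict(self.G),
            "log_fcal": dict(self.log_fcal),
            "log_fcal_root": self.log_fcal_root,
            "cdv_log_h": list(self.cdv_log_h),
            "cdv_log_gp": list(self.cdv_log_gp),
            "log_f_cond": self.log_f_cond,
            "log_fcal_total": self.log_fcal_total,
        }

    def propose_age_update(self, node_id: int, new_age: float) -> float:
        """Apply one age proposal; returns Delta (total log prior).

        The transaction class is detected from whether the node is
        calibrated and whether any calibration rank changed; only the CDV
        entries bordering affected calibrations are recomputed.
        """
        if self._pending is not None:
            raise RuntimeError("uncommitted transaction pending")
        snap = self._snapshot()
        self._pending = snap
        old_total = self.total_log_prior

        if node_id == self.tree.root_id:
            # every g and G depends on t_R: refresh all kernel caches
            self.tree.nodes[node_id].age = new_age
            self.rebuild()
            self.last_cdv_recomputes = self.c + 1
            self.transaction_counts["root"] += 1
            return self.total_log_prior - old_total

        is_cal = self.is_cal[node_id]
        old_cal_index = {cid: j for j, cid in enumerate(self.cals)}
        self.ages[node_id] = new_age
        self.tree.nodes[node_id].age = new_age

        # reposition by adjacent swaps, tracking crossed calibrations
        crossed: set[int] = set()
        i = self.pos[node_id]
        start = i
        while i > 0 and self.ages[self.order[i - 1]] > new_age:
            other = self.order[i - 1]
            self._swap(i - 1, i)
            if self.is_cal[other]:
                crossed.add(other)
            i -= 1
        while i < len(self.order) - 1 and self.ages[self.order[i + 1]] < new_age:
            other = self.order[i + 1]
            self._swap(i, i + 1)
            if self.is_cal[other]:
                crossed.add(other)
            i += 1
        moved = i != start

        # refresh the node's own kernel cache
        delta_g = 0.0
        delta_fcal = 0.0
        if is_cal:
            self.G[node_id] = float(bds_cdf(new_age, self.params, self.t_R))
            new_lf = calibration_logpdf(self.specs[node_id], new_age)
            delta_fcal = new_lf - self.log_fcal[node_id]
            self.log_fcal[node_id] = new_lf
        else:
            new_lg = float(np.log(bds_pdf(new_age, self.params, self.t_R)))
            delta_g = new_lg - self.log_g[node_id]
            self.log_g[node_id] = new_lg

        # CDV entries bordering every affected calibration (old + new index)
        touched = set(crossed)
        if is_cal:
            touched.add(node_id)
        affected: set[int] = set()
        for cid in touched:
            j_old = old_cal_index[cid]
            j_new = self.cals.index(cid)
            affected.update((j_old, j_old + 1, j_new, j_new + 1))

        delta_cdv = 0.0
        if affected:
            ranks = self.ranks()
            gvals = [self.G[cid] for cid in self.cals]
            for j in sorted(affected):
                new_h = segment_log_h(j, ranks, self.n, self.c)
                new_gp = segment_log_gprime(j, gvals, ranks, self.n, self.c)
                delta_cdv += (new_h - self.cdv_log_h[j]) - (
                    new_gp - self.cdv_log_gp[j]
                )
                self.cdv_log_h[j] = new_h
                self.cdv_log_gp[j] = new_gp
        self.last_cdv_recomputes = len(affected)

        self.log_f_cond += delta_g + delta_cdv
        self.log_fcal_total += delta_fcal

        if not is_cal:
            klass = 2 if moved else 1
        else:
            klass = 4 if (crossed or moved) else 3
        self.transaction_counts[klass] += 1
        return self.total_log_prior - old_total

    def _swap(self, i: int, j: int) -> None:
        a, b = self.order[i], self.order[j]
        self.order[i], self.order[j] = b, a
        self.pos[a], self.pos[b] = j, i
        if self.is_cal[a] and self.is_cal[b]:
            ia, ib = self.cals.index(a), self.cals.index(b)
            self.cals[ia], self.cals[ib] = b, a

    def revert(self) -> None:
        """Restore the state before the pending transaction, exactly."""
        snap = self._pending
        if snap is None:
            raise RuntimeError("nothing to revert")
        self.order = snap["order"]
        self.pos = snap["pos"]
        self.cals = snap["cals"]
        self.ages = snap["ages"]
        self.t_R = snap["t_R"]
        self.log_g = snap["log_g"]
        self.G = snap["G"]
        self.log_fcal = snap["log_fcal"]
        self.log_fcal_root = snap["log_fcal_root"]
        self.cdv_log_h = snap["cdv_log_h"]
        self.cdv_log_gp = snap["cdv_log_gp"]
        self.log_f_cond = snap["log_f_cond"]
        self.log_fcal_total = snap["log_fcal_total"]
        for nid, age in self.ages.items():
            self.tree.nodes[nid].age = age
        self.tree.nodes[self.tree.root_id].age = self.t_R
        self._pending = None

    def commit(self) -> None:
        self._pending = None


def full_log_prior(state: PriorState) -> float:
    """From-scratch evaluation of the log prior of ages (the oracle).

    Rebuilds the sorted age list, ranks, segment terms and calibration
    densities directly from the tree, sharing none of the incremental
    caches.
    """
    tree = state.tree
    params = state.params
    t_R = tree.root.age
    ids = [
        nid for nid in tree.preorder()
        if not tree.nodes[nid].is_leaf and nid != tree.root_id
    ]
    n = tree.n_leaves
    ages = {nid: tree.nodes[nid].age for nid in ids}
    order = sorted(ids, key=lambda nid: (ages[nid], nid))
    cals = [nid for nid in order if nid in state.specs]
    c = len(cals)
    ranks = [order.index(cid) + 1 for cid in cals]
    gvals = [float(bds_cdf(ages[cid], params, t_R)) for cid in cals]
    total = -float(gammaln(n - 2 - c + 1))
    for nid in ids:
        if nid not in state.specs:
            total += float(np.log(bds_pdf(ages[nid], params, t_R)))
    for i in range(c + 1):
        total += segment_log_h(i, ranks, n, c)
        total -= segment_log_gprime(i, gvals, ranks, n, c)
    for nid, spec in state.specs.items():
        total += calibration_logpdf(spec, tree.nodes[nid].age)
    return total
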