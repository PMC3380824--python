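"""Two-population isolation-with-migration coalescent simulator.

This is the package's synthetic-data engine: a backwards-in-time
structured coalescent for two populations that diverged from a common
ancestor and may exchange migrants, with infinite-sites mutation and
optional intra-locus recombination (an ancestral recombination graph).

Scaling follows the isolation-with-migration (IM) convention, in which
every parameter is expressed relative to the per-locus mutation rate u:

* theta_i = 4 N_i u   — mutation-scaled population sizes,
* t_split = T u       — mutation-scaled divergence time,
* m_i     = m_i / u   — mutation-scaled migration rate *into* population
  i (forwards in time), so lineages sampled in population i jump to the
  other deme backwards in time,
* rho     = r / u     — mutation-scaled intra-locus recombination rate.

Time is measured in mutational units: within deme i each lineage pair
coalesces at rate 2/theta_i, each lineage in deme i migrates at rate
m_i/2, each lineage recombines at rate rho/2 per unit of ancestral span,
and mutations fall at rate 1 per unit branch length, so a sample of two
from one population differs at theta sites on average and the effective
number of migrants per generation is 2 N_i m_i = theta_i m_i / 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .seqdata import HaplotypeAlignment, InputError

__all__ = [
    "IMParameters",
    "RateConstants",
    "Genealogy",
    "SegmentAncestry",
    "simulate_genealogy",
    "simulate_ancestry",
    "binary_site_matrix",
    "drop_mutations_infinite_sites",
    "StudyDesign",
    "LocusDesign",
    "SimulatedDataset",
    "default_study_design",
    "simulate_study",
    "fst_summary",
    "convert_to_2Nm",
    "mu_from_divergence",
]


@dataclass(frozen=True)
class IMParameters:
    """Mutation-scaled parameters of the two-population IM model."""

    theta1: float
    theta2: float
    thetaA: float
    t_split: float
    m1: float
    m2: float
    n1: int
    n2: int
    locus_length: int = 500
    rho: float = 0.0
    pulse_time: float = 0.0
    pulse1: float = 0.0
    pulse2: float = 0.0
    pulse_sweep: bool = False

    def __post_init__(self) -> None:
        if min(self.theta1, self.theta2, self.thetaA) <= 0:
            raise InputError("all theta must be > 0")
        if self.t_split < 0 or self.m1 < 0 or self.m2 < 0 or self.rho < 0:
            raise InputError("t_split, m1, m2 and rho must be >= 0")
        if not 0 <= self.pulse1 <= 1 or not 0 <= self.pulse2 <= 1:
            raise InputError("pulse fractions must be in [0, 1]")
        if (self.pulse1 or self.pulse2) and not 0 < self.pulse_time < self.t_split:
            raise InputError("pulse_time must lie strictly between 0 and t_split")
        if self.n1 < 0 or self.n2 < 0 or self.n1 + self.n2 < 1:
            raise InputError("need at least one sampled haplotype")
        if self.locus_length < 1:
            raise InputError("locus_length must be >= 1")


@dataclass(frozen=True)
class RateConstants:
    """Life-history constants used to convert mutation-scaled estimates
    into years and generations for Heliconius: roughly ten 35-day
    generations per year."""

    generations_per_year: float = 10.0
    generation_time_days: float = 35.0
    mu_per_locus_per_year: dict[str, float] = field(
        default_factory=lambda: {
            # per-locus per-year rates used for the published conversions
            "COI": 6.2e-6,
            "GAPDH": 7.1e-8,
            "Hsp90": 1.2e-6,
            "HmB453k": 3.4e-5,
        }
    )

    def __post_init__(self) -> None:
        days = self.generations_per_year * self.generation_time_days
        if not 300 <= days <= 430:
            raise InputError(
                "generations_per_year x generation_time_days should be about "
                f"one year, got {days:.0f} days"
            )

    def mu_per_generation(self, locus: str) -> float:
        return self.mu_per_locus_per_year[locus] / self.generations_per_year


# ---------------------------------------------------------------------------
# genealogy simulation (single non-recombining tree)
# ---------------------------------------------------------------------------


@dataclass
class Genealogy:
    """An ultrametric coalescent tree for n1 + n2 sampled haplotypes.

    Leaves are nodes 0..n-1 (population 1 first), internal nodes follow
    in coalescence order; ``parent`` is -1 for the root.  ``pieces``
    lists (branch length, descendant-leaf bitmask) for every non-root
    branch and is the substrate for mutation dropping.
    """

    n1: int
    n2: int
    times: np.ndarray
    parent: np.ndarray
    node_deme: np.ndarray  # deme at birth: 0, 1, or 2 (ancestral)
    pieces: list[tuple[float, int]]

    @property
    def n(self) -> int:
        return self.n1 + self.n2

    @property
    def total_branch_length(self) -> float:
        return float(sum(w for w, _ in self.pieces))

    @property
    def tmrca(self) -> float:
        return float(self.times.max())


def simulate_genealogy(params: IMParameters, rng: np.random.Generator) -> Genealogy:
    """Simulate one genealogy under the IM model (no recombination).

    Backwards in time: pairs within deme i coalesce at rate 2/theta_i,
    lineages in deme i migrate to the other deme at rate m_i/2, and at
    ``t_split`` the demes merge into the ancestral population (rate
    2/thetaA).  Node times are in mutational units.
    """
    n1, n2 = params.n1, params.n2
    n = n1 + n2
    times = [0.0] * n
    parent = [-1] * (2 * n - 1) if n > 1 else [-1] * n
    node_deme = [0] * n1 + [1] * n2
    masks: dict[int, int] = {i: 1 << i for i in range(n)}
    deme_of: dict[int, int] = {i: (0 if i < n1 else 1) for i in range(n)}
    active = list(range(n))
    tau = 0.0
    next_node = n
    merged = params.t_split == 0.0
    if merged:
        deme_of = {i: 2 for i in active}

    theta = (params.theta1, params.theta2)
    mig = (params.m1, params.m2)
    pulse_done = merged or not (params.pulse1 or params.pulse2)

    while len(active) > 1:
        if not merged:
            k = [sum(1 for v in deme_of.values() if v == d) for d in (0, 1)]
            rates = [
                k[0] * (k[0] - 1) / theta[0],
                k[1] * (k[1] - 1) / theta[1],
                k[0] * mig[0] / 2.0,
                k[1] * mig[1] / 2.0,
            ]
            total = sum(rates)
            wait = rng.exponential(1.0 / total) if total > 0 else math.inf
            if not pulse_done and tau + wait >= params.pulse_time:
                tau = params.pulse_time
                pulse_done = True
                for d in (0, 1):
                    frac = params.pulse1 if d == 0 else params.pulse2
                    if frac <= 0:
                        continue
                    pool = [i for i in active if deme_of[i] == d]
                    k_move = int(round(frac * len(pool)))
                    idx = rng.choice(len(pool), size=k_move, replace=False)
                    movers = [pool[int(i)] for i in idx]
                    if params.pulse_sweep and len(movers) > 1:
                        # sweep approximation: star-coalesce admixed lineages
                        while len(movers) > 1:
                            a, b = movers[0], movers[1]
                            _coalesce(a, b, tau, d, times, parent, node_deme,
                                      masks, deme_of, active, next_node)
                            movers = [next_node] + movers[2:]
                            next_node += 1
                    for i in movers:
                        deme_of[i] = 1 - d
                continue
            if tau + wait >= params.t_split:
                tau = params.t_split
                merged = True
                for i in active:
                    deme_of[i] = 2
                continue
            tau += wait
            ev = rng.choice(4, p=np.asarray(rates) / total)
            if ev < 2:  # coalescence in deme ev
                pool = [i for i in active if deme_of[i] == ev]
                a, b = rng.choice(len(pool), size=2, replace=False)
                _coalesce(pool[a], pool[b], tau, int(ev), times, parent,
                          node_deme, masks, deme_of, active, next_node)
                next_node += 1
            else:  # migration out of deme ev-2 (backwards)
                d = ev - 2
                pool = [i for i in active if deme_of[i] == d]
                mover = pool[rng.integers(len(pool))]
                deme_of[mover] = 1 - d
        else:
            k = len(active)
            rate = k * (k - 1) / params.thetaA
            tau += rng.exponential(1.0 / rate)
            a, b = rng.choice(k, size=2, replace=False)
            _coalesce(active[a], active[b], tau, 2, times, parent,
                      node_deme, masks, deme_of, active, next_node)
            next_node += 1

    times_arr = np.asarray(times)
    parent_arr = np.asarray(parent[: len(times)], dtype=int)
    pieces = [
        (float(times_arr[parent_arr[i]] - times_arr[i]), _mask_of(i, masks, parent_arr, times_arr))
        for i in range(len(times))
        if parent_arr[i] != -1
    ]
    return Genealogy(
        n1=n1,
        n2=n2,
        times=times_arr,
        parent=parent_arr,
        node_deme=np.asarray(node_deme, dtype=int),
        pieces=pieces,
    )


def _coalesce(a, b, tau, deme, times, parent, node_deme, masks, deme_of, active, new):
    times.append(tau)
    node_deme.append(deme)
    while len(parent) <= new:
        parent.append(-1)
    parent[a] = new
    parent[b] = new
    masks[new] = masks[a] | masks[b]
    deme_of[new] = deme
    for x in (a, b):
        active.remove(x)
        del deme_of[x]
    active.append(new)


def _mask_of(i, masks, parent_arr, times_arr):
    return masks[i]


# ---------------------------------------------------------------------------
# ancestral recombination graph (segment-tracking Hudson algorithm)
# ---------------------------------------------------------------------------


@dataclass
class SegmentAncestry:
    """Recorded ancestry of a recombining locus: mutation-bearing pieces.

    ``piece_weights[i]`` is lineage lifetime x segment span (locus span
    normalized to 1) and ``piece_masks[i]`` the descendant bitmask, so
    mutations dropped proportional to weight land on the correct marginal
    genealogy for their position.
    """

    n1: int
    n2: int
    piece_weights: np.ndarray
    piece_masks: np.ndarray  # uint64 descendant bitmasks

    @property
    def n(self) -> int:
        return self.n1 + self.n2

    @property
    def pieces(self) -> list[tuple[float, int]]:
        return list(zip(self.piece_weights.tolist(),
                        (int(m) for m in self.piece_masks)))

    @property
    def total_branch_length(self) -> float:
        return float(self.piece_weights.sum())


class _Lineage:
    __slots__ = ("segments", "deme", "birth")

    def __init__(self, segments, deme, birth):
        self.segments = segments  # list of (left, right, mask), sorted, on [0,1)
        self.deme = deme
        self.birth = birth

    @property
    def span(self) -> float:
        return self.segments[-1][1] - self.segments[0][0]

    @property
    def length(self) -> float:
        return sum(r - l for l, r, _ in self.segments)


def simulate_ancestry(
    params: IMParameters,
    rng: np.random.Generator,
    engine: str = "auto",
) -> SegmentAncestry:
    """Simulate locus ancestry under the IM model with intra-locus
    recombination at rate ``params.rho`` (mutation-scaled; rate rho/2
    per lineage per unit of ancestral span).

    With ``rho=0`` this reduces to a single genealogy and matches
    :func:`simulate_genealogy` in distribution.  ``engine`` selects the
    compiled kernel (``"numba"``, the default when available) or the
    pure-Python reference implementation (``"python"``); the two agree
    in distribution and are cross-checked in the test suite.
    """
    from . import _arg_kernel

    if engine not in {"auto", "numba", "python"}:
        raise InputError(f"unknown engine {engine!r}")
    if engine in {"auto", "numba"} and _arg_kernel.HAVE_NUMBA:
        if params.n1 + params.n2 > 64:
            if engine == "numba":
                raise InputError("compiled kernel supports at most 64 haplotypes")
        else:
            w, m = _arg_kernel._arg_kernel(
                params.theta1, params.theta2, params.thetaA, params.t_split,
                params.m1, params.m2, params.rho,
                params.pulse_time, params.pulse1, params.pulse2,
                params.pulse_sweep,
                params.n1, params.n2, int(rng.integers(2**31)),
            )
            return SegmentAncestry(params.n1, params.n2, w, m)
    return _simulate_ancestry_py(params, rng)


def _simulate_ancestry_py(params: IMParameters, rng: np.random.Generator) -> SegmentAncestry:
    n1, n2 = params.n1, params.n2
    n = n1 + n2
    full = (1 << n) - 1
    merged = params.t_split == 0.0
    start_deme = 2 if merged else None
    pools: dict[int, list[_Lineage]] = {0: [], 1: [], 2: []}
    for i in range(n):
        deme = start_deme if merged else (0 if i < n1 else 1)
        pools[deme].append(_Lineage([(0.0, 1.0, 1 << i)], deme, 0.0))
    pieces: list[tuple[float, int]] = []
    tau = 0.0
    theta = (params.theta1, params.theta2, params.thetaA)
    mig = (params.m1, params.m2)
    half_rho = params.rho / 2.0
    span_sum = float(n) if params.rho else 0.0
    pulse_done = merged or not (params.pulse1 or params.pulse2)

    def retire(lin: _Lineage, now: float) -> None:
        life = now - lin.birth
        if life > 0:
            for l, r, mask in lin.segments:
                pieces.append((life * (r - l), mask))

    def pick_weighted_span(target: float) -> tuple[int, int]:
        acc = 0.0
        for d in (0, 1, 2):
            for idx, lin in enumerate(pools[d]):
                acc += lin.span
                if acc >= target:
                    return d, idx
        d = 2 if merged else (0 if pools[0] else 1)
        return d, len(pools[d]) - 1  # float slop: last lineage

    while pools[0] or pools[1] or pools[2]:
        k0, k1, k2 = len(pools[0]), len(pools[1]), len(pools[2])
        if k0 + k1 + k2 == 1 and params.rho == 0:
            break  # n == 1: a single non-recombining sample has no history
        if merged:
            rates = (0.0, 0.0, 0.0, 0.0, k2 * (k2 - 1) / theta[2])
        else:
            rates = (
                k0 * (k0 - 1) / theta[0],
                k1 * (k1 - 1) / theta[1],
                k0 * mig[0] / 2.0,
                k1 * mig[1] / 2.0,
                0.0,
            )
        rec_rate = half_rho * span_sum
        total = rates[0] + rates[1] + rates[2] + rates[3] + rates[4] + rec_rate
        wait = rng.exponential() / total if total > 0 else math.inf
        if not pulse_done and tau + wait >= params.pulse_time:
            # admixture pulse: a fraction of each deme's lineages traces
            # its ancestry to the other deme at this instant (backwards)
            tau = params.pulse_time
            pulse_done = True
            for d, frac in ((0, params.pulse1), (1, params.pulse2)):
                if frac <= 0:
                    continue
                k_move = int(round(frac * len(pools[d])))
                idx = rng.choice(len(pools[d]), size=k_move, replace=False)
                movers = [pools[d][int(i)] for i in idx]
                for mover in movers:
                    retire(mover, tau)
                    pools[d].remove(mover)
                    span_sum -= mover.span
                if not movers:
                    continue
                if params.pulse_sweep and len(movers) > 1:
                    # selective-sweep approximation: all introgressed
                    # material descends from a single donor haplotype, so
                    # the admixed lineages star-coalesce at the pulse
                    segs = movers[0].segments
                    for other in movers[1:]:
                        segs = _merge_segments(segs, other.segments, full)
                    movers = [_Lineage(segs, d, tau)] if segs else []
                for mover in movers:
                    mover.birth = tau
                    mover.deme = 1 - d
                    pools[1 - d].append(mover)
                    span_sum += mover.span
            continue
        if not merged and tau + wait >= params.t_split:
            tau = params.t_split
            merged = True
            pools[2] = pools[0] + pools[1]
            pools[0] = []
            pools[1] = []
            for lin in pools[2]:
                lin.deme = 2
            continue
        if not math.isfinite(wait):  # pragma: no cover - defensive
            raise RuntimeError("stuck ancestry simulation")
        tau += wait
        u = rng.random() * total
        if u < rec_rate:
            d, idx = pick_weighted_span(u / half_rho)
            lin = pools[d][idx]
            left_edge = lin.segments[0][0]
            bp = left_edge + rng.random() * lin.span
            left = []
            right = []
            for l, r, m in lin.segments:
                if r <= bp:
                    left.append((l, r, m))
                elif l >= bp:
                    right.append((l, r, m))
                else:
                    left.append((l, bp, m))
                    right.append((bp, r, m))
            if not left or not right:
                continue  # breakpoint at the edge of ancestral material
            retire(lin, tau)
            pools[d][idx] = pools[d][-1]
            pools[d].pop()
            la = _Lineage(left, d, tau)
            lb = _Lineage(right, d, tau)
            pools[d].append(la)
            pools[d].append(lb)
            span_sum += la.span + lb.span - lin.span
        else:
            u -= rec_rate
            if u < rates[0] + rates[1] + rates[4]:
                if merged:
                    d = 2
                else:
                    d = 0 if u < rates[0] else 1
                pool = pools[d]
                ia = int(rng.integers(len(pool)))
                ib = int(rng.integers(len(pool) - 1))
                if ib >= ia:
                    ib += 1
                if ia > ib:
                    ia, ib = ib, ia
                la, lb = pool[ia], pool[ib]
                retire(la, tau)
                retire(lb, tau)
                pool[ib] = pool[-1]
                pool.pop()
                pool[ia] = pool[-1]
                pool.pop()
                span_sum -= la.span + lb.span
                segs = _merge_segments(la.segments, lb.segments, full)
                if segs:
                    lc = _Lineage(segs, d, tau)
                    pool.append(lc)
                    span_sum += lc.span
            else:
                u -= rates[0] + rates[1] + rates[4]
                d = 0 if u < rates[2] else 1
                pool = pools[d]
                idx = int(rng.integers(len(pool)))
                mover = pool[idx]
                retire(mover, tau)
                mover.birth = tau
                mover.deme = 1 - d
                pool[idx] = pool[-1]
                pool.pop()
                pools[1 - d].append(mover)
    w = np.array([p[0] for p in pieces], dtype=float)
    m = np.array([p[1] for p in pieces], dtype=np.uint64)
    return SegmentAncestry(n1=n1, n2=n2, piece_weights=w, piece_masks=m)


def _merge_segments(a, b, full):
    """Union of two sorted segment lists; overlapping parts get the OR'd
    mask and parts whose mask reaches all samples (marginal MRCA) are
    dropped.  Linear two-pointer sweep."""
    stitched: list[tuple[float, float, int]] = []
    ia = ib = 0
    na, nb = len(a), len(b)
    # current sweep position
    pos = min(a[0][0] if na else math.inf, b[0][0] if nb else math.inf)
    while ia < na or ib < nb:
        mask = 0
        nxt = math.inf
        if ia < na:
            la, ra, ma = a[ia]
            if la <= pos:
                if ra > pos:
                    mask |= ma
                    nxt = min(nxt, ra)
                else:
                    ia += 1
                    continue
            else:
                nxt = min(nxt, la)
        if ib < nb:
            lb, rb, mb = b[ib]
            if lb <= pos:
                if rb > pos:
                    mask |= mb
                    nxt = min(nxt, rb)
                else:
                    ib += 1
                    continue
            else:
                nxt = min(nxt, lb)
        if nxt is math.inf:  # pragma: no cover - defensive
            break
        if mask and mask != full:
            if stitched and stitched[-1][2] == mask and stitched[-1][1] == pos:
                stitched[-1] = (stitched[-1][0], nxt, mask)
            else:
                stitched.append((pos, nxt, mask))
        pos = nxt
    return stitched


# ---------------------------------------------------------------------------
# mutation dropping
# ---------------------------------------------------------------------------


def _piece_arrays(ancestry: "Genealogy | SegmentAncestry") -> tuple[np.ndarray, np.ndarray]:
    if isinstance(ancestry, SegmentAncestry):
        return ancestry.piece_weights, ancestry.piece_masks
    w = np.array([p[0] for p in ancestry.pieces], dtype=float)
    m = np.array([p[1] for p in ancestry.pieces], dtype=np.uint64)
    return w, m


def _masks_to_matrix(masks: np.ndarray, n: int) -> np.ndarray:
    bits = np.arange(n, dtype=np.uint64)
    return ((masks[None, :] >> bits[:, None]) & np.uint64(1)).astype(np.int8)


def binary_site_matrix(
    ancestry: Genealogy | SegmentAncestry,
    rng: np.random.Generator,
    n_mutations: int | None = None,
) -> np.ndarray:
    """Drop infinite-sites mutations and return a 0/1 haplotype-by-site
    matrix (1 = derived).  The mutation count is Poisson(total branch
    length) — time is mutational, so the rate per unit length is 1 —
    unless ``n_mutations`` fixes it (used by the conditional null
    simulations of the gene-flow test)."""
    weights, masks = _piece_arrays(ancestry)
    total = float(weights.sum())
    if n_mutations is None:
        n_mutations = int(rng.poisson(total)) if total > 0 else 0
    n = ancestry.n
    if n_mutations == 0 or total == 0:
        return np.zeros((n, 0), dtype=np.int8)
    idx = rng.choice(len(weights), size=n_mutations, p=weights / total)
    return _masks_to_matrix(masks[idx], n)


def classify_pieces(
    ancestry: Genealogy | SegmentAncestry, n1: int
) -> dict[str, np.ndarray]:
    """Index mutation-bearing pieces by the site class a mutation on them
    would produce relative to the two sampled populations: ``shared``
    (segregating in both), ``excl1``/``excl2`` (segregating in one only),
    ``fixed`` (a fixed difference)."""
    n = ancestry.n
    n2 = n - n1
    _, masks = _piece_arrays(ancestry)
    mask1 = np.uint64((1 << n1) - 1)
    mask2 = np.uint64(((1 << n) - 1) ^ int(mask1))
    a = np.bitwise_count(masks & mask1)
    b = np.bitwise_count(masks & mask2)
    seg1 = (a > 0) & (a < n1)
    seg2 = (b > 0) & (b < n2)
    return {
        "shared": np.where(seg1 & seg2)[0],
        "excl1": np.where(seg1 & ~seg2)[0],
        "excl2": np.where(seg2 & ~seg1)[0],
        "fixed": np.where(~seg1 & ~seg2)[0],
    }


def conditional_site_matrix(
    ancestry: Genealogy | SegmentAncestry,
    n1: int,
    class_counts: dict[str, int],
    rng: np.random.Generator,
) -> np.ndarray | None:
    """0/1 site matrix with mutation numbers fixed per site class.

    Used by the gene-flow test's conditional null: each replicate matches
    the observed numbers of shared and exclusive sites, so the comparison
    isolates the linkage-disequilibrium pattern.  Returns None when the
    genealogy cannot produce a required class.
    """
    weights, masks = _piece_arrays(ancestry)
    by_class = classify_pieces(ancestry, n1)
    chosen: list[np.ndarray] = []
    for klass, count in class_counts.items():
        if count == 0:
            continue
        idx = by_class[klass]
        if idx.size == 0:
            return None
        w = weights[idx]
        pick = rng.choice(idx.size, size=count, p=w / w.sum())
        chosen.append(masks[idx[pick]])
    if not chosen:
        return np.zeros((ancestry.n, 0), dtype=np.int8)
    return _masks_to_matrix(np.concatenate(chosen), ancestry.n)


def drop_mutations_infinite_sites(
    ancestry: Genealogy | SegmentAncestry,
    locus_length: int,
    rng: np.random.Generator,
    ids: Sequence[str] | None = None,
    locus_name: str = "locus",
    theta: float | None = None,
) -> HaplotypeAlignment:
    """Render an infinite-sites mutated alignment for a simulated
    ancestry.  Each mutation occupies its own column (ancestral base A,
    derived base T); unmutated columns are monomorphic A.

    ``theta`` is only needed for ancestries whose times are in coalescent
    units of 2N generations (mutation intensity theta/2 per unit length);
    ancestries from this module are in mutational units and use rate 1.
    """
    scale = 1.0 if theta is None else theta / 2.0
    total = ancestry.total_branch_length * scale
    n_mut = int(rng.poisson(total))
    if n_mut > locus_length:
        raise InputError(
            f"{n_mut} mutations exceed locus_length={locus_length}; "
            "increase locus_length (infinite-sites collision guard)"
        )
    mat01 = binary_site_matrix(ancestry, rng, n_mutations=n_mut)
    n = ancestry.n
    cols = np.sort(rng.choice(locus_length, size=n_mut, replace=False))
    grid = np.full((n, locus_length), "A", dtype="U1")
    for j, c in enumerate(cols):
        grid[mat01[:, j] == 1, c] = "T"
    if ids is None:
        ids = [f"p1_h{i+1:02d}" for i in range(ancestry.n1)] + [
            f"p2_h{i+1:02d}" for i in range(ancestry.n2)
        ]
    return HaplotypeAlignment(locus_name, list(ids), ["".join(row) for row in grid])


# ---------------------------------------------------------------------------
# multi-locus study designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocusDesign:
    name: str
    params: IMParameters
    colour: bool = False


@dataclass(frozen=True)
class StudyDesign:
    """A multi-locus sampling design: several weakly exchanging neutral
    loci plus one colour locus with elevated, strongly asymmetric
    migration from population 1 (the mimicry donor) into population 2."""

    loci: tuple[LocusDesign, ...]
    species1: str = "melpomene"
    species2: str = "timareta"

    def __post_init__(self) -> None:
        if not self.loci:
            raise InputError("design needs at least one locus")
        n1s = {l.params.n1 for l in self.loci}
        n2s = {l.params.n2 for l in self.loci}
        if len(n1s) != 1 or len(n2s) != 1:
            raise InputError("all loci must sample the same haplotype panel")
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise InputError("locus names must be unique")

    @property
    def colour_locus(self) -> LocusDesign:
        flagged = [l for l in self.loci if l.colour]
        if len(flagged) != 1:
            raise InputError("exactly one locus must be flagged as the colour locus")
        return flagged[0]


@dataclass
class SimulatedDataset:
    design: StudyDesign
    seed: int
    alignments: dict[str, HaplotypeAlignment]
    metadata: "pd.DataFrame"
    truth: dict[str, dict]


def default_study_design(
    n_per_pop: int = 20,
    locus_length: int = 500,
    theta: float = 20.0,
    t_split: float = 10.0,
    rho: float = 10.0,
    background_m: float = 0.01,
    colour_pulse_time: float = 0.1,
    colour_pulse_frac: float = 0.15,
    n_neutral: int = 8,
) -> StudyDesign:
    """The default 9-locus study design.

    Eight neutral loci exchange migrants weakly and symmetrically
    (2Nm = theta*m/2 = 0.1 each way at the defaults); the colour locus
    additionally carries a recent unidirectional adaptive-introgression
    event: at ``colour_pulse_time`` before the present, a fraction
    ``colour_pulse_frac`` of population 2's lineages trace to a single
    donor haplotype from population 1 (the selective-sweep approximation
    — mimicry selection drives one introgressed wing-pattern allele up
    in frequency, so the introgressed material is effectively
    single-origin).  Scales: theta=20 per 500-bp locus (0.04/site, the
    high nuclear diversity typical of Heliconius), one coalescent unit
    of divergence (t = theta/2), and rho = theta/2 — enough
    recombination that old shared polymorphisms decorrelate while the
    young introgressed block stays intact.
    """
    common = dict(
        theta1=theta,
        theta2=theta,
        thetaA=theta,
        t_split=t_split,
        n1=n_per_pop,
        n2=n_per_pop,
        locus_length=locus_length,
        rho=rho,
    )
    loci = [
        LocusDesign(f"neutral_{i+1}", IMParameters(m1=background_m, m2=background_m, **common))
        for i in range(n_neutral)
    ]
    loci.append(
        LocusDesign(
            "colour",
            IMParameters(
                m1=background_m,
                m2=background_m,
                pulse_time=colour_pulse_time,
                pulse2=colour_pulse_frac,
                pulse_sweep=True,
                **common,
            ),
            colour=True,
        )
    )
    return StudyDesign(tuple(loci))


def simulate_study(
    design: StudyDesign,
    seed: int,
    out_dir: "str | None" = None,
) -> SimulatedDataset:
    """Simulate a full multi-locus dataset with specimen metadata.

    The same haplotype panel is sampled at every locus.  Phenotypes
    follow colour-locus ancestry: population 1 is the red-banded donor
    (with a minority labelled rayed, mirroring within-species pattern
    diversity); a population-2 haplotype whose colour-locus sequence is
    closer to the population-1 pool than to its own is labelled
    red_banded (a donor-matched introgressed phenotype), otherwise
    non_red.  With ``out_dir`` set, writes one FASTA per locus, the
    metadata TSV, and a truth JSON of the generating parameters.
    """
    import json
    from pathlib import Path

    import pandas as pd

    from .seqdata import write_fasta_alignment

    rng = np.random.default_rng(seed)
    n1 = design.loci[0].params.n1
    n2 = design.loci[0].params.n2
    ids = [f"mel_h{i+1:02d}" for i in range(n1)] + [f"tim_h{i+1:02d}" for i in range(n2)]

    alignments: dict[str, HaplotypeAlignment] = {}
    truth: dict[str, dict] = {}
    for locus in design.loci:
        ancestry = simulate_ancestry(locus.params, rng)
        aln = drop_mutations_infinite_sites(
            ancestry, locus.params.locus_length, rng, ids=ids, locus_name=locus.name
        )
        alignments[locus.name] = aln
        truth[locus.name] = {
            "colour": locus.colour,
            **{k: getattr(locus.params, k) for k in (
                "theta1", "theta2", "thetaA", "t_split", "m1", "m2",
                "n1", "n2", "locus_length", "rho",
            )},
        }

    # Phenotypes mirror the mimicry classes: the donor species carries
    # both red-banded and rayed wing patterns (an arbitrary half/half
    # split — these markers carry no phenotype signal within the donor),
    # the recipient is non-red except where its colour-locus sequence is
    # closer to the donor pool than to its own (donor-matched
    # introgressed haplotypes, labelled rayed like their donors).
    colour_aln = alignments[design.colour_locus.name]
    mat = (colour_aln.matrix() == "T").astype(float)
    phenos = ["red_banded"] * (n1 // 2) + ["rayed"] * (n1 - n1 // 2)
    d11 = mat[:n1]
    d22 = mat[n1:]
    for i in range(n2):
        row = d22[i]
        to_donor = float(np.abs(d11 - row).sum(axis=1).mean())
        others = np.delete(d22, i, axis=0)
        to_own = float(np.abs(others - row).sum(axis=1).mean()) if len(others) else math.inf
        phenos.append("rayed" if to_donor < to_own else "non_red")

    half1, half2 = n1 // 2, n2 // 2
    meta = pd.DataFrame(
        {
            "species": [design.species1] * n1 + [design.species2] * n2,
            "race": ["aglaope"] * half1 + ["melpomene"] * (n1 - half1)
            + ["florencia"] * half2 + ["timareta"] * (n2 - half2),
            "phenotype": phenos,
            "region": ["amazon"] * half1 + ["guiana_shield"] * (n1 - half1)
            + ["east_andes_foothills"] * half2 + ["cauca_valley"] * (n2 - half2),
            "locality": ["Tarapoto"] * half1 + ["Cayenne"] * (n1 - half1)
            + ["Florencia"] * half2 + ["Cali"] * (n2 - half2),
        },
        index=pd.Index(ids, name="haplotype_id"),
    )

    dataset = SimulatedDataset(
        design=design, seed=seed, alignments=alignments, metadata=meta, truth=truth
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, aln in alignments.items():
            write_fasta_alignment(aln, out / f"{name}.fasta")
        meta.to_csv(out / "metadata.tsv", sep="\t")
        (out / "truth.json").write_text(json.dumps({"seed": seed, "loci": truth}, indent=2))
    return dataset


# ---------------------------------------------------------------------------
# summary statistics and unit conversions
# ---------------------------------------------------------------------------


def fst_summary(aln: HaplotypeAlignment, pop1: Sequence[str], pop2: Sequence[str]) -> float:
    """Hudson-style F_ST = 1 - pi_within / pi_between from mean pairwise
    differences (pi_within averages the two populations). NaN when the
    populations are identical everywhere (pi_between = 0)."""
    pop1, pop2 = list(pop1), list(pop2)
    if len(pop1) < 2 or len(pop2) < 2:
        raise InputError("both populations need >= 2 haplotypes")
    mat = aln.matrix()
    r1 = mat[aln.index_of(pop1)]
    r2 = mat[aln.index_of(pop2)]
    from .ldstats import _mean_pairwise_between, _mean_pairwise_within

    pi_b = _mean_pairwise_between(r1, r2)
    if pi_b == 0:
        return math.nan
    pi_w = 0.5 * (_mean_pairwise_within(r1) + _mean_pairwise_within(r2))
    return 1.0 - pi_w / pi_b


def convert_to_2Nm(params: IMParameters) -> tuple[float, float]:
    """Effective migrants received per generation, per direction:
    2 N_i m_i = theta_i * m_i / 2 under the IM scaling (theta = 4 N u,
    m = m/u)."""
    return params.theta1 * params.m1 / 2.0, params.theta2 * params.m2 / 2.0


def invert_2Nm(params: IMParameters, two_Nm: tuple[float, float]) -> tuple[float, float]:
    """Inverse of :func:`convert_to_2Nm`: recover (m1, m2)."""
    return 2.0 * two_Nm[0] / params.theta1, 2.0 * two_Nm[1] / params.theta2


def mu_from_divergence(
    d_xy: float,
    T_cal: float,
    generations_per_year: float = 10.0,
) -> tuple[float, float]:
    """Per-year and per-generation mutation rate from a divergence
    calibration: mu_year = d_xy / (2 T_cal) (divergence accrues on both
    branches), mu_gen = mu_year / generations_per_year."""
    if d_xy <= 0 or T_cal <= 0 or generations_per_year <= 0:
        raise InputError("d_xy, T_cal and generations_per_year must be > 0")
    mu_year = d_xy / (2.0 * T_cal)
    return mu_year, mu_year / generations_per_year
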