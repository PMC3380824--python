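"""Linkage disequilibrium and the shared-polymorphism gene-flow test.

The test statistic is, per species, x = D_SS - D_SX: the mean LD among
pairs of shared polymorphisms minus the mean LD among pairs of one
shared and one species-exclusive polymorphism.  Shared polymorphisms
introduced by recent gene flow are young and sit on a few migrant
haplotypes, so their rare alleles are coupled with one another and repel
the resident species' own variants; shared polymorphisms retained from
the ancestral species are old and have had time to recombine apart.  A
significantly positive x therefore indicates post-divergence gene flow,
and the species with the larger positive value is the recipient.
Significance comes from coalescent simulation of a strict-isolation
(zero migration) null fitted to the data.

LD is measured by Lewontin's D', computed within each species separately
and oriented on minor alleles; by default the sign is kept (coupling
positive), with magnitude-only averaging available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .seqdata import (
    HaplotypeAlignment,
    InputError,
    SiteClass,
    SiteClassification,
    classify_sites,
    maf_filter,
)

__all__ = [
    "LDPair",
    "GeneFlowResult",
    "ld_D_and_Dprime",
    "x_statistic",
    "geneflow_test",
    "infer_direction",
    "pairwise_ld_matrix",
]


@dataclass(frozen=True)
class LDPair:
    site_i: int
    site_j: int
    D: float
    D_prime: float
    pair_class: str

    @property
    def abs_D_prime(self) -> float:
        return abs(self.D_prime)


@dataclass
class GeneFlowResult:
    """Observed and (optionally) simulated gene-flow statistics for one locus.

    ``x`` values are NaN when the locus lacks shared or exclusive
    polymorphisms in that species; a NaN x yields a NaN p-value.
    """

    locus_name: str
    x_pop1: float
    x_pop2: float
    D_SS_mean_pop1: float
    D_SX_mean_pop1: float
    D_SS_mean_pop2: float
    D_SX_mean_pop2: float
    n_SS_pairs_pop1: int
    n_SX_pairs_pop1: int
    n_SS_pairs_pop2: int
    n_SX_pairs_pop2: int
    null_x_pop1: np.ndarray | None = None
    null_x_pop2: np.ndarray | None = None
    p_pop1: float = math.nan
    p_pop2: float = math.nan
    n_sims: int = 0

    @property
    def sim_mean_x_pop1(self) -> float:
        if self.null_x_pop1 is None:
            return math.nan
        vals = self.null_x_pop1[~np.isnan(self.null_x_pop1)]
        return float(vals.mean()) if vals.size else math.nan

    @property
    def sim_mean_x_pop2(self) -> float:
        if self.null_x_pop2 is None:
            return math.nan
        vals = self.null_x_pop2[~np.isnan(self.null_x_pop2)]
        return float(vals.mean()) if vals.size else math.nan


def _counts_to_freqs(alleles_i: Sequence[str], alleles_j: Sequence[str]):
    ai = np.asarray(alleles_i)
    aj = np.asarray(alleles_j)
    if ai.shape != aj.shape:
        raise InputError("allele vectors differ in length")
    ui, ci = np.unique(ai, return_counts=True)
    uj, cj = np.unique(aj, return_counts=True)
    if len(ui) != 2 or len(uj) != 2:
        raise InputError("both sites must be biallelic")
    # minor allele is the less frequent; ties break to the alphabetically
    # first base so results are deterministic
    minor_i = ui[np.lexsort((ui, ci))[0]]
    minor_j = uj[np.lexsort((uj, cj))[0]]
    n = ai.size
    p_a = float(np.mean(ai == minor_i))
    p_b = float(np.mean(aj == minor_j))
    p_ab = float(np.mean((ai == minor_i) & (aj == minor_j)))
    return p_a, p_b, p_ab


def ld_D_and_Dprime(alleles_i: Sequence[str], alleles_j: Sequence[str]) -> tuple[float, float]:
    """Gametic disequilibrium D and Lewontin's normalized D' between two
    biallelic sites, from paired haplotype alleles.

    D = p_AB - p_A p_B with A, B the minor alleles.  D' divides D by its
    frequency-constrained extreme, so D' lies in [-1, 1]; D' is defined
    as 0 when D = 0.
    """
    p_a, p_b, p_ab = _counts_to_freqs(alleles_i, alleles_j)
    d = p_ab - p_a * p_b
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    elif d < 0:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    else:
        return 0.0, 0.0
    return d, d / d_max


def _dprime_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Signed D' between every column of X and every column of Y.

    Columns are 0/1 indicator vectors (1 = minor allele) over the same
    haplotypes, so a positive entry means the rarer alleles at the two
    sites tend to ride on the same haplotypes.  Returns an
    (X.shape[1], Y.shape[1]) matrix.
    """
    n = X.shape[0]
    p_a = X.mean(axis=0)
    p_b = Y.mean(axis=0)
    p_ab = (X.T @ Y) / n
    D = p_ab - np.outer(p_a, p_b)
    dmax_pos = np.minimum(np.outer(p_a, 1 - p_b), np.outer(1 - p_a, p_b))
    dmax_neg = np.minimum(np.outer(p_a, p_b), np.outer(1 - p_a, 1 - p_b))
    dmax = np.where(D > 0, dmax_pos, dmax_neg)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(D == 0, 0.0, D / dmax)
    return out


def _abs_dprime_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """|D'| companion to :func:`_dprime_matrix`."""
    return np.abs(_dprime_matrix(X, Y))


def _minor_indicator(mat: np.ndarray) -> np.ndarray:
    """Encode each biallelic character column as a 0/1 minor-allele
    indicator (ties to the alphabetically first base)."""
    n, s = mat.shape
    out = np.empty((n, s), dtype=float)
    for j in range(s):
        col = mat[:, j]
        alleles, counts = np.unique(col, return_counts=True)
        if len(alleles) != 2:
            raise InputError(f"column {j} is not biallelic")
        minor = alleles[np.lexsort((alleles, counts))[0]]
        out[:, j] = col == minor
    return out


def _class_means(
    X_shared: np.ndarray, X_excl: np.ndarray, signed: bool
) -> tuple[float, float, int, int]:
    """Mean D' (signed or magnitude) over shared-shared and
    shared-exclusive column pairs."""
    s = X_shared.shape[1]
    e = X_excl.shape[1]
    n_ss = s * (s - 1) // 2
    n_sx = s * e
    d_ss = math.nan
    d_sx = math.nan
    fn = _dprime_matrix if signed else _abs_dprime_matrix
    if n_ss:
        m = fn(X_shared, X_shared)
        iu = np.triu_indices(s, k=1)
        d_ss = float(m[iu].mean())
    if n_sx:
        d_sx = float(fn(X_shared, X_excl).mean())
    return d_ss, d_sx, n_ss, n_sx


def _x_from_rows(rows: np.ndarray, shared_cols: np.ndarray, excl_cols: np.ndarray,
                 signed: bool = True):
    Xs = _minor_indicator(rows[:, shared_cols]) if shared_cols.size else np.empty((rows.shape[0], 0))
    Xe = _minor_indicator(rows[:, excl_cols]) if excl_cols.size else np.empty((rows.shape[0], 0))
    d_ss, d_sx, n_ss, n_sx = _class_means(Xs, Xe, signed)
    x = d_ss - d_sx if n_ss and n_sx else math.nan
    return x, d_ss, d_sx, n_ss, n_sx


def x_statistic(
    aln: HaplotypeAlignment,
    pop1: Iterable[str],
    pop2: Iterable[str],
    site_classes: Sequence[SiteClassification] | None = None,
    signed: bool = True,
) -> GeneFlowResult:
    """Observed x = D_SS - D_SX for each of two populations.

    For population p, D_SS averages D' over all pairs of shared
    polymorphisms and D_SX over all pairs of one shared and one
    p-exclusive polymorphism, with D' computed from p's haplotypes only
    and oriented on minor alleles.  By default D' keeps its sign —
    rare-allele coupling positive, repulsion negative — so x spans
    [-2, 2]; ``signed=False`` averages magnitudes |D'| instead.  x is
    NaN when either pair set is empty.
    """
    pop1 = list(pop1)
    pop2 = list(pop2)
    if site_classes is None:
        site_classes = classify_sites(aln, pop1, pop2)
    shared = np.array(
        [c.position for c in site_classes if c.klass is SiteClass.SHARED], dtype=int
    )
    ex1 = np.array(
        [c.position for c in site_classes if c.klass is SiteClass.EXCLUSIVE_POP1],
        dtype=int,
    )
    ex2 = np.array(
        [c.position for c in site_classes if c.klass is SiteClass.EXCLUSIVE_POP2],
        dtype=int,
    )
    mat = aln.matrix()
    rows1 = mat[aln.index_of(pop1)]
    rows2 = mat[aln.index_of(pop2)]
    x1, ss1, sx1, n_ss1, n_sx1 = _x_from_rows(rows1, shared, ex1, signed)
    x2, ss2, sx2, n_ss2, n_sx2 = _x_from_rows(rows2, shared, ex2, signed)
    return GeneFlowResult(
        locus_name=aln.locus_name,
        x_pop1=x1,
        x_pop2=x2,
        D_SS_mean_pop1=ss1,
        D_SX_mean_pop1=sx1,
        D_SS_mean_pop2=ss2,
        D_SX_mean_pop2=sx2,
        n_SS_pairs_pop1=n_ss1,
        n_SX_pairs_pop1=n_sx1,
        n_SS_pairs_pop2=n_ss2,
        n_SX_pairs_pop2=n_sx2,
    )


def _minor01(rows: np.ndarray) -> np.ndarray:
    """Flip 0/1 columns so 1 marks the minor allele (ties keep 1)."""
    f = rows.mean(axis=0)
    return np.where(f > 0.5, 1 - rows, rows).astype(float)


def _x_binary_onepop(rows: np.ndarray, shared: np.ndarray, excl: np.ndarray,
                     signed: bool = True) -> float:
    s, e = shared.size, excl.size
    if s * (s - 1) // 2 == 0 or s * e == 0:
        return math.nan
    Xs = _minor01(rows[:, shared])
    Xe = _minor01(rows[:, excl])
    fn = _dprime_matrix if signed else _abs_dprime_matrix
    m = fn(Xs, Xs)
    iu = np.triu_indices(s, k=1)
    d_ss = float(m[iu].mean())
    d_sx = float(fn(Xs, Xe).mean())
    return d_ss - d_sx


def x_from_binary(mat01: np.ndarray, n1: int, signed: bool = True) -> tuple[float, float]:
    """x for both populations from a 0/1 haplotype-by-site matrix
    (rows 0..n1-1 are population 1). Used on simulated infinite-sites data
    where every column is biallelic and gap-free."""
    rows1 = mat01[:n1]
    rows2 = mat01[n1:]
    f1 = rows1.mean(axis=0)
    f2 = rows2.mean(axis=0)
    seg1 = (f1 > 0) & (f1 < 1)
    seg2 = (f2 > 0) & (f2 < 1)
    shared = np.where(seg1 & seg2)[0]
    ex1 = np.where(seg1 & ~seg2)[0]
    ex2 = np.where(seg2 & ~seg1)[0]
    x1 = _x_binary_onepop(rows1, shared, ex1, signed)
    x2 = _x_binary_onepop(rows2, shared, ex2, signed)
    return x1, x2


def geneflow_test(
    aln: HaplotypeAlignment,
    pop1: Iterable[str],
    pop2: Iterable[str],
    n_sims: int = 30_000,
    seed: int | None = None,
    recombination_rate: float = 0.0,
    null_params: "coalsim.IMParameters | None" = None,
    signed: bool = True,
    null_conditioning: str = "class_counts",
) -> GeneFlowResult:
    """Gene-flow test: observed x compared against a zero-migration
    isolation null simulated by coalescent.

    Null parameters are fitted from the data unless ``null_params``
    supplies them (e.g. a multilocus background estimate): per-population
    theta by Watterson's estimator, ancestral theta as their mean, and
    the mutation-scaled split time from net between-population divergence
    (d_a = d_xy - (pi1 + pi2)/2, with t = d_a / 2 since d_a has
    expectation 2 t under isolation).  ``recombination_rate`` (rho, same
    mutation scaling) enters the fitted null; it defaults to 0, the
    conservative choice for non-recombining blocks, but should match the
    locus when recombination is believed present — with no recombination
    at all every site pair is tree-compatible and |D'| degenerates to 1.
    Each replicate matches the sample sizes and the observed
    segregating-site count (mutations are placed conditional on that
    count).  p-values are upper-tail with the add-one rule,
    p = (1 + #{x_sim >= x_obs}) / (n_sims + 1), so p is never 0.
    """
    from . import coalsim  # deferred: coalsim imports nothing from here

    if n_sims < 1:
        raise InputError("n_sims must be >= 1")
    if recombination_rate < 0:
        raise InputError("recombination_rate must be >= 0")
    pop1 = list(pop1)
    pop2 = list(pop2)
    classes = classify_sites(aln, pop1, pop2)
    result = x_statistic(aln, pop1, pop2, site_classes=classes, signed=signed)
    result.n_sims = n_sims

    n1, n2 = len(pop1), len(pop2)
    counts = {k: 0 for k in SiteClass}
    for c in classes:
        counts[c.klass] += 1
    s_obs = (
        counts[SiteClass.SHARED]
        + counts[SiteClass.EXCLUSIVE_POP1]
        + counts[SiteClass.EXCLUSIVE_POP2]
        + counts[SiteClass.FIXED_DIFFERENCE]
    )
    if s_obs == 0 or (math.isnan(result.x_pop1) and math.isnan(result.x_pop2)):
        return result

    a1 = sum(1.0 / k for k in range(1, n1))
    a2 = sum(1.0 / k for k in range(1, n2))
    theta1 = max((counts[SiteClass.SHARED] + counts[SiteClass.EXCLUSIVE_POP1]) / a1, 1e-8)
    theta2 = max((counts[SiteClass.SHARED] + counts[SiteClass.EXCLUSIVE_POP2]) / a2, 1e-8)
    theta_a = 0.5 * (theta1 + theta2)

    mat = aln.matrix()
    rows1 = mat[aln.index_of(pop1)]
    rows2 = mat[aln.index_of(pop2)]
    ok_cols = np.array([c.klass is not SiteClass.EXCLUDED for c in classes])
    d_xy = _mean_pairwise_between(rows1[:, ok_cols], rows2[:, ok_cols])
    pi1 = _mean_pairwise_within(rows1[:, ok_cols])
    pi2 = _mean_pairwise_within(rows2[:, ok_cols])
    d_a = max(d_xy - 0.5 * (pi1 + pi2), 0.0)
    t_split = d_a / 2.0

    if null_params is None:
        null_params = coalsim.IMParameters(
            theta1=theta1,
            theta2=theta2,
            thetaA=theta_a,
            t_split=t_split,
            m1=0.0,
            m2=0.0,
            n1=n1,
            n2=n2,
            locus_length=aln.length,
            rho=recombination_rate,
        )
    # fixed differences never enter x (no pair class uses them), so the
    # null is conditioned on the polymorphic classes only
    class_counts = {
        "shared": counts[SiteClass.SHARED],
        "excl1": counts[SiteClass.EXCLUSIVE_POP1],
        "excl2": counts[SiteClass.EXCLUSIVE_POP2],
    }
    rng = np.random.default_rng(seed)
    null1 = np.full(n_sims, math.nan)
    null2 = np.full(n_sims, math.nan)
    if null_conditioning not in {"class_counts", "total_sites", "poisson"}:
        raise InputError(f"unknown null_conditioning {null_conditioning!r}")
    recombining = null_params.rho > 0
    max_tries = 100
    for i in range(n_sims):
        # conditional null: resample genealogies until one can carry the
        # observed site-class counts, then place mutations class by class
        for _ in range(max_tries):
            if recombining:
                ancestry = coalsim.simulate_ancestry(null_params, rng)
            else:
                ancestry = coalsim.simulate_genealogy(null_params, rng)
            if null_conditioning == "class_counts":
                mat01 = coalsim.conditional_site_matrix(ancestry, n1, class_counts, rng)
            elif null_conditioning == "total_sites":
                mat01 = coalsim.binary_site_matrix(ancestry, rng, n_mutations=s_obs)
            else:
                mat01 = coalsim.binary_site_matrix(ancestry, rng)
            if mat01 is not None:
                null1[i], null2[i] = x_from_binary(mat01, n1, signed)
                break
    result.null_x_pop1 = null1
    result.null_x_pop2 = null2
    result.p_pop1 = _upper_tail_p(result.x_pop1, null1, n_sims)
    result.p_pop2 = _upper_tail_p(result.x_pop2, null2, n_sims)
    return result


def _upper_tail_p(x_obs: float, null: np.ndarray, n_sims: int) -> float:
    if math.isnan(x_obs):
        return math.nan
    # p is computed over replicates where the simulated x is defined
    # (a locus with no shared or exclusive polymorphisms has no x)
    defined = null[~np.isnan(null)]
    if defined.size == 0:
        return math.nan
    exceed = int(np.sum(defined >= x_obs))
    return (1 + exceed) / (defined.size + 1)


def _mean_pairwise_within(rows: np.ndarray) -> float:
    n = rows.shape[0]
    if n < 2:
        return 0.0
    total = 0
    for i in range(n - 1):
        total += int(np.sum(rows[i + 1 :] != rows[i]))
    return total / (n * (n - 1) / 2)


def _mean_pairwise_between(rows1: np.ndarray, rows2: np.ndarray) -> float:
    total = 0
    for i in range(rows1.shape[0]):
        total += int(np.sum(rows2 != rows1[i]))
    return total / (rows1.shape[0] * rows2.shape[0])


def infer_direction(
    result: GeneFlowResult,
    alpha: float = 0.05,
    labels: tuple[str, str] = ("pop1", "pop2"),
) -> str:
    """Name the recipient population: the one with the larger positive,
    significant x.  Returns ``"undetermined"`` when neither qualifies or
    the two are exactly tied."""
    x1, x2 = result.x_pop1, result.x_pop2
    if math.isnan(x1) and math.isnan(x2):
        raise InputError("both x values are NA; direction is undefined")
    sig1 = (not math.isnan(x1)) and x1 > 0 and result.p_pop1 < alpha
    sig2 = (not math.isnan(x2)) and x2 > 0 and result.p_pop2 < alpha
    if sig1 and sig2:
        if x1 > x2:
            return labels[0]
        if x2 > x1:
            return labels[1]
        return "undetermined"
    if sig1:
        return labels[0]
    if sig2:
        return labels[1]
    return "undetermined"


def pairwise_ld_matrix(
    aln: HaplotypeAlignment,
    maf: float = 0.05,
) -> tuple[np.ndarray, list[int]]:
    """Symmetric |D'| matrix over all biallelic sites passing the
    minor-allele-frequency filter, computed across all haplotypes.

    Returns the matrix and the retained 0-based site indices.  Haplotypes
    with a gap or N at either site of a pair are dropped for that pair;
    a pair left monomorphic by that is NaN.
    """
    sites = maf_filter(aln, maf)
    if len(sites) < 2:
        raise InputError(
            f"need >=2 sites passing the {maf:.0%} frequency filter, got {len(sites)}"
        )
    return _ld_matrix_over_sites(aln, sites)


def _ld_matrix_over_sites(aln: HaplotypeAlignment, sites: list[int]):
    mat = aln.matrix()[:, sites]
    s = len(sites)
    out = np.eye(s)
    for i in range(s):
        for j in range(i + 1, s):
            keep = np.isin(mat[:, i], list("ACGT")) & np.isin(mat[:, j], list("ACGT"))
            ci, cj = mat[keep, i], mat[keep, j]
            if len(set(ci)) != 2 or len(set(cj)) != 2:
                val = math.nan
            else:
                _, dp = ld_D_and_Dprime(ci, cj)
                val = abs(dp)
            out[i, j] = out[j, i] = val
    return out, sites


def write_ld_matrix_tsv(
    matrix: np.ndarray,
    sites: Sequence[int],
    path,
) -> None:
    """Export a pairwise |D'| matrix as TSV (1-based site positions as
    row/column labels) — the input format for heatmap rendering."""
    import pandas as pd

    labels = [s + 1 for s in sites]
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(
        path, sep="\t", index_label="position"
    )
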