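"""One-factor analysis of molecular variance (AMOVA) with permutation tests.

Partitions haplotype-level molecular variance into among-group and
within-group components from a matrix of pairwise nucleotide differences
(used as squared Euclidean distances, the standard convention for
haplotypic data), and attaches a permutation p-value to Phi_ST.  Run
independently for phenotype, species and geography groupings, this
reproduces the familiar "percentage of variation explained by" table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .seqdata import HaplotypeAlignment, InputError

__all__ = [
    "AmovaResult",
    "pairwise_difference_matrix",
    "amova_oneway",
    "amova_permutation_test",
]


@dataclass
class AmovaResult:
    factor: str
    sigma2_among: float
    sigma2_within: float
    phi_st: float
    p_perm: float = math.nan
    n_perm: int = 0

    @property
    def pct_among(self) -> float:
        """Percentage of molecular variance among groups. May be negative
        when the among-group component estimate is negative (no
        truncation is applied)."""
        return 100.0 * self.phi_st


def pairwise_difference_matrix(aln: HaplotypeAlignment) -> np.ndarray:
    """Number of columns at which each haplotype pair carries different
    unambiguous bases (positions where either has a gap or N are skipped
    for that pair)."""
    mat = aln.matrix()
    ok = np.isin(mat, list("ACGT"))
    n = aln.n_haplotypes
    out = np.zeros((n, n), dtype=int)
    for i in range(n - 1):
        both = ok[i] & ok[i + 1 :]
        diff = (mat[i] != mat[i + 1 :]) & both
        counts = diff.sum(axis=1)
        out[i, i + 1 :] = counts
        out[i + 1 :, i] = counts
    return out


def _group_vector(ids: Sequence[str], groups: Mapping[str, str], exclude: set[str]):
    labels = []
    keep = []
    for i, hid in enumerate(ids):
        g = groups.get(hid)
        if g is None:
            raise InputError(f"no group assignment for haplotype {hid!r}")
        if g in exclude:
            continue
        labels.append(g)
        keep.append(i)
    return np.asarray(labels), np.asarray(keep, dtype=int)


def _phi_from_labels(dist: np.ndarray, labels: np.ndarray):
    """Excoffier-style one-level decomposition from squared distances."""
    n = len(labels)
    uniq, inv = np.unique(labels, return_inverse=True)
    g = len(uniq)
    if g < 2:
        raise InputError("AMOVA needs at least two groups")
    iu = np.triu_indices(n, k=1)
    ssd_total = dist[iu].sum() / n
    ssd_within = 0.0
    sizes = np.zeros(g)
    for k in range(g):
        members = np.where(inv == k)[0]
        sizes[k] = len(members)
        if len(members) > 1:
            sub = dist[np.ix_(members, members)]
            ssd_within += sub[np.triu_indices(len(members), k=1)].sum() / len(members)
    ssd_among = ssd_total - ssd_within
    df_within = n - g
    if df_within == 0:
        raise InputError("every group has a single member; within variance undefined")
    sigma_w = ssd_within / df_within
    n_c = (n - (sizes**2).sum() / n) / (g - 1)
    sigma_a = (ssd_among / (g - 1) - sigma_w) / n_c
    denom = sigma_a + sigma_w
    phi = sigma_a / denom if denom != 0 else math.nan
    return sigma_a, sigma_w, phi


def amova_oneway(
    dist: np.ndarray,
    ids: Sequence[str],
    groups: Mapping[str, str],
    factor: str = "group",
    exclude_groups: Sequence[str] = (),
) -> AmovaResult:
    """Variance components and Phi_ST for one grouping factor.

    ``dist`` holds pairwise nucleotide differences in the order of
    ``ids``; ``groups`` maps haplotype id to its group label.  Groups in
    ``exclude_groups`` (typically the outgroup) are dropped before the
    decomposition.  The among-group component may be negative; it is
    reported as computed.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (len(ids), len(ids)):
        raise InputError("distance matrix does not match ids")
    labels, keep = _group_vector(ids, groups, set(exclude_groups))
    sub = dist[np.ix_(keep, keep)]
    sigma_a, sigma_w, phi = _phi_from_labels(sub, labels)
    return AmovaResult(factor=factor, sigma2_among=sigma_a, sigma2_within=sigma_w, phi_st=phi)


def amova_permutation_test(
    dist: np.ndarray,
    ids: Sequence[str],
    groups: Mapping[str, str],
    n_perm: int = 1000,
    seed: int | None = None,
    factor: str = "group",
    exclude_groups: Sequence[str] = (),
) -> AmovaResult:
    """AMOVA with significance from whole-haplotype label permutation:
    p = (1 + #{Phi_perm >= Phi_obs}) / (n_perm + 1)."""
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    dist = np.asarray(dist, dtype=float)
    labels, keep = _group_vector(ids, groups, set(exclude_groups))
    sub = dist[np.ix_(keep, keep)]
    sigma_a, sigma_w, phi_obs = _phi_from_labels(sub, labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    perm = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        _, _, phi = _phi_from_labels(sub, perm)
        if phi >= phi_obs:
            exceed += 1
    return AmovaResult(
        factor=factor,
        sigma2_among=sigma_a,
        sigma2_within=sigma_w,
        phi_st=phi_obs,
        p_perm=(1 + exceed) / (n_perm + 1),
        n_perm=n_perm,
    )
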