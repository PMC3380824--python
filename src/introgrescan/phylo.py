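"""Genealogy reconstruction and topology testing.

Neighbour-joining on uncorrected p-distance with nonparametric bootstrap
support; Felsenstein-pruning log-likelihood under GTR+I+Gamma evaluated
on fixed topologies with per-branch length optimization; and the
Shimodaira-Hasegawa test, which asks whether alternative genealogical
hypotheses (for wing-pattern loci: a species tree, independent
convergence, or ancestral polymorphism) are significantly worse than the
best tree, using RELL resampling of per-site log-likelihoods.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .seqdata import HaplotypeAlignment, InputError

__all__ = [
    "SubstitutionModel",
    "SHTestResult",
    "p_distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "tree_loglikelihood",
    "optimize_branch_lengths",
    "sh_test",
    "simulate_alignment",
    "nj_tree",
    "tree_from_newick",
    "tree_to_newick",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


# ---------------------------------------------------------------------------
# distances and neighbour joining
# ---------------------------------------------------------------------------


def p_distance_matrix(aln: HaplotypeAlignment) -> np.ndarray:
    """Uncorrected p-distance: mismatches over compared columns, with
    pairwise deletion of columns where either sequence has a gap or N.
    Errors if some pair shares no comparable column."""
    mat = aln.matrix()
    ok = np.isin(mat, list(_BASES))
    n = aln.n_haplotypes
    out = np.zeros((n, n))
    for i in range(n - 1):
        both = ok[i] & ok[i + 1 :]
        comp = both.sum(axis=1)
        for off, c in enumerate(comp):
            if c == 0:
                raise InputError(
                    f"no comparable columns between {aln.ids[i]!r} and "
                    f"{aln.ids[i + 1 + off]!r}"
                )
        diff = ((mat[i] != mat[i + 1 :]) & both).sum(axis=1)
        out[i, i + 1 :] = diff / comp
        out[i + 1 :, i] = out[i, i + 1 :]
    return out


def _new_leaf(taxon_namespace, label):
    node = dendropy.Node()
    node.taxon = taxon_namespace.require_taxon(label=label)
    return node


def _clamp(va: float, vb: float) -> tuple[float, float]:
    # negative estimate set to 0, deficit moved to the sister branch so
    # the path length between the two children is preserved
    if va < 0:
        vb = max(vb + va, 0.0)
        va = 0.0
    if vb < 0:
        va = max(va + vb, 0.0)
        vb = 0.0
    return va, vb


def neighbor_joining(dist: np.ndarray, ids: list[str]) -> dendropy.Tree:
    """Saitou-Nei neighbour joining.

    Ties in the Q criterion break to the smallest (row, column) index
    pair, so the output is deterministic.  Negative branch-length
    estimates are clamped to zero with the deficit transferred to the
    sister branch.  Returns an unrooted tree (trifurcating root node).
    """
    D = np.array(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise InputError("distance matrix must be square")
    if D.shape[0] != len(ids):
        raise InputError("distance matrix does not match ids")
    if not np.allclose(D, D.T):
        raise InputError("distance matrix must be symmetric")
    r = D.shape[0]
    if r < 3:
        raise InputError("neighbour joining needs at least 3 taxa")

    tns = dendropy.TaxonNamespace()
    nodes = [_new_leaf(tns, label) for label in ids]

    while r > 3:
        R = D.sum(axis=1)
        Q = (r - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # row-major argmin = smallest (i, j) tie-break
        i, j = divmod(flat, r)
        if i > j:
            i, j = j, i
        vi = 0.5 * D[i, j] + (R[i] - R[j]) / (2 * (r - 2))
        vj = D[i, j] - vi
        vi, vj = _clamp(vi, vj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = vi
        nodes[j].edge.length = vj
        new_row = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], new_row[keep]])
        D = np.hstack([D, np.append(new_row[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
        r -= 1

    # final three-way join with three-point formulas
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    center = dendropy.Node()
    lengths = [
        (d01 + d02 - d12) / 2.0,
        (d01 + d12 - d02) / 2.0,
        (d02 + d12 - d01) / 2.0,
    ]
    for node, length in zip(nodes, lengths):
        center.add_child(node)
        node.edge.length = max(length, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


def nj_tree(aln: HaplotypeAlignment) -> dendropy.Tree:
    """Neighbour-joining tree from uncorrected p-distances."""
    return neighbor_joining(p_distance_matrix(aln), list(aln.ids))


# ---------------------------------------------------------------------------
# bipartitions and bootstrap
# ---------------------------------------------------------------------------


def _bipartitions(tree: dendropy.Tree) -> dict[frozenset, dendropy.Node]:
    """Non-trivial bipartitions as frozensets of taxon labels, normalized
    to the side not containing the first taxon in the namespace."""
    all_labels = frozenset(t.label for t in tree.taxon_namespace)
    ref = min(all_labels)
    out: dict[frozenset, dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if ref in side:
            side = all_labels - side
        if len(side) > 1 and len(all_labels) - len(side) > 1:
            out[side] = node
    return out


def bootstrap_support(
    aln: HaplotypeAlignment,
    n_reps: int = 1000,
    seed: int | None = None,
) -> dendropy.Tree:
    """NJ tree with bootstrap support on internal nodes.

    Columns are resampled with replacement ``n_reps`` times, an NJ tree
    is rebuilt from each pseudo-alignment, and support is the percentage
    of replicates whose tree contains each bipartition of the
    point-estimate tree (stored in ``node.label``)."""
    if n_reps < 1:
        raise InputError("n_reps must be >= 1")
    tree = nj_tree(aln)
    target = _bipartitions(tree)
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    mat = aln.matrix()
    for _ in range(n_reps):
        cols = rng.integers(0, aln.length, size=aln.length)
        boot = HaplotypeAlignment(
            aln.locus_name, list(aln.ids), ["".join(row) for row in mat[:, cols]]
        )
        seen = set(_bipartitions(nj_tree(boot)))
        for bp in counts:
            if bp in seen:
                counts[bp] += 1
    for bp, node in target.items():
        node.label = f"{100.0 * counts[bp] / n_reps:g}"
    return tree


# ---------------------------------------------------------------------------
# substitution model and pruning likelihood
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubstitutionModel:
    """GTR+I+Gamma: six exchangeabilities (AC, AG, AT, CG, CT, GT), base
    frequencies, a proportion of invariant sites and a discrete-Gamma
    rate distribution (mean-of-quantile discretization)."""

    exchangeabilities: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    base_frequencies: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    p_inv: float = 0.0
    alpha: float = math.inf  # inf = rate homogeneity
    n_categories: int = 4

    def __post_init__(self) -> None:
        if len(self.exchangeabilities) != 6 or min(self.exchangeabilities) <= 0:
            raise InputError("need 6 positive exchangeabilities")
        f = np.asarray(self.base_frequencies, dtype=float)
        if len(f) != 4 or f.min() <= 0 or abs(f.sum() - 1) > 1e-8:
            raise InputError("base frequencies must be 4 positive values summing to 1")
        if not 0 <= self.p_inv < 1:
            raise InputError("p_inv must be in [0, 1)")
        if not self.alpha > 0:
            raise InputError("gamma shape alpha must be > 0")
        if self.n_categories < 1:
            raise InputError("n_categories must be >= 1")

    @classmethod
    def jc(cls, p_inv: float = 0.0, alpha: float = math.inf) -> "SubstitutionModel":
        """Jukes-Cantor special case: equal rates and frequencies."""
        return cls(p_inv=p_inv, alpha=alpha)

    def rate_matrix(self) -> np.ndarray:
        """GTR rate matrix scaled to mean rate 1 over variable sites."""
        s = np.zeros((4, 4))
        ac, ag, at, cg, ct, gt = self.exchangeabilities
        s[0, 1] = s[1, 0] = ac
        s[0, 2] = s[2, 0] = ag
        s[0, 3] = s[3, 0] = at
        s[1, 2] = s[2, 1] = cg
        s[1, 3] = s[3, 1] = ct
        s[2, 3] = s[3, 2] = gt
        pi = np.asarray(self.base_frequencies)
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -float(np.dot(pi, np.diag(q)))
        return q / mu

    def gamma_rates(self) -> np.ndarray:
        """Category rates (mean of each quantile interval); mean 1."""
        if not math.isfinite(self.alpha) or self.n_categories == 1:
            return np.ones(1)
        k = self.n_categories
        a = self.alpha
        bounds = stats.gamma.ppf(np.arange(k + 1) / k, a=a, scale=1.0 / a)
        upper = stats.gamma.cdf(bounds, a=a + 1, scale=1.0 / a)
        return k * np.diff(upper)

    def _eig(self):
        pi = np.asarray(self.base_frequencies)
        q = self.rate_matrix()
        sq = np.sqrt(pi)
        b = (sq[:, None] * q) / sq[None, :]
        w, u = np.linalg.eigh((b + b.T) / 2.0)
        return w, u, sq

    def transition_matrices(self, t: float) -> np.ndarray:
        """P(t r_c) for each gamma category: (n_categories, 4, 4)."""
        w, u, sq = self._eig()
        rates = self.gamma_rates()
        out = np.empty((len(rates), 4, 4))
        for c, r in enumerate(rates):
            if t * r == 0.0:
                out[c] = np.eye(4)
                continue
            e = u @ np.diag(np.exp(w * t * r)) @ u.T
            p = (e / sq[:, None]) * sq[None, :]
            out[c] = np.clip(p, 0.0, None)
        return out


def _encode_alignment(aln: HaplotypeAlignment):
    """Unique site patterns: (patterns array n x P with -1 = missing,
    counts, inverse map pattern->original sites)."""
    mat = aln.matrix()
    codes = np.full(mat.shape, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        codes[mat == b] = i
    patterns, inverse, counts = np.unique(
        codes.T, axis=0, return_inverse=True, return_counts=True
    )
    return patterns.T, counts, inverse


def tree_loglikelihood(
    aln: HaplotypeAlignment,
    tree: dendropy.Tree,
    model: SubstitutionModel,
) -> tuple[float, np.ndarray]:
    """Felsenstein pruning log-likelihood of an alignment on a fixed tree.

    Site likelihood = p_inv * [site constant] * pi(base)
    + (1 - p_inv) * mean over gamma categories of the pruning likelihood.
    Gaps and N are missing data.  Returns the total lnL and the per-site
    lnL vector (which sums to the total); sites with zero probability
    give -inf.
    """
    leaf_row = {}
    labels = {t.label for t in tree.taxon_namespace if t.label is not None}
    if labels != set(aln.ids):
        raise InputError("tree leaf set does not match alignment ids")
    for i, hid in enumerate(aln.ids):
        leaf_row[hid] = i
    patterns, counts, inverse = _encode_alignment(aln)
    n_pat = patterns.shape[1]
    rates = model.gamma_rates()
    k = len(rates)
    pi = np.asarray(model.base_frequencies)
    w, u, sq = model._eig()

    def pmat(t: float) -> np.ndarray:
        out = np.empty((k, 4, 4))
        for c, r in enumerate(rates):
            if t * r == 0.0:
                out[c] = np.eye(4)
                continue
            e = u @ np.diag(np.exp(w * t * r)) @ u.T
            out[c] = np.clip((e / sq[:, None]) * sq[None, :], 0.0, None)
        return out

    partial: dict[int, np.ndarray] = {}
    logscale = np.zeros((k, n_pat))
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            row = leaf_row[node.taxon.label]
            p = np.zeros((k, n_pat, 4))
            codes = patterns[row]
            miss = codes < 0
            p[:, miss, :] = 1.0
            obs = np.where(~miss)[0]
            p[:, obs, codes[obs]] = 1.0
            partial[id(node)] = p
        else:
            acc = np.ones((k, n_pat, 4))
            for child in node.child_nodes():
                t = child.edge.length if child.edge.length is not None else 0.0
                P = pmat(max(t, 0.0))
                acc = acc * np.einsum("cab,cpb->cpa", P, partial.pop(id(child)))
            # rescale to dodge underflow on large trees
            mx = acc.max(axis=2)
            safe = mx > 0
            scaled = np.where(safe[:, :, None], acc / np.where(safe, mx, 1.0)[:, :, None], acc)
            logscale += np.where(safe, np.log(np.where(safe, mx, 1.0)), -np.inf)
            partial[id(node)] = scaled

    root = partial[id(tree.seed_node)]
    with np.errstate(divide="ignore"):
        log_var = np.log(np.einsum("cpa,a->cp", root, pi))
    log_var = log_var + logscale
    # mean over gamma categories in log space
    log_mean_var = logsumexp(log_var, axis=0) - math.log(k)

    # invariant-site component
    inv_lik = np.zeros(n_pat)
    for p_idx in range(n_pat):
        col = patterns[:, p_idx]
        obs = col[col >= 0]
        if obs.size == 0:
            inv_lik[p_idx] = 1.0
        elif np.all(obs == obs[0]):
            inv_lik[p_idx] = pi[obs[0]]

    with np.errstate(divide="ignore"):
        if model.p_inv > 0:
            site_log = np.logaddexp(
                np.log(model.p_inv * inv_lik),
                math.log1p(-model.p_inv) + log_mean_var,
            )
        else:
            site_log = log_mean_var
    per_site = site_log[inverse]
    total = float(np.dot(site_log, counts))
    if not np.all(np.isfinite(per_site)):
        warnings.warn("zero-probability site pattern: lnL is -inf", stacklevel=2)
    return total, per_site


def optimize_branch_lengths(
    aln: HaplotypeAlignment,
    tree: dendropy.Tree,
    model: SubstitutionModel,
    tol: float = 1e-6,
    max_cycles: int = 20,
    max_branch_length: float = 20.0,
) -> dendropy.Tree:
    """Maximize lnL over branch lengths on a fixed topology by cycling
    coordinate-wise univariate optimization until the improvement per
    cycle drops below ``tol``.  lnL is non-decreasing across cycles."""
    tree = tree.clone(depth=1)
    edges = [
        node for node in tree.preorder_node_iter() if node.parent_node is not None
    ]
    for node in edges:
        if node.edge.length is None or node.edge.length < 0:
            node.edge.length = 0.01
    best, _ = tree_loglikelihood(aln, tree, model)
    for _ in range(max_cycles):
        for node in edges:
            current = node.edge.length

            def neg(t: float, node=node) -> float:
                node.edge.length = t
                val, _ = tree_loglikelihood(aln, tree, model)
                return -val

            res = minimize_scalar(
                neg, bounds=(1e-9, max_branch_length), method="bounded",
                options={"xatol": 1e-8},
            )
            if -res.fun >= best:
                node.edge.length = float(res.x)
                best = -res.fun
            else:
                node.edge.length = current
        new, _ = tree_loglikelihood(aln, tree, model)
        if new - best < tol and new >= best - 1e-12:
            best = max(best, new)
            break
        best = max(best, new)
    else:
        warnings.warn(
            "branch-length optimization did not converge; returning best so far",
            stacklevel=2,
        )
    return tree


def simulate_alignment(
    tree: dendropy.Tree,
    model: SubstitutionModel,
    n_sites: int,
    rng: np.random.Generator,
    locus_name: str = "simulated",
) -> HaplotypeAlignment:
    """Evolve sequences along a fixed tree under the substitution model.

    Root states are drawn from the stationary frequencies; each branch
    applies its transition matrix (rate category drawn per site).  Used
    for likelihood validation and topology-test calibration.
    """
    rates = model.gamma_rates()
    k = len(rates)
    cat = rng.integers(0, k, size=n_sites)
    if model.p_inv > 0:
        invariant = rng.random(n_sites) < model.p_inv
    else:
        invariant = np.zeros(n_sites, dtype=bool)
    pi = np.asarray(model.base_frequencies)
    states: dict[int, np.ndarray] = {
        id(tree.seed_node): rng.choice(4, size=n_sites, p=pi)
    }
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = node.edge.length or 0.0
        P = model.transition_matrices(t)  # (k, 4, 4)
        parent = states[id(node.parent_node)]
        child = parent.copy()
        vary = ~invariant
        u = rng.random(n_sites)
        cum = np.cumsum(P[cat, parent, :], axis=1)
        child_all = (u[:, None] < cum).argmax(axis=1)
        child[vary] = child_all[vary]
        states[id(node)] = child
    bases = np.array(list(_BASES))
    seqs = {}
    for leaf in tree.leaf_node_iter():
        seqs[leaf.taxon.label] = "".join(bases[states[id(leaf)]])
    ids = sorted(seqs)
    return HaplotypeAlignment(locus_name, ids, [seqs[i] for i in ids])


# ---------------------------------------------------------------------------
# Shimodaira-Hasegawa test
# ---------------------------------------------------------------------------


@dataclass
class SHTestResult:
    log_likelihoods: np.ndarray
    per_site: np.ndarray  # (n_topologies, n_sites)
    deltas: np.ndarray
    p_values: np.ndarray
    n_resamples: int
    best_index: int
    trees: list = field(default_factory=list)


def sh_test(
    aln: HaplotypeAlignment,
    topologies: list[dendropy.Tree],
    model: SubstitutionModel,
    n_resamples: int = 1000,
    seed: int | None = None,
    optimize: bool = True,
) -> SHTestResult:
    """Shimodaira-Hasegawa topology test with RELL resampling.

    Branch lengths are optimized per topology (unless ``optimize`` is
    False), per-site lnL vectors are bootstrap-resampled, each topology's
    resampled totals are centered by their own mean, and
    p_i = Pr(max_j centered_j - centered_i >= lnL_best - lnL_i) with the
    add-one rule.  The best topology always gets p = 1.
    """
    if len(topologies) < 2:
        raise InputError("SH test needs at least two topologies")
    if n_resamples < 1:
        raise InputError("n_resamples must be >= 1")
    trees = []
    per_site = []
    for top in topologies:
        fitted = optimize_branch_lengths(aln, top, model) if optimize else top
        _, vec = tree_loglikelihood(aln, fitted, model)
        trees.append(fitted)
        per_site.append(vec)
    M = np.vstack(per_site)  # (T, n_sites)
    totals = M.sum(axis=1)
    best = int(np.argmax(totals))
    deltas = totals[best] - totals

    rng = np.random.default_rng(seed)
    n_sites = M.shape[1]
    counts = rng.multinomial(n_sites, np.full(n_sites, 1.0 / n_sites), size=n_resamples)
    boot = counts @ M.T  # (B, T)
    centered = boot - boot.mean(axis=0, keepdims=True)
    dstar = centered.max(axis=1, keepdims=True) - centered  # (B, T)
    exceed = (dstar >= deltas[None, :]).sum(axis=0)
    p = (1 + exceed) / (n_resamples + 1)
    return SHTestResult(
        log_likelihoods=totals,
        per_site=M,
        deltas=deltas,
        p_values=p,
        n_resamples=n_resamples,
        best_index=best,
        trees=trees,
    )


# ---------------------------------------------------------------------------
# newick IO
# ---------------------------------------------------------------------------


def tree_from_newick(newick: str) -> dendropy.Tree:
    """Parse a newick string (underscores kept literal, as in taxon ids)."""
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()
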