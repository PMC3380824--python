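"""Linkage disequilibrium, the x = D_SS - D_SX statistic, and its test."""

import itertools
import math

import numpy as np
import pytest

from introgrescan import coalsim as cs
from introgrescan.ldstats import (
    GeneFlowResult,
    geneflow_test,
    infer_direction,
    ld_D_and_Dprime,
    pairwise_ld_matrix,
    x_statistic,
)
from introgrescan.seqdata import (
    HaplotypeAlignment,
    InputError,
    SiteClass,
    classify_sites,
)

from conftest import random_alignment


class TestDPrime:
    def test_complete_association(self):
        a = list("AACC")
        b = list("GGTT")
        d, dp = ld_D_and_Dprime(a, b)
        assert d == pytest.approx(0.25)
        assert dp == pytest.approx(1.0)

    def test_independence(self):
        a = list("AACC")
        b = list("GTGT")
        d, dp = ld_D_and_Dprime(a, b)
        assert d == 0.0
        assert dp == 0.0

    def test_hand_computed_intermediate(self):
        # 3x AB, 1x Ab, 1x aB, 5x ab: p_A=p_B=0.4, p_AB=0.3,
        # D=0.14, D_max=0.24, D'=0.5833...
        a = list("AAAACCCCCC")
        b = list("GGGTGTTTTT")
        d, dp = ld_D_and_Dprime(a, b)
        assert d == pytest.approx(0.14)
        assert dp == pytest.approx(0.14 / 0.24)

    def test_monomorphic_rejected(self):
        with pytest.raises(InputError):
            ld_D_and_Dprime(list("AAAA"), list("GGTT"))

    def test_exhaustive_two_site_configurations(self):
        """|D'| <= 1 always and |D'| = 1 exactly when at most three of the
        four gametic types occur, over every configuration with n <= 8."""
        for n in range(2, 9):
            for nab in range(n + 1):
                for nAb in range(n + 1 - nab):
                    for naB in range(n + 1 - nab - nAb):
                        nAB = n - nab - nAb - naB
                        a = ["A"] * (nAB + nAb) + ["C"] * (naB + nab)
                        b = (
                            ["G"] * nAB + ["T"] * nAb + ["G"] * naB + ["T"] * nab
                        )
                        if len(set(a)) != 2 or len(set(b)) != 2:
                            continue
                        _, dp = ld_D_and_Dprime(a, b)
                        assert abs(dp) <= 1 + 1e-12
                        gametes = len({g for g in zip(a, b)})
                        if gametes <= 3:
                            assert abs(dp) == pytest.approx(1.0)
                        else:
                            # all four gametes present: |D'| < 1
                            assert abs(dp) < 1 - 1e-12


def brute_force_x(aln, pop1, pop2, signed=True):
    """Pair-by-pair re-derivation of x via ld_D_and_Dprime."""
    classes = classify_sites(aln, pop1, pop2)
    shared = [c.position for c in classes if c.klass is SiteClass.SHARED]
    excl = {
        1: [c.position for c in classes if c.klass is SiteClass.EXCLUSIVE_POP1],
        2: [c.position for c in classes if c.klass is SiteClass.EXCLUSIVE_POP2],
    }
    mat = aln.matrix()
    out = []
    for pop, which in ((pop1, 1), (pop2, 2)):
        rows = mat[aln.index_of(pop)]
        dss = [
            ld_D_and_Dprime(rows[:, i], rows[:, j])[1]
            for i, j in itertools.combinations(shared, 2)
        ]
        dsx = [
            ld_D_and_Dprime(rows[:, i], rows[:, j])[1]
            for i in shared
            for j in excl[which]
        ]
        if not signed:
            dss = [abs(v) for v in dss]
            dsx = [abs(v) for v in dsx]
        if dss and dsx:
            out.append(np.mean(dss) - np.mean(dsx))
        else:
            out.append(math.nan)
    return out


class TestXStatistic:
    @pytest.mark.parametrize("signed", [True, False])
    def test_matches_bruteforce_on_random_alignments(self, rng, signed):
        checked = 0
        for _ in range(60):
            aln = random_alignment(rng, n=20, length=60, bases="AAAT")
            pop1 = list(aln.ids[:10])
            pop2 = list(aln.ids[10:])
            res = x_statistic(aln, pop1, pop2, signed=signed)
            want1, want2 = brute_force_x(aln, pop1, pop2, signed=signed)
            for got, want in ((res.x_pop1, want1), (res.x_pop2, want2)):
                if math.isnan(want):
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(want, abs=1e-12)
                    checked += 1
        assert checked > 20  # the draw actually exercised defined cases

    def test_constructed_extreme_case(self):
        # pop1: two shared sites in complete coupling, one pop1-exclusive
        # site independent of them -> x_pop1 = 1 - 0 = 1
        pop1_rows = ["AGA", "AGC", "CTA", "CTC"]
        pop2_rows = ["AGA", "CTA"]
        aln = HaplotypeAlignment(
            "L", ["p1", "p2", "p3", "p4", "q1", "q2"], pop1_rows + pop2_rows
        )
        pop1 = ["p1", "p2", "p3", "p4"]
        pop2 = ["q1", "q2"]
        for signed in (True, False):
            res = x_statistic(aln, pop1, pop2, signed=signed)
            assert res.x_pop1 == pytest.approx(1.0)
        assert res.n_SS_pairs_pop1 == 1
        assert res.n_SX_pairs_pop1 == 2

    def test_na_without_shared_polymorphisms(self):
        aln = HaplotypeAlignment(
            "L",
            ["a", "b", "c", "d"],
            ["AAG", "ACG", "TAG", "TAG"],
        )
        res = x_statistic(aln, ["a", "b"], ["c", "d"])
        assert math.isnan(res.x_pop1)
        assert math.isnan(res.x_pop2)

    def test_label_swap_symmetry(self, rng):
        aln = random_alignment(rng, n=16, length=50, bases="AAAT")
        pop1 = list(aln.ids[:8])
        pop2 = list(aln.ids[8:])
        r12 = x_statistic(aln, pop1, pop2)
        r21 = x_statistic(aln, pop2, pop1)
        assert (r12.x_pop1 == r21.x_pop2) or (
            math.isnan(r12.x_pop1) and math.isnan(r21.x_pop2)
        )
        assert (r12.x_pop2 == r21.x_pop1) or (
            math.isnan(r12.x_pop2) and math.isnan(r21.x_pop1)
        )

    def test_random_relabelings_exchangeable(self, rng):
        """Random halves of one panmictic pool give x values with the
        same distribution for both labels (paired permutation check)."""
        p = cs.IMParameters(theta1=8, theta2=8, thetaA=8, t_split=0, m1=0,
                            m2=0, n1=16, n2=0, rho=5)
        x1s, x2s = [], []
        for _ in range(120):
            mat = cs.binary_site_matrix(cs.simulate_ancestry(p, rng), rng)
            perm = rng.permutation(16)
            from introgrescan.ldstats import x_from_binary

            x1, x2 = x_from_binary(mat[perm], 8)
            x1s.append(x1)
            x2s.append(x2)
        x1s = np.array(x1s)
        x2s = np.array(x2s)
        from scipy.stats import ks_2samp

        ok = ~(np.isnan(x1s) | np.isnan(x2s))
        assert ks_2samp(x1s[ok], x2s[ok]).pvalue > 0.001


class TestGeneFlowTest:
    def make_data(self, seed, **kw):
        params = dict(theta1=10, theta2=10, thetaA=10, t_split=5, m1=0.1,
                      m2=0.1, n1=10, n2=10, rho=5, locus_length=400)
        params.update(kw)
        rng = np.random.default_rng(seed)
        p = cs.IMParameters(**params)
        a = cs.simulate_ancestry(p, rng)
        return cs.drop_mutations_infinite_sites(a, p.locus_length, rng)

    def test_seed_reproducibility(self):
        aln = self.make_data(3)
        r1 = geneflow_test(aln, aln.ids[:10], aln.ids[10:], n_sims=60,
                           seed=5, recombination_rate=5)
        r2 = geneflow_test(aln, aln.ids[:10], aln.ids[10:], n_sims=60,
                           seed=5, recombination_rate=5)
        assert r1.p_pop1 == r2.p_pop1
        assert r1.p_pop2 == r2.p_pop2
        assert np.array_equal(r1.null_x_pop2, r2.null_x_pop2, equal_nan=True)

    def test_na_statistic_gives_na_p(self):
        aln = HaplotypeAlignment(
            "L", ["a", "b", "c", "d"], ["AAG", "ACG", "TAG", "TAG"]
        )
        res = geneflow_test(aln, ["a", "b"], ["c", "d"], n_sims=10, seed=0)
        assert math.isnan(res.p_pop1)
        assert math.isnan(res.p_pop2)

    def test_p_values_in_unit_interval(self):
        aln = self.make_data(11)
        res = geneflow_test(aln, aln.ids[:10], aln.ids[10:], n_sims=40,
                            seed=2, recombination_rate=5)
        for p in (res.p_pop1, res.p_pop2):
            assert math.isnan(p) or 0 < p <= 1

    def test_conditioning_modes_agree_on_scale(self):
        aln = self.make_data(7)
        ps = {}
        for mode in ("class_counts", "total_sites", "poisson"):
            res = geneflow_test(aln, aln.ids[:10], aln.ids[10:], n_sims=80,
                                seed=4, recombination_rate=5,
                                null_conditioning=mode)
            ps[mode] = res.p_pop2
        vals = [p for p in ps.values() if not math.isnan(p)]
        assert len(vals) >= 2  # the modes all produce usable p-values

    def test_invalid_inputs(self):
        aln = self.make_data(1)
        with pytest.raises(InputError):
            geneflow_test(aln, aln.ids[:10], aln.ids[10:], n_sims=0)
        with pytest.raises(InputError):
            geneflow_test(aln, aln.ids[:10], aln.ids[10:], n_sims=10,
                          null_conditioning="bogus")


class TestInferDirection:
    def mk(self, x1, x2, p1, p2):
        return GeneFlowResult(
            locus_name="L", x_pop1=x1, x_pop2=x2,
            D_SS_mean_pop1=0, D_SX_mean_pop1=0,
            D_SS_mean_pop2=0, D_SX_mean_pop2=0,
            n_SS_pairs_pop1=1, n_SX_pairs_pop1=1,
            n_SS_pairs_pop2=1, n_SX_pairs_pop2=1,
            p_pop1=p1, p_pop2=p2,
        )

    def test_published_style_asymmetry(self):
        # one species strongly positive and significant, the other weak
        res = self.mk(0.205, 0.056, 0.001, 0.83)
        assert infer_direction(res, labels=("timareta", "melpomene")) == "timareta"

    def test_both_negative_undetermined(self):
        assert infer_direction(self.mk(-0.1, -0.2, 0.5, 0.5)) == "undetermined"

    def test_exact_tie_undetermined(self):
        assert infer_direction(self.mk(0.4, 0.4, 0.01, 0.01)) == "undetermined"

    def test_larger_significant_value_wins(self):
        assert infer_direction(self.mk(0.2, 0.9, 0.01, 0.002)) == "pop2"

    def test_both_na_is_error(self):
        with pytest.raises(InputError):
            infer_direction(self.mk(math.nan, math.nan, math.nan, math.nan))


class TestPairwiseLDMatrix:
    def test_perfectly_coupled_sites(self):
        seqs = ["AG"] * 5 + ["CT"] * 5
        aln = HaplotypeAlignment("L", [f"h{i}" for i in range(10)], seqs)
        m, sites = pairwise_ld_matrix(aln, maf=0.05)
        assert sites == [0, 1]
        assert m[0, 1] == pytest.approx(1.0)
        assert m[1, 0] == pytest.approx(1.0)

    def test_symmetry_on_random_input(self, rng):
        aln = random_alignment(rng, n=20, length=30, bases="AAAT")
        m, sites = pairwise_ld_matrix(aln, maf=0.05)
        assert np.allclose(m, m.T, equal_nan=True)
        assert np.allclose(np.diag(m), 1.0)

    def test_too_few_sites_rejected(self):
        aln = HaplotypeAlignment("L", ["a", "b"], ["AA", "AA"])
        with pytest.raises(InputError):
            pairwise_ld_matrix(aln, maf=0.05)

    def test_background_ld_declines_with_sample_size(self, rng):
        """In a panmictic sample, mean off-diagonal |D'| decays toward its
        neutral expectation as the sample grows."""
        def mean_offdiag(n, reps=6):
            vals = []
            for _ in range(reps):
                p = cs.IMParameters(theta1=10, theta2=10, thetaA=10,
                                    t_split=0, m1=0, m2=0, n1=n, n2=0, rho=20,
                                    locus_length=400)
                aln = cs.drop_mutations_infinite_sites(
                    cs.simulate_ancestry(p, rng), 400, rng,
                    ids=[f"h{i}" for i in range(n)],
                )
                try:
                    m, _ = pairwise_ld_matrix(aln, maf=0.1)
                except InputError:
                    continue
                iu = np.triu_indices(m.shape[0], k=1)
                vals.append(np.nanmean(np.abs(m[iu])))
            return np.mean(vals)

        assert mean_offdiag(40) < mean_offdiag(8)


class TestDPrimeProperties:
    """Randomized invariants of D'."""

    from hypothesis import given, settings, strategies as st

    @given(
        counts=st.tuples(
            st.integers(0, 12), st.integers(0, 12),
            st.integers(0, 12), st.integers(0, 12),
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounds_sign_and_orientation_invariance(self, counts):
        nAB, nAb, naB, nab = counts
        a = ["A"] * (nAB + nAb) + ["C"] * (naB + nab)
        b = ["G"] * nAB + ["T"] * nAb + ["G"] * naB + ["T"] * nab
        if len(set(a)) != 2 or len(set(b)) != 2:
            return
        d, dp = ld_D_and_Dprime(a, b)
        assert -1 - 1e-12 <= dp <= 1 + 1e-12
        assert (d == 0) == (dp == 0)
        assert np.sign(d) == np.sign(dp)
        # |D'| does not depend on which base letters encode the alleles
        swap = {"A": "C", "C": "A"}
        _, dp_sw = ld_D_and_Dprime([swap[x] for x in a], b)
        assert abs(dp_sw) == pytest.approx(abs(dp), abs=1e-12)


class TestLDMatrixExport:
    def test_tsv_roundtrip(self, tmp_path):
        import pandas as pd

        from introgrescan.ldstats import write_ld_matrix_tsv

        seqs = ["AG"] * 5 + ["CT"] * 5
        aln = HaplotypeAlignment("L", [f"h{i}" for i in range(10)], seqs)
        m, sites = pairwise_ld_matrix(aln, maf=0.05)
        out = tmp_path / "ld.tsv"
        write_ld_matrix_tsv(m, sites, out)
        back = pd.read_csv(out, sep="\t", index_col="position")
        assert list(back.index) == [1, 2]  # 1-based positions
        assert np.allclose(back.values, m)
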