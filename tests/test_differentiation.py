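import math
from itertools import combinations

import numpy as np
import pytest

import oracles
from conftest import make_alignment
from mtpopgen.differentiation import (
    amova_two_level,
    fst_matrix,
    gene_flow,
    pairwise_differences,
    pairwise_phist,
)
from mtpopgen.seqio import PopulationMap


def _pm(labels):
    return PopulationMap({f"s{i+1}": l for i, l in enumerate(labels)})


class TestPairwiseDifferences:
    def test_identical_pair(self):
        dm = pairwise_differences(make_alignment(["ACGT", "ACGT"]))
        assert dm.d[0, 1] == 0

    def test_single_difference(self):
        dm = pairwise_differences(make_alignment(["ACGT", "ACGA"]))
        assert dm.d[0, 1] == 1

    def test_matches_bruteforce(self, rng):
        seqs = oracles.random_alignment(rng, 6, 20)
        dm = pairwise_differences(make_alignment(seqs))
        for i in range(6):
            for j in range(6):
                assert dm.d[i, j] == oracles.hamming(seqs[i], seqs[j])


class TestAmova:
    def test_fixed_difference_gives_phi_1(self):
        aln = make_alignment(["AAAA", "AAAA", "TTTT", "TTTT"])
        pm = _pm(["P1", "P1", "P2", "P2"])
        dm = pairwise_differences(aln)
        res = amova_two_level(dm, pm, n_perm=50, seed=0)
        # direct SSD arithmetic: ssd_total = 4*4/4 = 4, ssd_within = 0
        assert res.ssd_within == 0
        assert res.ssd_among == pytest.approx(4.0)
        assert res.fst == pytest.approx(1.0)
        assert res.pct_among == pytest.approx(100.0)
        assert res.df_among == 1 and res.df_within == 2

    def test_no_structure_by_construction(self, rng):
        # one pool split at random: Phi_ST ~ 0, p typically > 0.05
        seqs = oracles.random_alignment(rng, 16, 30)
        labels = ["A"] * 8 + ["B"] * 8
        rng.shuffle(labels)
        dm = pairwise_differences(make_alignment(seqs))
        res = amova_two_level(dm, _pm(labels), n_perm=200, seed=7)
        assert abs(res.fst) < 0.25
        assert res.p_value > 0.05

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(20):
            n1, n2 = int(rng.integers(2, 5)), int(rng.integers(2, 5))
            seqs = oracles.random_alignment(rng, n1 + n2, 25)
            by_pop = {"X": seqs[:n1], "Y": seqs[n1:]}
            dm = pairwise_differences(make_alignment(seqs))
            pm = _pm(["X"] * n1 + ["Y"] * n2)
            res = amova_two_level(dm, pm, n_perm=1, seed=0)
            ssd_a, ssd_w, s2a, s2w, phi = oracles.amova_bruteforce(by_pop)
            assert res.ssd_among == pytest.approx(ssd_a)
            assert res.ssd_within == pytest.approx(ssd_w)
            assert res.sigma2_a == pytest.approx(s2a)
            assert res.sigma2_w == pytest.approx(s2w)
            if abs(s2a + s2w) > 1e-12:
                assert res.fst == pytest.approx(phi)

    def test_label_order_invariance(self, rng):
        seqs = oracles.random_alignment(rng, 8, 20)
        pm = _pm(["X"] * 4 + ["Y"] * 4)
        dm = pairwise_differences(make_alignment(seqs))
        a = amova_two_level(dm, pm, n_perm=1, seed=0, populations=["X", "Y"])
        b = amova_two_level(dm, pm, n_perm=1, seed=0, populations=["Y", "X"])
        assert a.fst == pytest.approx(b.fst)
        assert a.pct_among == pytest.approx(b.pct_among)

    def test_small_population_rejected(self):
        aln = make_alignment(["AAAA", "TTTT", "TTTA"])
        pm = _pm(["X", "Y", "Y"])
        dm = pairwise_differences(aln)
        with pytest.raises(ValueError, match="fewer than 2"):
            amova_two_level(dm, pm, n_perm=10, seed=0)

    def test_monomorphic_reports_zero(self):
        aln = make_alignment(["AAAA"] * 4)
        pm = _pm(["X", "X", "Y", "Y"])
        res = amova_two_level(pairwise_differences(aln), pm, n_perm=10, seed=0)
        assert res.fst == 0.0

    def test_permutation_rank_uniformity_small_n(self, rng):
        # For n=6 with groups of 3, exact label assignments are few; check
        # the p-value of the observed split matches its enumeration rank.
        seqs = oracles.random_alignment(rng, 6, 15)
        dm = pairwise_differences(make_alignment(seqs))
        pm = _pm(["X"] * 3 + ["Y"] * 3)
        obs = amova_two_level(dm, pm, n_perm=1, seed=0).fst
        groups = np.array([0, 0, 0, 1, 1, 1])
        from itertools import permutations

        stats = []
        seen = set()
        for perm in permutations(range(6)):
            key = tuple(groups[list(perm)])
            if key in seen:
                continue
            seen.add(key)
            stats.append(
                oracles.amova_bruteforce(
                    {
                        "X": [seqs[i] for i in range(6) if key[i] == 0],
                        "Y": [seqs[i] for i in range(6) if key[i] == 1],
                    }
                )[4]
            )
        exact_p = sum(1 for s in stats if s >= obs - 1e-12) / len(stats)
        res = amova_two_level(dm, pm, n_perm=2000, seed=3)
        assert res.p_value == pytest.approx(exact_p, abs=0.06)

    def test_determinism(self, rng):
        seqs = oracles.random_alignment(rng, 8, 20)
        pm = _pm(["X"] * 4 + ["Y"] * 4)
        dm = pairwise_differences(make_alignment(seqs))
        a = amova_two_level(dm, pm, n_perm=100, seed=5)
        b = amova_two_level(dm, pm, n_perm=100, seed=5)
        assert a == b


class TestPairwisePhist:
    def test_identical_populations(self):
        aln = make_alignment(["ACGT", "ACGA", "ACGT", "ACGA"])
        pm = _pm(["X", "X", "Y", "Y"])
        dm = pairwise_differences(aln)
        f, p = pairwise_phist(dm, pm, ("X", "Y"), n_perm=50, seed=0)
        assert f <= 0 + 1e-12

    def test_equals_amova_on_two_pops(self, rng):
        seqs = oracles.random_alignment(rng, 10, 25)
        pm = _pm(["X"] * 5 + ["Y"] * 5)
        dm = pairwise_differences(make_alignment(seqs))
        f, p = pairwise_phist(dm, pm, ("X", "Y"), n_perm=99, seed=11)
        res = amova_two_level(dm, pm, n_perm=99, seed=11,
                              populations=("X", "Y"))
        assert f == res.fst
        assert p == res.p_value

    def test_matrix_symmetric(self, study_ds):
        from mtpopgen.differentiation import pairwise_differences

        dm = pairwise_differences(study_ds.alignment)
        fm = fst_matrix(dm, study_ds.popmap, n_perm=20, seed=0)
        assert np.allclose(fm.fst, fm.fst.T)
        assert ((fm.p >= 0) & (fm.p <= 1)).all()


class TestGeneFlow:
    def test_half(self):
        gf = gene_flow(0.5)
        assert gf.nm == pytest.approx(0.5)
        assert gf.category == "medium"

    def test_one(self):
        gf = gene_flow(1.0)
        assert gf.nm == 0.0
        assert gf.category == "low"

    def test_paper_value(self):
        gf = gene_flow(0.4557)
        assert round(gf.nm, 3) == 0.597
        assert gf.category == "medium"

    def test_out_of_domain(self):
        with pytest.raises(ValueError):
            gene_flow(0.0)
        with pytest.raises(ValueError):
            gene_flow(-0.2)
        with pytest.raises(ValueError):
            gene_flow(1.2)

    def test_inverse_roundtrip(self):
        for fst in (0.01, 0.1, 0.4557, 0.9, 1.0):
            nm = gene_flow(fst).nm
            assert 1.0 / (2.0 * nm + 1.0) == pytest.approx(fst, rel=1e-12)

    def test_categories(self):
        assert gene_flow(1 / 3).category == "high"      # nm = 1.0
        assert gene_flow(0.6).category == "medium"  # nm = 1/3
        assert gene_flow(0.9).category == "low"
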