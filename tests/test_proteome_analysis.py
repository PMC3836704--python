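"""Proteome vocabulary, Jaccard comparison and power-law fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from compord.ft_core import FTParams, ProteinRecord, detect_fts
from compord.order_measures import COProfile
from compord.proteome_analysis import (
    ProteomeVocabulary,
    binned_measure_length_regression,
    build_vocabulary,
    correlation_matrix,
    dft_abundance_distribution,
    fit_loglog,
    jaccard,
    rank_predominant_fts,
)

RUN = ProteinRecord("run", "AAAAAAA")
AQ = ProteinRecord("aq", "AQAQAQAQAQAQ")


def vocab_from_sets(*sets):
    from collections import Counter

    vocabs = []
    for i, s in enumerate(sets):
        vocabs.append(
            ProteomeVocabulary(
                source_id=f"v{i}",
                dft_set=frozenset(s),
                carrier_counts=Counter({ft: 1 for ft in s}),
                per_protein_dft=[len(s)] if s else [],
                n_proteins=1,
                n_co=1 if s else 0,
            )
        )
    return vocabs


class TestVocabulary:
    def test_duplicates_do_not_grow_the_set(self):
        one = build_vocabulary([RUN])
        two = build_vocabulary([RUN, RUN])
        assert one.dft_set == two.dft_set
        assert two.carrier_counts["AAA"] == 2

    def test_disjoint_union(self):
        v = build_vocabulary([RUN, AQ])
        assert v.dft_set == {"AAA", "AQA", "QAQ"}
        assert all(c == 1 for c in v.carrier_counts.values())
        assert v.n_co == 2

    def test_union_matches_per_protein_sets(self, table1):
        records = list(table1.values())
        v = build_vocabulary(records)
        expected = set()
        for rec in records:
            expected |= set(detect_fts(rec).fts())
        assert v.dft_set == expected
        assert v.n_co == 6

    def test_order_invariance(self, table1):
        records = list(table1.values())
        a = build_vocabulary(records)
        b = build_vocabulary(records[::-1])
        assert a.dft_set == b.dft_set
        assert a.carrier_counts == b.carrier_counts

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError):
            build_vocabulary([])


class TestJaccard:
    def test_identical_sets(self):
        a, b = vocab_from_sets({"AAA", "GGG"}, {"AAA", "GGG"})
        assert jaccard(a, b) == 1.0

    def test_disjoint_sets(self):
        a, b = vocab_from_sets({"AAA"}, {"GGG"})
        assert jaccard(a, b) == 0.0

    def test_partial_overlap(self):
        a, b = vocab_from_sets({"AAA", "GGG", "PPP"}, {"GGG", "PPP", "QQQ"})
        assert jaccard(a, b) == 0.5

    def test_both_empty_warns_and_returns_zero(self):
        a, b = vocab_from_sets(set(), set())
        with pytest.warns(UserWarning):
            assert jaccard(a, b) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.sets(st.sampled_from(["AAA", "CCC", "GGG", "PPP", "QQQ"])),
        st.sets(st.sampled_from(["AAA", "CCC", "GGG", "PPP", "QQQ"])),
    )
    def test_axioms(self, sa, sb):
        a, b = vocab_from_sets(sa, sb)
        if not (sa | sb):
            return
        c = jaccard(a, b)
        assert 0.0 <= c <= 1.0
        assert c == jaccard(b, a)
        assert jaccard(a, a) == (1.0 if sa else 0.0) or not sa
        if c == 1.0:
            assert sa == sb


class TestCorrelationMatrix:
    def test_identical_vocabularies(self):
        a, b = vocab_from_sets({"AAA"}, {"AAA"})
        m = correlation_matrix([a, b])
        assert (m.to_numpy() == 1.0).all()

    def test_hand_computed_and_symmetric(self):
        vocabs = vocab_from_sets(
            {"AAA", "GGG", "PPP"}, {"GGG", "PPP", "QQQ"}, {"AAA"}
        )
        m = correlation_matrix(vocabs)
        assert m.loc["v0", "v1"] == 0.5
        assert m.loc["v0", "v2"] == pytest.approx(1 / 3)
        assert m.loc["v1", "v2"] == 0.0
        assert np.allclose(m.to_numpy(), m.to_numpy().T)
        assert np.allclose(np.diag(m.to_numpy()), 1.0)

    def test_newick_tree_contains_all_leaves(self):
        vocabs = vocab_from_sets({"AAA", "GGG"}, {"AAA"}, {"QQQ"})
        _, newick = correlation_matrix(vocabs, tree=True)
        from skbio.tree import TreeNode
        from io import StringIO

        tree = TreeNode.read(StringIO(newick))
        assert {t.name for t in tree.tips()} == {"v0", "v1", "v2"}


class TestPredominantFts:
    def test_homo_run_flagging_and_order(self):
        poly_e = [ProteinRecord(f"e{i}", "EEEEEEE" + "ACDFW") for i in range(3)]
        pgp = [ProteinRecord(f"p{i}", "PGP" * 5 + "W") for i in range(2)]
        v = build_vocabulary(poly_e + pgp)
        ranked = rank_predominant_fts(v)
        assert ranked.ft.iloc[0] == "EEE"
        assert bool(ranked.homo_run.iloc[0])
        row_pgp = ranked[ranked.ft == "PGP"].iloc[0]
        assert not bool(row_pgp.homo_run)
        # carrier-count ordering: EEE in 3 proteins beats PGP-family in 2
        assert ranked.carrier_count.iloc[0] == 3
        assert (ranked.carrier_count.diff().dropna() <= 0).all()


class TestAbundance:
    def test_point_mass_when_all_unique(self):
        v = vocab_from_sets({"AAA", "CCC"})[0]
        carrier, per_protein = dft_abundance_distribution(v)
        assert carrier.index.tolist() == [1]
        assert carrier.iloc[0] == 1.0

    def test_normalization(self, table1):
        v = build_vocabulary(list(table1.values()))
        carrier, per_protein = dft_abundance_distribution(v)
        assert carrier.sum() == pytest.approx(1.0)
        assert per_protein.sum() == pytest.approx(1.0)


class TestFitLoglog:
    def test_exact_inverse_square(self):
        x = np.arange(1, 50)
        fit = fit_loglog(x, 3.0 * x**-2.0)
        assert fit.slope == pytest.approx(-2.0)
        assert fit.r == pytest.approx(-1.0)

    def test_exact_zipf(self):
        ranks = np.arange(1, 100)
        fit = fit_loglog(ranks, 0.5 / ranks)
        assert fit.slope == pytest.approx(-1.0)

    def test_fit_range_restricts_points(self):
        x = np.arange(1, 1001)
        y = x**-1.5
        y[x > 100] *= 10  # corrupt outside the fitted decade range
        fit = fit_loglog(x, y, fit_range=(0, 2))
        assert fit.slope == pytest.approx(-1.5)
        assert fit.n_points == 100

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_loglog([1, 2], [1, 0.5])

    def test_noisy_exponent_recovery(self):
        rng = np.random.default_rng(31)
        x = np.arange(1, 200)
        y = x**-1.6 * np.exp(rng.normal(0, 0.05, size=x.size))
        fit = fit_loglog(x, y)
        assert fit.slope == pytest.approx(-1.6, abs=0.05)


def synthetic_profiles(lengths, rp_exponent=-0.5, dft_exponent=None, c=30.0):
    """COProfiles with planted power laws RP = c*L^a and DFT = L^b."""
    profs = []
    for i, L in enumerate(lengths):
        rp = c * L**rp_exponent
        dft = max(1, round(L**dft_exponent)) if dft_exponent else 3
        profs.append(
            COProfile(
                protein_id=f"s{i}", L=int(L), is_co=True, dft_count=int(dft),
                dfts=["AAA"], total_occurrences=10, rc=0.2, mfi=1,
                mfi_support=4, rp=float(min(rp, 1.0)), periodic=True,
                purity_class="complex",
            )
        )
    return profs


class TestBinnedRegression:
    def test_planted_rp_exponent(self):
        lengths = np.unique(np.geomspace(1000, 100000, 400).astype(int))
        profs = synthetic_profiles(lengths, rp_exponent=-0.5)
        fit = binned_measure_length_regression(profs, "rp")
        assert fit.slope == pytest.approx(-0.5, abs=0.03)
        assert fit.rho_unbinned == pytest.approx(-1.0, abs=0.01)

    def test_length_independent_measure_uncorrelated(self):
        rng = np.random.default_rng(37)
        lengths = rng.integers(100, 10000, size=500)
        profs = synthetic_profiles(lengths, rp_exponent=-0.5)
        for p in profs:
            p.rc = float(rng.uniform(0.05, 0.95))
        fit = binned_measure_length_regression(profs, "rc")
        assert abs(fit.rho_unbinned) < 0.15

    def test_opposite_exponents_slope_ratio_minus_one(self):
        lengths = np.unique(np.geomspace(1000, 100000, 600).astype(int))
        profs = synthetic_profiles(
            lengths, rp_exponent=-0.4, dft_exponent=0.4, c=40.0
        )
        rp_fit = binned_measure_length_regression(profs, "rp")
        dft_fit = binned_measure_length_regression(profs, "dft_count")
        assert rp_fit.slope / dft_fit.slope == pytest.approx(-1.0, abs=0.15)

    def test_too_few_proteins_rejected(self):
        profs = synthetic_profiles([100, 200, 300])
        with pytest.raises(ValueError):
            binned_measure_length_regression(profs, "rp", n_bins=50)
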