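import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from ucps_motif import (
    DegenerateTestError,
    ProteinRecord,
    class_enrichment,
    class_sty_enrichment,
    differential_motifs,
    presence_table,
    rows_to_dataframe,
    two_prop_ztest,
)


def recs(*seqs, cohort="unlabelled"):
    return [
        ProteinRecord(id=f"r{i}", sequence=s, cohort=cohort)
        for i, s in enumerate(seqs)
    ]


class TestPresenceTable:
    def test_counts_presence_not_occurrences(self):
        table = presence_table(recs("EEE", "AEEEA"), k=3)
        assert table["EEE"] == 2
        assert table["AEE"] == 1
        assert table["EEA"] == 1
        # a protein with two overlapping EEE occurrences still counts once
        assert presence_table(recs("EEEE"), k=3)["EEE"] == 1

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            presence_table([], k=3)

    def test_additive_over_disjoint_unions(self, small_cohorts):
        _, pos, neg, _ = small_cohorts
        ta = presence_table(pos[:20], 3)
        tb = presence_table(pos[20:40], 3)
        tab = presence_table(pos[:40], 3)
        for m in ("EEE", "KKA", "WAA", "DDD"):
            assert ta[m] + tb[m] == tab[m]

    def test_agrees_with_bruteforce_substring_counting(self, rng):
        from .conftest import random_protein

        proteins = recs(*(random_protein(rng, 40) for _ in range(50)))
        table = presence_table(proteins, k=3)
        probe = rng.choice(sorted(table), size=300)
        for m in probe:
            assert table[m] == sum(m in p.sequence for p in proteins)

    def test_mirror_mode_uses_canonical_keys(self):
        table = presence_table(recs("MEKK"), k=3, mirror=True)
        assert table["EKK"] == 1  # KKE counted under its canonical form
        assert "KKE" not in table


class TestTwoPropZtest:
    def test_equal_proportions_give_zero(self):
        t = two_prop_ztest(10, 20, 10, 20)
        assert t.z == 0.0
        assert t.p_two_sided == 1.0

    def test_headline_counts(self):
        # frozen from an independent evaluation of the pooled-z formula
        t = two_prop_ztest(160, 202, 625, 1576)
        assert t.z == pytest.approx(10.657684467490837, abs=1e-9)
        assert t.p_two_sided < 0.0002
        t2 = two_prop_ztest(170, 202, 603, 1576)
        assert t2.p_two_sided < 0.00001

    def test_degenerate_pooled_proportion(self):
        with pytest.raises(DegenerateTestError):
            two_prop_ztest(0, 10, 0, 20)
        with pytest.raises(DegenerateTestError):
            two_prop_ztest(10, 10, 20, 20)

    def test_antisymmetry_exact(self, rng):
        for _ in range(100):
            n1, n2 = int(rng.integers(2, 50)), int(rng.integers(2, 50))
            x1, x2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
            if x1 + x2 == 0 or x1 + x2 == n1 + n2:
                continue
            a = two_prop_ztest(x1, n1, x2, n2)
            b = two_prop_ztest(x2, n2, x1, n1)
            assert a.z == -b.z
            assert a.p_two_sided == b.p_two_sided

    def test_z_squared_equals_uncorrected_chisquare(self, rng):
        for _ in range(100):
            n1, n2 = int(rng.integers(5, 80)), int(rng.integers(5, 80))
            x1, x2 = int(rng.integers(1, n1)), int(rng.integers(1, n2))
            t = two_prop_ztest(x1, n1, x2, n2)
            table = [[x1, n1 - x1], [x2, n2 - x2]]
            chi2 = chi2_contingency(table, correction=False).statistic
            assert t.z**2 == pytest.approx(chi2, abs=1e-9)

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.proportion import proportions_ztest

        for _ in range(50):
            n1, n2 = int(rng.integers(5, 100)), int(rng.integers(5, 100))
            x1, x2 = int(rng.integers(1, n1)), int(rng.integers(1, n2))
            t = two_prop_ztest(x1, n1, x2, n2)
            z_ref, p_ref = proportions_ztest([x1, x2], [n1, n2])
            assert t.z == pytest.approx(z_ref, abs=1e-10)
            assert t.p_two_sided == pytest.approx(p_ref, abs=1e-12)

    def test_p_monotone_in_abs_z(self):
        ps = [two_prop_ztest(x, 100, 50, 100).p_two_sided for x in (50, 60, 70, 90)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_log10_p_finite_in_far_tail(self):
        t = two_prop_ztest(1000, 1000, 1, 1000)
        assert t.p_two_sided == 0.0  # underflows
        assert math.isfinite(t.log10_p) and t.log10_p < -100


class TestDifferentialMotifs:
    def test_identical_cohorts_yield_nothing(self):
        same = recs("MDEEKAL", "MKKSEEL", "AWEELAK")
        assert differential_motifs(same, same, k=3) == []

    def test_planted_motif_ranks_first(self, small_cohorts):
        _, pos, neg, _ = small_cohorts
        rows = differential_motifs(pos, neg, k=3)
        assert rows[0].motif_or_class == "EEE"
        assert rows[0].diff > 0.2

    def test_ratio_constraint_and_ranking(self):
        pos = recs("EEEAAA", "EEEKKK", "MMMAAA", "CCCAAA")
        neg = recs("EEEAAA", "MMMAAA", "MMMCCC", "PPPQQQ")
        rows = differential_motifs(pos, neg, k=3, min_ratio=1.3, top_n=100)
        by_motif = {r.motif_or_class: r for r in rows}
        # EEE: f_pos=0.5, f_neg=0.25 -> ratio 2, qualifies
        assert by_motif["EEE"].ratio == pytest.approx(2.0)
        # MMM: equal prevalence, must not qualify
        assert "MMM" not in by_motif
        # motifs absent from neg qualify with infinite ratio
        assert math.isinf(by_motif["KKK"].ratio)
        assert rows == sorted(rows, key=lambda r: (-r.diff, r.motif_or_class))

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            differential_motifs([], recs("MDE"), k=3)


class TestClassEnrichment:
    def test_single_motif_class_matches_presence_row(self, small_cohorts):
        _, pos, neg, _ = small_cohorts
        row = class_enrichment(pos, neg, ["EEE"])
        assert row.n_pos == presence_table(pos, 3)["EEE"]
        assert row.n_neg == presence_table(neg, 3)["EEE"]

    def test_empty_class_rejected(self, small_cohorts):
        _, pos, neg, _ = small_cohorts
        with pytest.raises(ValueError):
            class_enrichment(pos, neg, [])

    def test_planted_rates_recovered(self, small_cohorts):
        params, pos, neg, truth = small_cohorts
        row = class_enrichment(pos, neg, "triacidic")
        for f, p, n in ((row.f_pos, 0.8, len(pos)), (row.f_neg, 0.4, len(neg))):
            se = math.sqrt(p * (1 - p) / n)
            assert abs(f - p) <= 3 * se

    def test_sty_context_subset_of_class(self, small_cohorts):
        _, pos, neg, _ = small_cohorts
        full = class_enrichment(pos, neg, "KKX")
        ctx = class_sty_enrichment(pos, neg, "KKX")
        assert ctx.n_pos <= full.n_pos
        assert ctx.n_neg <= full.n_neg


def test_dataframe_column_order_and_bonferroni(small_cohorts):
    _, pos, neg, _ = small_cohorts
    rows = differential_motifs(pos, neg, k=3, top_n=5)
    df = rows_to_dataframe(rows, bonferroni_m=8000)
    assert list(df.columns)[:12] == [
        "motif", "n_pos", "N_pos", "n_neg", "N_neg",
        "f_pos", "f_neg", "ratio", "diff", "z", "p", "log10_p",
    ]
    assert (df["p_bonferroni"] <= 1.0).all()
    assert np.all(df["p_bonferroni"] >= df["p"])
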