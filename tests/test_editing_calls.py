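"""Per-site editing statistics: Fisher tests, Hochberg adjustment, odds ratios."""

import math
from functools import lru_cache

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from pprforge import (
    call_editing,
    design_array,
    editing_fraction,
    fisher_exact_site,
    hochberg_adjust,
    odds_ratio_pseudo,
)
from pprforge.editing_calls import read_counts_tsv, write_counts_tsv
from pprforge.synthetic_data import make_genome, simulate_counts


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration over all
    tables with the observed margins (independent of scipy's fisher_exact)."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(ks, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


def hochberg_stepup_oracle(pvals):
    """Hand application of the step-up recursion, independent of statsmodels."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    running = None
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        val = (m - rank) * p[i]
        running = val if running is None else min(running, val)
        adj[i] = min(running, 1.0)
    return adj


class TestEditingFraction:
    @pytest.mark.parametrize(
        "edited,total,expected",
        [(14, 10303, 0.14), (0, 10419, 0.0), (1, 10419, 0.01), (5000, 10000, 50.0)],
    )
    def test_percent_to_two_decimals(self, edited, total, expected):
        assert editing_fraction(edited, total) == expected

    def test_zero_total_undefined(self):
        with pytest.raises(ValueError):
            editing_fraction(0, 0)

    def test_edited_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            editing_fraction(11, 10)


class TestFisher:
    def test_extreme_table_matches_enumeration(self):
        p = fisher_exact_site(0, 10, 10, 0)
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)
        assert p == pytest.approx(1.0825e-5, rel=1e-4)

    def test_balanced_table_is_null(self):
        assert fisher_exact_site(5, 5, 5, 5) == 1.0

    def test_matches_enumeration_oracle_on_random_tables(self, rng):
        for _ in range(300):
            a, b, c, d = rng.integers(0, 31, size=4)
            if a + b + c + d == 0:
                continue
            assert fisher_exact_site(a, b, c, d) == pytest.approx(
                fisher_enumeration_oracle(a, b, c, d), abs=1e-12
            )

    def test_one_sided_alternative_supported(self):
        two = fisher_exact_site(8, 2, 2, 8)
        greater = fisher_exact_site(8, 2, 2, 8, alternative="greater")
        assert greater <= two

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_site(-1, 5, 5, 5)


class TestHochberg:
    def test_handchecked_vector(self):
        np.testing.assert_allclose(
            hochberg_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_and_all_null(self):
        np.testing.assert_allclose(hochberg_adjust([0.5]), [0.5])
        np.testing.assert_allclose(hochberg_adjust([1.0] * 7), [1.0] * 7)

    def test_matches_stepup_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(
                hochberg_adjust(p), hochberg_stepup_oracle(p), atol=1e-12
            )

    def test_monotone_along_sorted_raw_p(self, rng):
        for _ in range(50):
            p = rng.uniform(size=25)
            adj = hochberg_adjust(p)
            assert np.all(np.diff(adj[np.argsort(p, kind="stable")]) >= -1e-15)

    def test_rejections_superset_of_bonferroni(self, rng):
        alpha = 0.05
        for _ in range(100):
            p = rng.uniform(size=20) ** 3  # push some toward significance
            adj = hochberg_adjust(p)
            bonf = np.minimum(p * len(p), 1.0)
            assert np.all(adj[bonf < alpha] < alpha)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            hochberg_adjust([0.5, 1.2])


class TestOddsRatio:
    def test_symmetric_null(self):
        odds, log_odds = odds_ratio_pseudo(0, 100, 0, 100)
        assert odds == 1.0 and log_odds == 0.0

    def test_offtarget_scale_table(self):
        odds, log_odds = odds_ratio_pseudo(14, 10289, 0, 10000)
        assert odds == pytest.approx((14.5 * 10000.5) / (10289.5 * 0.5))
        assert odds == pytest.approx(28.19, abs=0.01)
        assert log_odds == pytest.approx(math.log(odds))

    def test_all_zero_table_stays_finite(self):
        odds, log_odds = odds_ratio_pseudo(0, 0, 0, 0)
        assert odds == 1.0 and math.isfinite(log_odds)

    def test_finite_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 1000, size=4)
            odds, log_odds = odds_ratio_pseudo(a, b, c, d)
            assert odds > 0 and math.isfinite(log_odds)

    def test_negative_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_pseudo(1, 1, 1, 1, pseudocount=-0.5)


@pytest.fixture(scope="module")
def small_run():
    array = design_array("UUACACGUG")
    truth = make_genome(2000, 1, array, seed=11, mean_depth=2000.0)
    treat = simulate_counts(truth, "treat")
    ctrl = simulate_counts(truth, "ctrl")
    return truth, treat, ctrl


class TestCallEditing:
    def test_planted_site_is_the_unique_call(self, small_run):
        truth, treat, ctrl = small_run
        report = call_editing(treat, ctrl)
        assert len(report.calls) == 1
        row = report.calls.iloc[0]
        p = truth.planted[0]
        assert (row.seq_id, row.pos0, row.strand) == (p.seq_id, p.pos0, p.strand)
        assert row.editing_percent_treat == pytest.approx(50.0, abs=5.0)
        assert row.log_odds_ratio > 2.0

    def test_self_comparison_yields_no_calls(self, small_run):
        _, treat, _ = small_run
        report = call_editing(treat, treat, alpha=0.05)
        assert len(report.calls) == 0
        assert np.all(report.tests["p_value"] == 1.0)

    def test_scores_joined_by_site_key(self, small_run):
        truth, treat, ctrl = small_run
        p = truth.planted[0]
        scores = {(p.seq_id, p.pos0, p.strand): 9.0}
        report = call_editing(treat, ctrl, scores=scores)
        assert report.calls.iloc[0]["raw_score"] == 9.0
        others = report.tests[report.tests["pos0"] != p.pos0]["raw_score"]
        assert others.isna().all()

    def test_mismatched_universes_rejected_with_keys(self, small_run):
        _, treat, ctrl = small_run
        with pytest.raises(ValueError, match="site universes differ"):
            call_editing(treat.iloc[:-3], ctrl)

    def test_counts_tsv_roundtrip(self, small_run, tmp_path):
        _, treat, _ = small_run
        path = tmp_path / "counts.tsv"
        write_counts_tsv(treat, path, ["seed=11"])
        back = read_counts_tsv(path)
        pd.testing.assert_frame_equal(back, treat.reset_index(drop=True))

    def test_low_fraction_site_not_significant_at_scan_scale(self):
        # a 0.14%-edited site against a clean control, depth ~10k: raw p is
        # small but cannot survive a transcriptome-scale correction
        p = fisher_exact_site(14, 10289, 0, 10000)
        assert p * 733_000 > 0.05


class TestTypeIControl:
    def test_family_wise_false_call_rate_under_null(self, rng):
        """With no true editing, the fraction of replicates producing any
        call at alpha 0.05 stays near the nominal level."""

        @lru_cache(maxsize=None)
        def cached_p(a, b, c, d):
            return fisher_exact_site(a, b, c, d)

        n_sites, n_reps, alpha = 1000, 200, 0.05
        err, depth = 0.001, 500
        false_reps = 0
        for _ in range(n_reps):
            a = rng.binomial(depth, err, size=n_sites)
            c = rng.binomial(depth, err, size=n_sites)
            p = np.array(
                [cached_p(ai, depth - ai, ci, depth - ci) for ai, ci in zip(a, c)]
            )
            adj = hochberg_adjust(p)
            ors = (a + 0.5) * (depth - c + 0.5) / ((depth - a + 0.5) * (c + 0.5))
            if np.any((adj < alpha) & (np.log(ors) > 2.0)):
                false_reps += 1
        assert false_reps / n_reps <= 0.07
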