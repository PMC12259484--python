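"""CIBER statistics: CIs against independent oracles, PΔ indices, tables, plots."""

import io

import numpy as np
import pandas as pd
import pytest

from riskdet.ciber import (
    behaviour_vector,
    ciber_plot,
    ciber_table,
    correlation_ci,
    mean_ci,
    potential_for_change_1,
    potential_for_change_2,
    select_targets,
)
from riskdet.errors import (
    InsufficientDataError,
    UndefinedStatisticError,
)
from riskdet.simulate import SimulationConfig, simulate_cohort
from riskdet.survey import DistanceFrequency

from conftest import make_response


# ----------------------------------------------------------------------- #
# Independent brute-force implementations of the two indices, written
# directly from their verbal definitions (used as oracles only).
# ----------------------------------------------------------------------- #

def brute_pd1(scores, behaviour):
    x = np.asarray(scores, float)
    y = np.asarray(behaviour, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    r = np.corrcoef(x[ok], y[ok])[0, 1]
    obs = x[~np.isnan(x)]
    if r > 0:
        return (obs.max() - obs.mean()) * r
    if r < 0:
        return (obs.min() - obs.mean()) * r
    return 0.0


def brute_pd2(scores, behaviour, uq=0.95, lq=0.05):
    x = np.asarray(scores, float)
    y = np.asarray(behaviour, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    r = np.corrcoef(x[ok], y[ok])[0, 1]
    obs = x[~np.isnan(x)]
    if r > 0:
        return (np.quantile(obs, uq) - obs.mean()) * r * r
    if r < 0:
        return abs(np.quantile(obs, lq) - obs.mean()) * r * r
    return 0.0


class TestMeanCi:
    def test_constant_vector_degenerates(self):
        assert mean_ci([5, 5, 5, 5]) == (5.0, 5.0, 5.0)

    def test_needs_two_observations(self):
        with pytest.raises(InsufficientDataError):
            mean_ci([3.0])

    def test_textbook_t_interval(self):
        """Independent oracle: statsmodels' t-based CI for the mean."""
        from statsmodels.stats.weightstats import DescrStatsW

        x = [1, 2, 3, 4, 5]
        m, lo, hi = mean_ci(x, level=0.95)
        exp_lo, exp_hi = DescrStatsW(np.asarray(x, float)).tconfint_mean(alpha=0.05)
        assert m == pytest.approx(3.0)
        assert (lo, hi) == pytest.approx((exp_lo, exp_hi), rel=1e-12)

    def test_9999_interval_strictly_contains_95(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(4, 2, size=rng.integers(5, 60))
            _, lo99, hi99 = mean_ci(x, level=0.9999)
            _, lo95, hi95 = mean_ci(x, level=0.95)
            assert lo99 < lo95 and hi99 > hi95


class TestCorrelationCi:
    def test_perfect_correlation_hits_one(self):
        x = np.arange(10.0)
        r, lo, hi = correlation_ci(x, x)
        assert r == 1.0 and hi == 1.0

    def test_orthogonal_deviations_give_zero(self):
        r, lo, hi = correlation_ci([1, 2, 3], [1, 0, 1])
        assert r == pytest.approx(0.0, abs=1e-15)
        assert (lo, hi) == (-1.0, 1.0)  # n = 3: infinite Fisher half-width

    def test_constant_input_flagged_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            correlation_ci([2, 2, 2, 2], [1, 2, 3, 4])

    def test_matches_pingouin_fisher_interval(self):
        """Independent oracle: pingouin's Pearson CI (Fisher z)."""
        import pingouin as pg

        rng = np.random.default_rng(5)
        for n in (10, 50, 200):
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            r, lo, hi = correlation_ci(x, y, level=0.95)
            res = pg.corr(x, y, method="pearson")
            assert r == pytest.approx(float(res["r"].iloc[0]), abs=1e-12)
            ci = res["CI95"].iloc[0]  # pingouin rounds the CI to 2 decimals
            assert lo == pytest.approx(ci[0], abs=6e-3)
            assert hi == pytest.approx(ci[1], abs=6e-3)

    def test_pairwise_deletion(self):
        x = [1, 2, 3, 4, np.nan, 6]
        y = [2, 1, 4, 3, 5, np.nan]
        r, _, _ = correlation_ci(x, y)
        r_manual = np.corrcoef([1, 2, 3, 4], [2, 1, 4, 3])[0, 1]
        assert r == pytest.approx(r_manual)

    def test_empirical_coverage_at_rho_zero(self):
        """CI covers rho=0 in about 95% of independent-normal replicates."""
        rng = np.random.default_rng(11)
        n, reps = 60, 2000
        x = rng.standard_normal((reps, n))
        y = rng.standard_normal((reps, n))
        covered = 0
        for i in range(reps):
            _, lo, hi = correlation_ci(x[i], y[i])
            covered += lo <= 0 <= hi
        assert 0.94 <= covered / reps <= 0.96


class TestPotentialForChange:
    def test_forced_positive_case(self):
        # identical vectors force r = 1; room = max - mean = 5 - 7/3
        val = potential_for_change_1([1, 1, 5], [1, 1, 5])
        assert val == pytest.approx(5 - 7 / 3)

    def test_forced_negative_case(self):
        val = potential_for_change_1([1, 1, 5], [5, 5, 1])
        assert val == pytest.approx((1 - 7 / 3) * -1.0)
        assert val >= 0

    def test_pd2_hand_computed_quantile(self):
        # q.95 of (1,1,5) under linear interpolation: index 1.9 -> 1 + 0.9*4 = 4.6
        val = potential_for_change_2([1, 1, 5], [1, 1, 5])
        assert val == pytest.approx(4.6 - 7 / 3)

    def test_zero_correlation_gives_zero(self):
        assert potential_for_change_1([1, 2, 3], [1, 0, 1]) == 0.0
        assert potential_for_change_2([1, 2, 3], [1, 0, 1]) == 0.0

    def test_constant_behaviour_flagged(self):
        with pytest.raises(UndefinedStatisticError):
            potential_for_change_1([1, 2, 3, 4], [2, 2, 2, 2])

    def test_oracle_equivalence_on_random_likert_data(self):
        """Both indices match the brute-force definitions on 1,000 datasets."""
        rng = np.random.default_rng(202)
        for _ in range(1000):
            n = int(rng.integers(10, 60))
            latent = rng.standard_normal(n)
            x = np.clip(np.rint(4 + 1.5 * latent), 1, 7)
            y = np.clip(
                np.rint(3 + 1.2 * (0.5 * latent + rng.standard_normal(n))), 1, 5
            )
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert potential_for_change_1(x, y) == pytest.approx(
                brute_pd1(x, y), abs=1e-12
            )
            assert potential_for_change_2(x, y) == pytest.approx(
                brute_pd2(x, y), abs=1e-12
            )

    def test_pd2_more_outlier_robust_than_pd1(self):
        """Injecting one extreme score moves PΔ2 less than PΔ1."""
        rng = np.random.default_rng(9)
        latent = rng.standard_normal(80)
        x = np.clip(np.rint(4 + 1.3 * latent), 1, 7)
        y = np.clip(np.rint(3 + 1.1 * (0.6 * latent + rng.standard_normal(80))), 1, 5)
        pd1, pd2 = potential_for_change_1(x, y), potential_for_change_2(x, y)
        x_out = np.append(x, 70.0)  # one score at 10x the scale maximum
        y_out = np.append(y, 3.0)
        d1 = abs(potential_for_change_1(x_out, y_out) - pd1)
        d2 = abs(potential_for_change_2(x_out, y_out) - pd2)
        assert d2 < d1

    def test_non_negative_whenever_r_nonzero(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            n = int(rng.integers(8, 40))
            x = rng.integers(1, 8, size=n).astype(float)
            y = rng.integers(1, 6, size=n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert potential_for_change_1(x, y) >= 0
            assert potential_for_change_2(x, y) >= 0


class TestCiberTable:
    def _cohort(self, small_bank, planted, n=2000, seed=12):
        config = SimulationConfig(
            n_respondents=n,
            seed=seed,
            planted_r=planted,
            opt_in_distribution={20: 1.0},
        )
        records, _, truth = simulate_cohort(config, small_bank, compute_manifest=False)
        return records

    def test_planted_item_outranks_null_item_in_all_orderings(self, small_bank):
        records = self._cohort(small_bank, {"item_0": 0.5, "item_1": 0.0})
        results = ciber_table(records, small_bank)
        for key in ("pdelta1", "pdelta2", "r"):
            table = results.sorted_by(key)
            ids = list(table["item_id"])
            assert ids.index("item_0") < ids.index("item_1")

    def test_ceiling_cohort_has_zero_pd1(self, small_bank):
        """Every score at the scale max -> no item spread, PΔ1 = 0 (or skipped)."""
        recs = []
        for i in range(30):
            level = [
                DistanceFrequency.SOMETIMES, DistanceFrequency.OFTEN,
                DistanceFrequency.ALMOST_ALWAYS,
            ][i % 3]
            recs.append(
                make_response(
                    respondent_id=f"r{i}", distance=level,
                    n_items_opted=2, scores={"item_0": 7},
                )
            )
        results = ciber_table(recs, small_bank, min_pairs=10)
        # constant scores: correlation undefined -> reported insufficient/undefined
        assert len(results.summaries) == 0
        assert "item_0" in set(results.insufficient["item_id"])

    def test_scores_all_at_scale_max_give_zero_pd1(self):
        # no spread at the ceiling: r is treated as 0, and mean == max anyway
        vals = np.full(20, 7.0)
        y = np.tile([1, 2, 3, 4, 5], 4).astype(float)
        assert potential_for_change_1(vals, y) == 0.0

    def test_single_item_bank_yields_single_row(self, small_bank):
        records = self._cohort(small_bank, {"item_2": 0.3}, n=200)
        # restrict every record to item_2 only
        for rec in records:
            rec.determinant_scores = {
                k: v for k, v in rec.determinant_scores.items() if k == "item_2"
            }
        results = ciber_table(records, small_bank)
        assert set(results.summaries["item_id"]) == {"item_2"}

    def test_empty_cohort_warns(self, small_bank):
        recs = [make_response(respondent_id=f"r{i}") for i in range(5)]
        with pytest.warns(UserWarning, match="threshold"):
            results = ciber_table(recs, small_bank)
        assert results.summaries.empty

    def test_insufficient_items_reported_not_dropped(self, small_bank):
        records = self._cohort(small_bank, {}, n=30)
        for rec in records[5:]:
            rec.determinant_scores = {}
        results = ciber_table(records, small_bank, min_pairs=10)
        assert len(results.insufficient) > 0


class TestSelectTargets:
    def _frame(self, r_lo, r_hi, mean):
        return pd.DataFrame(
            {
                "r_ci_low": [r_lo], "r_ci_high": [r_hi], "mean": [mean],
            }
        )

    def test_associated_with_room_selected(self):
        out = select_targets(self._frame(0.3, 0.5, 3.0), 1, 7)
        assert out.tolist() == [True]

    def test_ci_spanning_zero_not_selected(self):
        out = select_targets(self._frame(-0.1, 0.2, 3.0), 1, 7)
        assert out.tolist() == [False]

    def test_strong_r_but_no_room_not_selected(self):
        out = select_targets(self._frame(0.4, 0.6, 7.0), 1, 7)
        assert out.tolist() == [False]


class TestCiberPlot:
    def _results(self, small_bank):
        config = SimulationConfig(
            n_respondents=300, seed=4,
            planted_r={"item_0": 0.5, "item_1": 0.4, "item_2": 0.35,
                       "item_3": 0.0, "item_4": 0.0},
            opt_in_distribution={20: 1.0},
        )
        records, _, _ = simulate_cohort(config, small_bank, compute_manifest=False)
        return ciber_table(records, small_bank), records

    def test_five_item_fixture_renders_with_relevant_diamonds_off_zero(
        self, small_bank
    ):
        results, records = self._results(small_bank)
        planted = results.summaries.set_index("item_id")
        for iid in ("item_0", "item_1", "item_2"):
            assert planted.loc[iid, "r_ci_low"] > 0
        fig = ciber_plot(results, records, seed=0)
        assert fig is not None
        import matplotlib.pyplot as plt

        plt.close(fig)

    def test_same_seed_is_byte_identical(self, small_bank):
        results, records = self._results(small_bank)
        blobs = []
        import matplotlib.pyplot as plt

        for _ in range(2):
            fig = ciber_plot(results, records, seed=123)
            buf = io.BytesIO()
            fig.savefig(buf, format="png", metadata={"Software": None})
            blobs.append(buf.getvalue())
            plt.close(fig)
        assert blobs[0] == blobs[1]

    def test_empty_summaries_error(self, small_bank):
        results, records = self._results(small_bank)
        results.summaries = results.summaries.iloc[0:0]
        with pytest.raises(InsufficientDataError, match="nothing to plot"):
            ciber_plot(results, records)


class TestBehaviourVector:
    def test_never_in_public_is_nan(self):
        recs = [
            make_response(respondent_id="a", distance=DistanceFrequency.OFTEN),
            make_response(respondent_id="b", distance=DistanceFrequency.NEVER_IN_PUBLIC),
        ]
        vec = behaviour_vector(recs)
        assert vec[0] == 4.0 and np.isnan(vec[1])
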