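"""Aggregation, fraction of release, Mann-Whitney and bootstrap CIs."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata

from ampero import (
    ParameterError,
    aggregate_cells,
    fraction_bootstrap_ci,
    fraction_of_release,
    group_summary,
    mann_whitney,
)


def _event_frame(cells: dict[str, list[float]]) -> pd.DataFrame:
    rows = []
    for cid, mols in cells.items():
        for m in mols:
            rows.append(
                {
                    "cell_id": cid, "condition": "c", "mode": "sca",
                    "molecules": m, "i_max_pA": 1.0, "t_half_ms": 2.0,
                    "t_rise_ms": 0.5, "t_fall_ms": 1.0,
                }
            )
    return pd.DataFrame(rows)


def brute_force_mw_p(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating every labelling."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1, n2 = a.size, b.size
    mu = n1 * n2 / 2.0

    def u_of(idx):
        ranks = rankdata(pooled)
        r1 = ranks[list(idx)].sum()
        return r1 - n1 * (n1 + 1) / 2.0

    u_obs = u_of(range(n1))
    count = total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        total += 1
        if abs(u_of(idx) - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return u_obs, count / total


class TestAggregateCells:
    def test_single_cell_summary(self):
        cells = aggregate_cells(_event_frame({"a": [100.0, 200.0, 300.0]}))
        row = cells.iloc[0]
        assert row["n_events"] == 3
        assert row["molecules_mean"] == 200.0
        assert row["molecules_median"] == 200.0

    def test_empty_input_gives_empty_frame(self):
        out = aggregate_cells(pd.DataFrame(columns=_event_frame({"a": [1.0]}).columns))
        assert out.empty
        assert "molecules_mean" in out.columns

    def test_cells_ordered_and_nan_shapes_excluded(self):
        df = _event_frame({"b": [10.0, 20.0], "a": [5.0]})
        df.loc[0, "t_half_ms"] = np.nan
        cells = aggregate_cells(df)
        assert list(cells["cell_id"]) == ["a", "b"]
        assert cells.set_index("cell_id").loc["b", "t_half_ms_mean"] == 2.0

    def test_simulated_condition_mean_recovered(self):
        from ampero import SimulationConfig, simulate_condition

        cfg = SimulationConfig(n_cells=20, molecules_mean=105_000.0, seed=321)
        rows = []
        for trace, truth in simulate_condition(cfg, "sca"):
            for m in truth.molecules:
                rows.append({"cell_id": trace.cell_id, "condition": "c", "mode": "sca",
                             "molecules": m, "i_max_pA": 1.0, "t_half_ms": 1.0,
                             "t_rise_ms": 1.0, "t_fall_ms": 1.0})
        cells = aggregate_cells(pd.DataFrame(rows))
        grand = cells["molecules_mean"].mean()
        sem = cells["molecules_mean"].std(ddof=1) / np.sqrt(len(cells))
        assert abs(grand - 105_000.0) < 3 * sem


class TestGroupSummary:
    def test_hand_computed_sem(self):
        mean, sem = group_summary([10.0, 20.0, 30.0])
        assert mean == 20.0
        assert sem == pytest.approx(5.7735, abs=1e-3)

    def test_equal_values_zero_sem(self):
        assert group_summary([4.0, 4.0, 4.0])[1] == 0.0

    def test_single_value_rejected(self):
        with pytest.raises(ParameterError):
            group_summary([1.0])


class TestFractionOfRelease:
    @pytest.mark.parametrize(
        "released,stored,expected",
        [
            (105_000.0, 176_000.0, 60),
            (208_000.0, 299_000.0, 70),
            (103_000.0, 126_000.0, 82),
            (116_000.0, 205_000.0, 57),
        ],
    )
    def test_condition_fractions(self, released, stored, expected):
        pct, rounded = fraction_of_release(released, stored)
        assert rounded == expected
        assert pct == pytest.approx(100.0 * released / stored)

    def test_full_release_is_100(self):
        assert fraction_of_release(5.0, 5.0) == (100.0, 100)

    def test_zero_storage_rejected(self):
        with pytest.raises(ParameterError):
            fraction_of_release(10.0, 0.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(1e-3, 1e6), st.floats(1e-3, 1e6), st.floats(1e-3, 1e3))
    def test_scale_invariance(self, rel, sto, k):
        assert fraction_of_release(k * rel, k * sto)[0] == pytest.approx(
            fraction_of_release(rel, sto)[0], rel=1e-9
        )


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        res = mann_whitney([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.u_statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    def test_identical_samples_p_one(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_u_plus_u_prime(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=6), rng.normal(size=5)
        res_ab = mann_whitney(a, b)
        res_ba = mann_whitney(b, a)
        assert res_ab.u_statistic + res_ba.u_statistic == pytest.approx(30.0)

    def test_exact_p_matches_enumeration_small_sizes(self):
        # spot-check against the brute-force oracle (full sweep in acceptance)
        rng = np.random.default_rng(5)
        for n1, n2 in [(3, 3), (4, 6), (7, 5)]:
            a = rng.normal(size=n1)
            b = rng.normal(0.8, size=n2)
            res = mann_whitney(a, b)
            u_bf, p_bf = brute_force_mw_p(a, b)
            assert res.method == "exact"
            assert res.u_statistic == pytest.approx(u_bf)
            assert res.p_value == pytest.approx(p_bf, rel=1e-9)

    def test_large_or_tied_samples_use_normal_approximation(self):
        rng = np.random.default_rng(1)
        res = mann_whitney(rng.normal(size=25), rng.normal(size=25))
        assert res.method == "normal-approximation"
        res_tied = mann_whitney([1.0, 2.0, 2.0], [2.0, 3.0, 4.0])
        assert res_tied.method == "normal-approximation"

    def test_empty_sample_rejected(self):
        with pytest.raises(ParameterError):
            mann_whitney([], [1.0])


class TestFractionBootstrap:
    def test_degenerate_zero_width(self):
        lo, hi = fraction_bootstrap_ci([3.0, 3.0, 3.0], [6.0, 6.0, 6.0], seed=1)
        assert lo == hi == pytest.approx(50.0)

    def test_bounds_bracket_point_estimate(self):
        rng = np.random.default_rng(2)
        rel = rng.lognormal(np.log(100), 0.2, 17)
        sto = rng.lognormal(np.log(170), 0.2, 17)
        lo, hi = fraction_bootstrap_ci(rel, sto, seed=3)
        point = 100.0 * rel.mean() / sto.mean()
        assert lo <= point <= hi

    def test_deterministic_given_seed(self):
        rel, sto = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        assert fraction_bootstrap_ci(rel, sto, seed=7) == fraction_bootstrap_ci(rel, sto, seed=7)

    def test_coverage_near_nominal(self):
        # nominal 95% within +/- 5 points; 600 replicates of 17-cell groups
        # keep the Monte-Carlo error on the coverage estimate near 1%
        rng = np.random.default_rng(11)
        true_ratio = 100.0 * 105.0 / 176.0
        hits = 0
        n_rep = 600
        for i in range(n_rep):
            rel = rng.lognormal(np.log(105.0) - 0.18**2 / 2, 0.18, 17)
            sto = rng.lognormal(np.log(176.0) - 0.18**2 / 2, 0.18, 17)
            lo, hi = fraction_bootstrap_ci(rel, sto, n_boot=600, seed=1000 + i)
            hits += lo <= true_ratio <= hi
        assert 0.90 <= hits / n_rep <= 1.0
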