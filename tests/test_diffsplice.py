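"""The empirical, expression-matched differential splicing test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spliceflow import (
    BackgroundDistribution,
    ComparisonPlan,
    PsiMatrix,
    build_background,
    compute_psi,
    correct_per_gene,
    diffsplice_multi,
    diffsplice_pair,
    empirical_pvalue,
    enumerate_events,
    nearest_window,
    parse_gtf,
)
from spliceflow.simulate import SimulationConfig, simulate_dataset

from conftest import expr_matrix


def fixture_pipeline(config):
    """Simulate, enumerate and quantify in one go."""
    import os
    import tempfile

    gtf_text, genes, expr, truth = simulate_dataset(config)
    with tempfile.NamedTemporaryFile("w", suffix=".gtf", delete=False) as fh:
        fh.write(gtf_text)
        path = fh.name
    try:
        events = enumerate_events(parse_gtf(path))
    finally:
        os.unlink(path)
    psi = compute_psi(events, expr)
    return events, expr, psi, truth


def bg_from(e, d, window_size=1000):
    e = np.asarray(e, dtype=float)
    d = np.asarray(d, dtype=float)
    order = np.argsort(e, kind="stable")
    return BackgroundDistribution(e_rep=e[order], abs_dpsi=d[order], window_size=window_size)


def brute_force_pvalue(e_sorted, d_sorted, window_size, e_cond, observed):
    """Independent linear-scan implementation of the whole test."""
    diffs = [abs(x - e_cond) for x in e_sorted]
    center = diffs.index(min(diffs))  # first minimum = lowest index
    n = len(e_sorted)
    w = min(window_size, n)
    start = max(0, min(center - (w - 1) // 2, n - w))
    window = d_sorted[start : start + w]
    count = sum(1 for v in window if v <= abs(observed))
    return max((1 - count / w) / 2, 1 / (2 * w))


class TestBuildBackground:
    def _simple(self, psi_rows, design, tpm=10.0):
        """One two-isoform event; PSI values given per sample directly."""
        samples = list(design)
        from test_psi import two_iso_event

        expr = expr_matrix(
            {
                "T1": {s: tpm for s in samples},
                "T2": {s: tpm for s in samples},
            },
            design=design,
        )
        psi = PsiMatrix(
            values=pd.DataFrame([psi_rows], index=[two_iso_event().event_id],
                                columns=samples)
        )
        return psi, expr, [two_iso_event()]

    def test_single_pair_single_point(self):
        design = {"a": ("c1", 1), "b": ("c1", 2)}
        psi, expr, events = self._simple([0.5, 0.7], design)
        bg = build_background(psi, expr, events)
        assert len(bg) == 1
        assert bg.abs_dpsi[0] == pytest.approx(0.2)

    def test_three_replicates_three_pairs(self):
        design = {"a": ("c1", 1), "b": ("c1", 2), "c": ("c1", 3)}
        psi, expr, events = self._simple([0.1, 0.5, 0.9], design)
        bg = build_background(psi, expr, events)
        assert len(bg) == 3

    def test_point_count_scales_with_events_conditions_pairs(self):
        events, expr, psi, _ = fixture_pipeline(
            SimulationConfig(n_genes=100, seed=2, noise_sd=0.05)
        )
        bg = build_background(psi, expr, events)
        # 100 events x 2 conditions x C(3,2) pairs
        assert len(bg) == 600
        assert np.all(np.diff(bg.e_rep) >= 0)

    def test_na_replicates_contribute_no_point(self):
        design = {"a": ("c1", 1), "b": ("c1", 2), "c": ("c1", 3)}
        psi, expr, events = self._simple([0.1, np.nan, 0.9], design)
        bg = build_background(psi, expr, events)
        assert len(bg) == 1  # only the (a, c) pair survives

    def test_error_without_replicated_condition(self):
        design = {"a": ("c1", 1), "b": ("c2", 1)}
        psi, expr, events = self._simple([0.1, 0.9], design)
        with pytest.raises(ValueError, match="replicate variability"):
            build_background(psi, expr, events)


class TestNearestWindow:
    def test_small_background_returns_everything(self):
        bg = bg_from(np.arange(10), np.linspace(0, 1, 10), window_size=1000)
        assert len(nearest_window(bg, 5.0)) == 10

    def test_query_below_minimum_takes_lowest_block(self):
        bg = bg_from(np.arange(10), np.arange(10) / 10, window_size=4)
        window = nearest_window(bg, -100.0)
        assert list(window) == [0.0, 0.1, 0.2, 0.3]

    def test_query_above_maximum_takes_highest_block(self):
        bg = bg_from(np.arange(10), np.arange(10) / 10, window_size=4)
        window = nearest_window(bg, 100.0)
        assert list(window) == [0.6, 0.7, 0.8, 0.9]

    def test_center_minimizes_distance_with_lowest_index_ties(self):
        rng = np.random.default_rng(4)
        e = np.sort(rng.normal(size=5000))
        d = rng.uniform(size=5000)
        bg = bg_from(e, d, window_size=101)
        for q in rng.normal(size=100):
            window = nearest_window(bg, q)
            diffs = np.abs(e - q)
            center = int(np.argmin(diffs))
            start = max(0, min(center - 50, 5000 - 101))
            assert np.array_equal(window, d[start : start + 101])


class TestEmpiricalPvalue:
    WINDOW = np.array([0.1, 0.2, 0.3, 0.4])

    def test_observation_beyond_all_background_hits_floor(self):
        assert empirical_pvalue(0.5, self.WINDOW) == pytest.approx(0.125)

    def test_null_centered_observation(self):
        assert empirical_pvalue(0.0, self.WINDOW) == pytest.approx(0.5)

    def test_median_observation(self):
        assert empirical_pvalue(0.25, self.WINDOW) == pytest.approx(0.25)

    def test_observation_above_one_rejected(self):
        with pytest.raises(ValueError, match="exceed 1"):
            empirical_pvalue(1.5, self.WINDOW)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            empirical_pvalue(0.5, np.array([]))

    @given(
        obs=st.floats(min_value=-1, max_value=1),
        window=st.lists(
            st.floats(min_value=0, max_value=1), min_size=1, max_size=200
        ),
    )
    def test_symmetry_and_range(self, obs, window):
        window = np.array(window)
        p = empirical_pvalue(obs, window)
        assert p == empirical_pvalue(-obs, window)
        n = len(window)
        assert 1 / (2 * n) <= p <= 0.5

    @given(
        pair=st.tuples(
            st.floats(min_value=0, max_value=1), st.floats(min_value=0, max_value=1)
        ),
        window=st.lists(
            st.floats(min_value=0, max_value=1), min_size=1, max_size=200
        ),
    )
    def test_monotone_in_observed_magnitude(self, pair, window):
        lo, hi = sorted(pair)
        window = np.array(window)
        assert empirical_pvalue(hi, window) <= empirical_pvalue(lo, window)

    def test_matches_brute_force_on_random_backgrounds(self):
        rng = np.random.default_rng(123)
        for _ in range(25):
            n = int(rng.integers(5, 2000))
            w = int(rng.integers(1, 1500))
            e = np.sort(rng.normal(size=n))
            d = rng.uniform(size=n)
            bg = bg_from(e, d, window_size=w)
            for _ in range(4):
                q = float(rng.normal())
                obs = float(rng.uniform(-1, 1))
                expected = brute_force_pvalue(list(e), list(d), w, q, obs)
                assert empirical_pvalue(obs, nearest_window(bg, q)) == expected


class TestDiffsplicePair:
    def test_sign_convention_later_minus_earlier(self):
        events, expr, psi, _ = fixture_pipeline(
            SimulationConfig(n_genes=50, seed=5, noise_sd=0.05)
        )
        eid = psi.values.index[0]
        psi.values.loc[eid, expr.samples_of("c1")] = 0.2
        psi.values.loc[eid, expr.samples_of("c2")] = 0.8
        records = diffsplice_pair(psi, expr, events, "c1", "c2")
        assert records.loc[eid, "dpsi"] == pytest.approx(0.6)

    def test_no_change_gives_half_pvalue(self):
        events, expr, psi, _ = fixture_pipeline(
            SimulationConfig(n_genes=100, seed=6, noise_sd=0.05)
        )
        eid = psi.values.index[0]
        psi.values.loc[eid, :] = 0.5  # identical in both conditions
        records = diffsplice_pair(psi, expr, events, "c1", "c2")
        assert records.loc[eid, "dpsi"] == pytest.approx(0.0)
        # continuous noise: the only zero-valued background points are the
        # six replicate pairs this very event contributes, so p sits just
        # below the theoretical 0.5 of a continuous null
        assert 0.49 <= records.loc[eid, "pvalue"] <= 0.5

    def test_planted_changes_recovered(self):
        events, expr, psi, truth = fixture_pipeline(
            SimulationConfig(n_genes=500, seed=7, noise_sd=0.05)
        )
        records = diffsplice_pair(psi, expr, events, "c1", "c2")
        t = truth.reset_index().set_index("event_id")
        planted = t.loc[records.index, "planted_dpsi"].to_numpy()
        r = np.corrcoef(records["dpsi"].to_numpy(), planted)[0, 1]
        assert r > 0.9

    def test_all_na_condition_reported_as_nan(self):
        events, expr, psi, _ = fixture_pipeline(
            SimulationConfig(n_genes=50, seed=8, noise_sd=0.05)
        )
        eid = psi.values.index[3]
        psi.values.loc[eid, expr.samples_of("c2")] = np.nan
        records = diffsplice_pair(psi, expr, events, "c1", "c2")
        assert np.isnan(records.loc[eid, "dpsi"])
        assert np.isnan(records.loc[eid, "pvalue"])
        assert not records.loc[eid, "significant"]


def stepup_bh(pvalues):
    """Independent Benjamini-Hochberg step-up implementation."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


class TestCorrectPerGene:
    def _records(self, genes, pvals):
        return pd.DataFrame(
            {
                "gene_id": genes,
                "dpsi": 0.0,
                "e_cond": 0.0,
                "pvalue": pvals,
                "adj_pvalue": np.nan,
                "significant": False,
                "n_background": 10,
            },
            index=[f"e{i}" for i in range(len(genes))],
        )

    def test_single_event_gene_is_identity(self):
        out = correct_per_gene(self._records(["g1"], [0.03]))
        assert out["adj_pvalue"].iloc[0] == pytest.approx(0.03)

    def test_hand_computed_bh(self):
        out = correct_per_gene(self._records(["g"] * 3, [0.01, 0.02, 0.04]))
        assert list(out["adj_pvalue"].round(10)) == [0.03, 0.03, 0.04]

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in rng.integers(0, 10, size=100)]
        out = correct_per_gene(self._records(genes, rng.uniform(size=100)))
        assert (out["adj_pvalue"] >= out["pvalue"] - 1e-12).all()

    def test_matches_stepup_oracle_gene_wise(self):
        rng = np.random.default_rng(10)
        genes = [f"g{i}" for i in rng.integers(0, 50, size=300)]
        pvals = rng.uniform(size=300)
        out = correct_per_gene(self._records(genes, pvals))
        df = out.assign(raw=pvals)
        for gene, sub in df.groupby("gene_id"):
            expected = stepup_bh(sub["raw"].to_numpy())
            assert np.allclose(sub["adj_pvalue"].to_numpy(), expected)

    def test_invalid_fdr_rejected(self):
        with pytest.raises(ValueError, match="fdr"):
            correct_per_gene(self._records(["g"], [0.5]), fdr=1.5)


class TestMultiCondition:
    def test_default_plan_chains_consecutive_conditions(self):
        events, expr, psi, _ = fixture_pipeline(
            SimulationConfig(n_genes=60, n_conditions=4, seed=12, noise_sd=0.05)
        )
        results = diffsplice_multi(psi, expr, events)
        assert list(results) == [("c1", "c2"), ("c2", "c3"), ("c3", "c4")]

    def test_explicit_pair_plan(self):
        events, expr, psi, _ = fixture_pipeline(
            SimulationConfig(n_genes=60, n_conditions=3, seed=13, noise_sd=0.05)
        )
        plan = ComparisonPlan(conditions=("c1", "c2", "c3"), pairs=(("c1", "c3"),))
        results = diffsplice_multi(psi, expr, events, plan=plan)
        assert list(results) == [("c1", "c3")]

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError, match="unknown condition"):
            ComparisonPlan(conditions=("c1", "c2"), pairs=(("c1", "cX"),))

    def test_composition_equals_pairwise_calls(self):
        events, expr, psi, _ = fixture_pipeline(
            SimulationConfig(n_genes=60, n_conditions=4, seed=14, noise_sd=0.05)
        )
        results = diffsplice_multi(psi, expr, events)
        for (c1, c2), table in results.items():
            alone = diffsplice_pair(psi, expr, events, c1, c2)
            pd.testing.assert_frame_equal(table, alone)


class TestNullCalibration:
    def test_false_positive_fraction_bounded_without_planted_signal(self):
        events, expr, psi, truth = fixture_pipeline(
            SimulationConfig(n_genes=400, positive_fraction=0.0, seed=15, noise_sd=0.1)
        )
        records = diffsplice_pair(psi, expr, events, "c1", "c2", correct=False)
        p = records["pvalue"].dropna().to_numpy()
        n = len(p)
        for alpha in (0.01, 0.05):
            se = np.sqrt(alpha * (1 - alpha) / n)
            assert (p < alpha).mean() <= alpha + 3 * se
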