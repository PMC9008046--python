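"""Permutation tests, FDR adjustment, group comparison and correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import eegraph as eg
from eegraph.io import UndefinedCorrelationError

from _oracles import bh_adjust, permutation_p


class TestPermutationTest:
    def test_identical_groups_give_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        obs, p = eg.permutation_test(a, a)
        assert obs == 0.0
        assert p == 1.0

    def test_exhaustive_2_2_matches_enumeration(self):
        a, b = [1.0, 2.0], [5.0, 7.0]
        obs, p = eg.permutation_test(a, b)  # C(4,2)=6 -> exhaustive
        o_obs, o_p = permutation_p(a, b)
        assert obs == pytest.approx(o_obs)
        assert p == o_p
        assert p == pytest.approx(2 / 6)  # only the true split and its mirror

    def test_exhaustive_4_4_matches_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a, b = rng.normal(size=4), rng.normal(1.0, 1.0, size=4)
            obs, p = eg.permutation_test(a, b)
            o_obs, o_p = permutation_p(a, b)
            assert (obs, p) == pytest.approx((o_obs, o_p))

    def test_sampled_close_to_exact(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=4), rng.normal(0.8, 1.0, size=4)
        _, p_exact = eg.permutation_test(a, b)
        _, p_samp = eg.permutation_test(a, b, n_perm=5000, rng=2, exhaustive=False)
        se = np.sqrt(p_exact * (1 - p_exact) / 5000)
        assert abs(p_samp - p_exact) < 4 * se + 1 / 5001

    def test_extreme_shift_hits_minimum_attainable_p(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=20)
        b = a + 100.0
        _, p = eg.permutation_test(a, b, n_perm=500, rng=0)
        assert p == pytest.approx(1 / 501)

    def test_seed_determinism_and_group_size_guard(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=20), rng.normal(size=20)
        r1 = eg.permutation_test(a, b, n_perm=200, rng=7)
        r2 = eg.permutation_test(a, b, n_perm=200, rng=7)
        assert r1 == r2
        with pytest.raises(ValueError):
            eg.permutation_test([1.0], [2.0, 3.0])


class TestFDR:
    def test_single_p_unchanged(self):
        assert eg.fdr_adjust([0.03]) == pytest.approx([0.03])

    def test_all_equal_fixed_point(self):
        np.testing.assert_allclose(eg.fdr_adjust([0.2] * 5), [0.2] * 5)

    def test_known_vector_step_up(self):
        p = [0.005, 0.01, 0.03, 0.04]
        # step-up: p_(i) * m / i with running minima from the largest rank
        expected = [0.02, 0.02, 0.04, 0.04]
        np.testing.assert_allclose(eg.fdr_adjust(p), expected)
        np.testing.assert_allclose(eg.fdr_adjust(p), bh_adjust(p))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=30)
    )
    def test_matches_direct_formula_and_invariants(self, pvals):
        adj = eg.fdr_adjust(pvals)
        np.testing.assert_allclose(adj, bh_adjust(pvals), atol=1e-12)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            eg.fdr_adjust([])
        with pytest.raises(ValueError):
            eg.fdr_adjust([0.0, 0.5])


def _toy_metrics_and_covariates(rng, n_per_group=6, shift=0.0):
    rows = []
    cov = []
    for g, label in enumerate("AB"):
        for i in range(n_per_group):
            sid = f"{label}{i}"
            cov.append({"subject_id": sid, "group": label, "sex": i % 2, "mmse": 27.0})
            for measure in ("modularity", "radius"):
                for band in ("beta", "gamma"):
                    val = rng.normal() + (shift if (g == 1 and measure == "modularity" and band == "beta") else 0.0)
                    rows.append(
                        {"subject_id": sid, "band": band, "measure": measure, "value": val}
                    )
    return pd.DataFrame(rows), eg.CovariateTable(pd.DataFrame(cov))


class TestCompareGroups:
    def test_output_shape_and_flags(self, fast_config):
        rng = np.random.default_rng(0)
        metrics, cov = _toy_metrics_and_covariates(rng, shift=5.0)
        out = eg.compare_groups(metrics, cov, fast_config)
        assert len(out) == 4  # 2 measures x 2 bands
        assert set(out.columns) >= {
            "measure", "band", "mean_A", "mean_B", "observed_diff",
            "p_perm", "p_fdr", "significant",
        }
        assert np.all((out["p_perm"] > 0) & (out["p_perm"] <= 1))
        assert np.all(out["p_fdr"] >= out["p_perm"] - 1e-15)
        assert (out["significant"] == (out["p_fdr"] < fast_config.fdr_level)).all()
        row = out.set_index(["measure", "band"]).loc[("modularity", "beta")]
        assert row["significant"]
        assert row["observed_diff"] == pytest.approx(row["mean_A"] - row["mean_B"])
        assert row["observed_diff"] < 0  # B was shifted up

    def test_full_cohort_has_sixty_rows(self, fast_config, small_cohort):
        _, subjects, cov = small_cohort
        graphs = [(s.subject_id, eg.subject_connectivity(s)) for s in subjects]
        metrics = eg.metrics_table(graphs, fast_config, seed=0)
        out = eg.compare_groups(metrics, cov, fast_config)
        assert len(out) == 60
        assert out[["mean_A", "mean_B", "observed_diff", "p_perm", "p_fdr"]].notna().all().all()

    def test_seed_determinism(self, fast_config):
        rng = np.random.default_rng(1)
        metrics, cov = _toy_metrics_and_covariates(rng)
        out1 = eg.compare_groups(metrics, cov, fast_config, seed=9)
        out2 = eg.compare_groups(metrics, cov, fast_config, seed=9)
        pd.testing.assert_frame_equal(out1, out2)

    def test_missing_covariates_rejected(self, fast_config):
        rng = np.random.default_rng(2)
        metrics, cov = _toy_metrics_and_covariates(rng)
        with pytest.raises(ValueError, match="without covariates"):
            eg.compare_groups(metrics, eg.CovariateTable(cov.frame.iloc[:-1]), fast_config)


class TestCorrelate:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        metrics = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(10)], "band": "gamma",
             "measure": "radius", "value": x}
        )
        cov = eg.CovariateTable(pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(10)], "group": ["A"] * 5 + ["B"] * 5,
             "sex": 0, "mmse": 25.0, "score": 2 * x + 1}
        ))
        out = eg.correlate(metrics, cov, pairs=[("radius", "gamma")])
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert out.loc[0, "p"] < 1e-10

    def test_independent_near_zero(self):
        rng = np.random.default_rng(3)
        n = 2000
        metrics = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(n)], "band": "beta",
             "measure": "modularity", "value": rng.normal(size=n)}
        )
        cov = eg.CovariateTable(pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(n)], "group": "A",
             "sex": 0, "mmse": 25.0, "score": rng.normal(size=n)}
        ))
        out = eg.correlate(metrics, cov)
        assert abs(out.loc[0, "r"]) < 0.07

    def test_constant_vector_rejected(self):
        metrics = pd.DataFrame(
            {"subject_id": ["a", "b", "c"], "band": "beta",
             "measure": "modularity", "value": [1.0, 1.0, 1.0]}
        )
        cov = eg.CovariateTable(pd.DataFrame(
            {"subject_id": ["a", "b", "c"], "group": "A", "sex": 0,
             "mmse": 25.0, "score": [0.1, 0.5, 0.2]}
        ))
        with pytest.raises(UndefinedCorrelationError):
            eg.correlate(metrics, cov)

    def test_loading_sign_recovered_from_synthetic_cohort(self, fast_config):
        """Scores generated with a negative beta-band loading correlate
        negatively with beta-band modularity."""
        hits = 0
        for rep in range(5):
            cfg = eg.SyntheticCohortConfig(
                n_per_group=20, seed=300 + rep, coupling_jitter_sd=0.08,
                score_loadings={"semantic": ("beta", -1.0)}, score_noise_sd=0.5,
            )
            subjects, cov = eg.generate_cohort(cfg)
            graphs = [(s.subject_id, eg.subject_connectivity(s, [cfg.bands[3]]))
                      for s in subjects]
            metrics = eg.metrics_table(graphs, fast_config, seed=rep)
            out = eg.correlate(metrics, cov, pairs=[("modularity", "beta")],
                               scores=["semantic"])
            hits += out.loc[0, "r"] < 0
        assert hits >= 4


def test_demographics_summary():
    rng = np.random.default_rng(4)
    cov = eg.CovariateTable(pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(40)],
        "group": ["A"] * 20 + ["B"] * 20,
        "sex": rng.integers(0, 2, 40),
        "mmse": np.r_[rng.normal(26, 2, 20), rng.normal(22, 2, 20)],
        "recall": rng.normal(size=40),
    }))
    out = eg.demographics_summary(cov)
    assert set(out["variable"]) == {"mmse", "recall"}
    assert out.set_index("variable").loc["mmse", "p"] < 0.01
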