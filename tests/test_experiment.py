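"""Scaling-experiment orchestration, regression and raw/CBF comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kmerpop import (
    ExperimentConfig,
    compare_raw_cbf,
    plateau_check,
    regress_scores,
    run_experiment,
)
from kmerpop.experiment import RECORD_COLUMNS


def tiny_config(**overrides) -> ExperimentConfig:
    base = dict(
        thetas=[0.001, 0.005, 0.02],
        replicates=1,
        L=2000,
        n=4,
        ploidy=2,
        ks=(10,),
        coverages=(10.0,),
        threshold=5,
        metrics=("braycurtis", "cosine"),
        read_length=100,
        error_rate=0.001,
        cbf_m=2000,
        cbf_h=2,
        cbf_seed=1,
        use_cbf=True,
        pi_max=0.025,
        seed=101,
    )
    base.update(overrides)
    return ExperimentConfig(**base)


def synthetic_records(x, y, metric="cosine", k=10, coverage=30.0, pipeline="raw"):
    return pd.DataFrame({
        "replicate": 0,
        "theta": x,
        "pi_per_site": x,
        "pi_count": np.asarray(x) * 1000,
        "k": k,
        "coverage": coverage,
        "metric": metric,
        "pipeline": pipeline,
        "score": y,
    })[RECORD_COLUMNS]


@pytest.fixture(scope="module")
def tiny_records():
    return run_experiment(tiny_config())


class TestRunExperiment:
    @pytest.fixture
    def records(self, tiny_records):
        return tiny_records

    def test_record_bookkeeping(self, records):
        # per (replicate, theta, k, coverage): braycurtis + cosine raw + cosine cbf
        assert len(records) == 1 * 3 * 1 * 1 * 3
        assert list(records.columns) == RECORD_COLUMNS
        assert set(records["pipeline"]) == {"raw", "cbf"}
        assert records["score"].between(0, 1).all()
        assert (records["pi_per_site"] >= 0).all()

    def test_end_to_end_determinism(self, records):
        again = run_experiment(tiny_config())
        pd.testing.assert_frame_equal(records, again)

    def test_zero_theta_error_free_scores(self):
        """Identical genomes with error-free reads: key sets coincide, so
        Jaccard is exactly 0; count-based metrics keep only the small
        Poisson coverage-noise floor."""
        config = tiny_config(thetas=[0.0], error_rate=0.0, use_cbf=False,
                             metrics=("jaccard", "cosine"), threshold=0)
        records = run_experiment(config)
        jac = records[records["metric"] == "jaccard"]["score"]
        cos = records[records["metric"] == "cosine"]["score"]
        # a handful of under-covered sequence-end k-mers keep Jaccard
        # marginally above zero even without errors or variation
        assert (jac < 0.01).all()
        assert (cos < 0.1).all()

    def test_scores_grow_from_low_to_high_diversity(self, records):
        sel = records[(records["metric"] == "braycurtis")].sort_values("theta")
        assert sel["score"].iloc[-1] > sel["score"].iloc[0]


class TestRegression:
    def test_collinear_records_give_r2_one(self):
        x = np.linspace(0.001, 0.02, 10)
        records = synthetic_records(x, 3 * x + 0.05)
        fit = regress_scores(records, "cosine", 10, 30.0, pi_max=0.025)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(3.0)
        assert fit.intercept == pytest.approx(0.05)

    def test_zero_score_variance_rejected(self):
        x = np.linspace(0.001, 0.02, 10)
        records = synthetic_records(x, np.full_like(x, 0.3))
        with pytest.raises(ValueError):
            regress_scores(records, "cosine", 10, 30.0, pi_max=0.025)

    def test_needs_three_points_in_range(self):
        records = synthetic_records([0.001, 0.002], [0.1, 0.2])
        with pytest.raises(ValueError):
            regress_scores(records, "cosine", 10, 30.0, pi_max=0.025)

    def test_r2_matches_direct_sums(self, rng):
        x = rng.uniform(0.001, 0.02, size=25)
        y = 2 * x + rng.normal(0, 0.01, size=25)
        records = synthetic_records(x, y)
        fit = regress_scores(records, "cosine", 10, 30.0, pi_max=0.025)
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_res = np.sum(resid**2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert fit.r_squared == pytest.approx(1 - ss_res / ss_tot)

    def test_pi_max_restricts_points(self):
        x = np.concatenate([np.linspace(0.001, 0.02, 10), [0.05, 0.08]])
        records = synthetic_records(x, 2 * x)
        fit = regress_scores(records, "cosine", 10, 30.0, pi_max=0.025)
        assert fit.n_points == 10
        assert fit.pi_range[1] <= 0.025


class TestPlateau:
    def test_saturating_curve_ratio_near_zero(self):
        x = np.linspace(0.001, 0.1, 40)
        # saturates at pi = 0.025 up to a faint residual tilt
        y = np.minimum(20 * x, 0.5) + 0.05 * x
        records = synthetic_records(x, y)
        ratio = plateau_check(records, "cosine", 10, 30.0)
        assert abs(ratio) < 0.05

    def test_linear_records_ratio_near_one(self):
        x = np.linspace(0.001, 0.1, 40)
        records = synthetic_records(x, 2 * x + 0.01)
        ratio = plateau_check(records, "cosine", 10, 30.0)
        assert ratio == pytest.approx(1.0, abs=1e-6)

    def test_insufficient_points_rejected(self):
        records = synthetic_records([0.001, 0.005, 0.01], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            plateau_check(records, "cosine", 10, 30.0)


class TestCompareRawCbf:
    def test_identical_pipelines_give_zero_difference(self):
        x = np.linspace(0.001, 0.02, 12)
        y = 2 * x + np.sin(x * 1000) * 0.001
        records = pd.concat([
            synthetic_records(x, y, pipeline="raw"),
            synthetic_records(x, y, pipeline="cbf"),
        ], ignore_index=True)
        cmp = compare_raw_cbf(records, 10, 30.0, pi_max=0.025)
        assert cmp.r_squared_difference == pytest.approx(0.0, abs=1e-12)
        assert cmp.spearman_rho == pytest.approx(1.0)

    def test_missing_pipeline_rejected(self):
        x = np.linspace(0.001, 0.02, 12)
        records = synthetic_records(x, 2 * x, pipeline="raw")
        with pytest.raises(ValueError):
            compare_raw_cbf(records, 10, 30.0, pi_max=0.025)


class TestConfigIO:
    def test_json_and_yaml_round_trip(self, tmp_path):
        import json

        import yaml

        config = tiny_config()
        jpath = tmp_path / "config.json"
        jpath.write_text(json.dumps(config.to_dict()))
        ypath = tmp_path / "config.yaml"
        ypath.write_text(yaml.safe_dump(config.to_dict()))
        for path in (jpath, ypath):
            loaded = ExperimentConfig.from_file(path)
            assert loaded.to_dict() == config.to_dict()

    def test_validation(self):
        with pytest.raises(ValueError):
            tiny_config(thetas=[])
        with pytest.raises(ValueError):
            tiny_config(pi_max=0.9)
        with pytest.raises(ValueError):
            tiny_config(replicates=0)


@pytest.fixture(scope="module")
def robustness_records():
    config = ExperimentConfig(
        thetas=list(np.linspace(0.004, 0.1, 10)),
        L=4000, n=6, ploidy=2,
        ks=(10, 30), coverages=(10.0, 30.0), threshold=5,
        metrics=("braycurtis",), read_length=100, error_rate=0.001,
        use_cbf=False, seed=321,
    )
    return run_experiment(config)


class TestRobustnessAcrossSettings:
    """Coverage and short-k behavior of the score-pi relationship."""

    @pytest.fixture
    def records(self, robustness_records):
        return robustness_records

    def test_low_and_high_coverage_rank_scores_alike(self, records):
        sel = records[(records["metric"] == "braycurtis") & (records["k"] == 30)]
        low = sel[sel["coverage"] == 10.0].groupby("theta")["score"].mean()
        high = sel[sel["coverage"] == 30.0].groupby("theta")["score"].mean()
        rho = stats.spearmanr(low, high).statistic
        assert rho >= 0.9

    def test_short_k_stays_monotone_to_pi_point_one(self, records):
        sel = records[(records["metric"] == "braycurtis") & (records["k"] == 10)
                      & (records["coverage"] == 30.0)]
        rho = stats.spearmanr(sel["pi_per_site"], sel["score"]).statistic
        assert rho >= 0.9
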