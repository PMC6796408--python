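import math

import numpy as np
import pandas as pd
import pytest

import cardiosem as cs
from cardiosem.moments import MomentValidationError


class TestStudyFixtures:
    def test_loads_fourteen_variables(self, moments):
        assert moments.p == 14
        assert moments.n == 227
        assert moments.variable_names[0] == "AGE"
        assert moments.variable_names[-1] == "DBP"

    def test_printed_descriptives(self, moments):
        i = moments.index("AGE")
        assert moments.means[i] == pytest.approx(39.4)
        assert moments.sds[i] == pytest.approx(9.8)

    def test_printed_correlations(self, moments):
        r = moments.correlations
        assert r[moments.index("SBP"), moments.index("DBP")] == pytest.approx(0.66)
        assert r[moments.index("WC"), moments.index("BMI")] == pytest.approx(0.89)

    def test_derived_binary_and_categorical_cells(self, moments):
        # the ASA and SMOKE moments are not printed directly; the fixture
        # stores values derived from the printed prevalence and counts
        prev = 88 / 227
        assert moments.means[moments.index("ASA")] == pytest.approx(prev, abs=1e-6)
        assert moments.sds[moments.index("ASA")] == pytest.approx(
            cs.binary_sd(prev), abs=1e-6
        )
        mean, sd = cs.categorical_moments(
            {"never": 75, "past": 68, "current": 84},
            {"never": 0, "past": 1, "current": 2},
        )
        assert moments.means[moments.index("SMOKE")] == pytest.approx(mean, abs=1e-6)
        assert moments.sds[moments.index("SMOKE")] == pytest.approx(sd, abs=1e-6)

    def test_fixture_matrix_is_positive_definite(self, moments):
        w = np.linalg.eigvalsh(moments.correlations)
        assert w.min() > 0
        repaired = cs.nearest_pd(moments.correlations)
        assert np.abs(repaired - moments.correlations).max() < 0.01


class TestValidation:
    def test_correlation_out_of_bounds(self, tmp_path):
        d = tmp_path / "d.csv"
        c = tmp_path / "c.csv"
        d.write_text("variable,mean,sd,n\na,0,1,50\nb,0,1,50\n")
        c.write_text("variable,a,b\na,1.0,1.2\nb,1.2,1.0\n")
        with pytest.raises(MomentValidationError, match="outside"):
            cs.load_moments(d, c)

    def test_asymmetric_matrix(self, tmp_path):
        d = tmp_path / "d.csv"
        c = tmp_path / "c.csv"
        d.write_text("variable,mean,sd,n\na,0,1,50\nb,0,1,50\n")
        c.write_text("variable,a,b\na,1.0,0.3\nb,0.5,1.0\n")
        with pytest.raises(MomentValidationError, match="asymmetric"):
            cs.load_moments(d, c)

    def test_missing_variable(self, tmp_path):
        d = tmp_path / "d.csv"
        c = tmp_path / "c.csv"
        d.write_text("variable,mean,sd,n\na,0,1,50\n")
        c.write_text("variable,a,b\na,1.0,0.3\nb,0.3,1.0\n")
        with pytest.raises(MomentValidationError, match="'b'"):
            cs.load_moments(d, c)

    def test_missing_sd(self, tmp_path):
        d = tmp_path / "d.csv"
        c = tmp_path / "c.csv"
        d.write_text("variable,mean,sd,n\na,0,1,50\nb,0,,50\n")
        c.write_text("variable,a,b\na,1.0,0.3\nb,0.3,1.0\n")
        with pytest.raises(MomentValidationError, match="SD"):
            cs.load_moments(d, c)

    def test_sample_size_too_small(self):
        with pytest.raises(MomentValidationError, match="sample size"):
            cs.MomentSet(("a", "b"), np.zeros(2), np.ones(2), np.eye(2), n=2)


@pytest.mark.parametrize(
    "prevalence, expected",
    [(0.5, 0.5), (0.388, math.sqrt(0.388 * 0.612)), (0.01, math.sqrt(0.01 * 0.99))],
)
def test_binary_sd(prevalence, expected):
    assert cs.binary_sd(prevalence) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
def test_binary_sd_domain(bad):
    with pytest.raises(ValueError):
        cs.binary_sd(bad)


class TestCategoricalMoments:
    def test_symmetric_binary(self):
        mean, sd = cs.categorical_moments({"a": 10, "b": 10}, {"a": 0, "b": 1})
        assert (mean, sd) == (0.5, 0.5)

    def test_study_smoking_counts(self):
        # population divisor: mean 236/227, variance 404/227 - mean^2
        mean, sd = cs.categorical_moments(
            {"never": 75, "past": 68, "current": 84},
            {"never": 0, "past": 1, "current": 2},
        )
        assert mean == pytest.approx(236 / 227, rel=1e-12)
        assert sd == pytest.approx(math.sqrt(404 / 227 - (236 / 227) ** 2), rel=1e-12)

    def test_single_category(self):
        mean, sd = cs.categorical_moments({"only": 7}, {"only": 3.0})
        assert (mean, sd) == (3.0, 0.0)

    def test_empty_counts(self):
        with pytest.raises(ValueError):
            cs.categorical_moments({}, {})


class TestToCovariance:
    def test_identity_correlations(self):
        m = cs.MomentSet(("a", "b"), np.zeros(2), np.array([2.0, 3.0]), np.eye(2), 50)
        assert np.allclose(cs.to_covariance(m), np.diag([4.0, 9.0]))

    def test_standardized_abuse_covariances(self, moments):
        cov = cs.to_covariance(moments, standardize=cs.ABUSE_INDICATORS)
        i, j = moments.index("CTQ"), moments.index("ISA")
        assert cov[i, j] == pytest.approx(0.34)
        assert cov[i, i] == pytest.approx(1.0)

    def test_raw_metric_covariance(self, moments):
        cov = cs.to_covariance(moments)
        i, j = moments.index("SBP"), moments.index("DBP")
        assert cov[i, j] == pytest.approx(0.66 * 15.5 * 9.5)

    def test_unknown_identifier(self, moments):
        with pytest.raises(ValueError, match="unknown"):
            cs.to_covariance(moments, standardize=("NOPE",))

    def test_round_trip_through_sample_statistics(self):
        rng = np.random.default_rng(42)
        X = rng.standard_normal((400, 4)) @ rng.standard_normal((4, 4))
        m = cs.MomentSet(
            ("a", "b", "c", "d"),
            X.mean(axis=0),
            X.std(axis=0, ddof=1),
            np.corrcoef(X, rowvar=False),
            400,
        )
        assert np.allclose(cs.to_covariance(m), np.cov(X, rowvar=False), rtol=1e-10)


class TestNearestPd:
    def test_identity_unchanged(self):
        assert np.array_equal(cs.nearest_pd(np.eye(3)), np.eye(3))

    def test_degenerate_correlation_is_shrunk(self):
        A = np.array([[1.0, 1.0], [1.0, 1.0]])
        out = cs.nearest_pd(A, eigen_floor=1e-6)
        assert abs(out[0, 1]) < 1.0
        assert np.linalg.eigvalsh(out).min() > 0

    def test_idempotent(self):
        A = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, -0.9], [0.9, -0.9, 1.0]])
        once = cs.nearest_pd(A, eigen_floor=1e-6)
        twice = cs.nearest_pd(once, eigen_floor=1e-6)
        assert np.allclose(once, twice, atol=1e-12)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            cs.nearest_pd(np.array([[1.0, 0.5], [0.2, 1.0]]))


def test_save_load_round_trip(tmp_path, moments):
    d = tmp_path / "desc.csv"
    c = tmp_path / "corr.csv"
    moments.save(d, c)
    back = cs.load_moments(d, c)
    assert back.variable_names == moments.variable_names
    assert back.n == moments.n
    assert np.allclose(back.means, moments.means)
    assert np.allclose(back.sds, moments.sds)
    assert np.allclose(back.correlations, moments.correlations)
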