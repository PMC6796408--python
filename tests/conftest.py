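import numpy as np
import pytest

import cardiosem as cs


@pytest.fixture(scope="session")
def moments():
    return cs.study_moments()


@pytest.fixture(scope="session")
def whes():
    return cs.build_whes_model()


@pytest.fixture(scope="session")
def study():
    """The full published-model fit (with standard errors), computed once."""
    return cs.fit_study()


@pytest.fixture(scope="session")
def mini_model():
    """Two 2-indicator latents with one regression; fixed error variances.

    Small enough for closed-form checks: F1 =~ x1 (1) + x2 (lambda free),
    F2 =~ y1 (1) + y2 (1), F2 ~ F1; all error variances fixed at 0.5.
    """
    V = cs.VariableDef
    P = cs.PathSpec
    variables = (
        V("x1", "observed"), V("x2", "observed"),
        V("y1", "observed"), V("y2", "observed"),
        V("F1", "latent", "exogenous"), V("F2", "latent"),
    )
    paths = (
        P("F1", "x1", "directed", "fixed", 1.0),
        P("F1", "x2", "directed", "free", label="F1=~x2"),
        P("F2", "y1", "directed", "fixed", 1.0),
        P("F2", "y2", "directed", "fixed", 1.0),
        P("F1", "F2", "directed", "free", label="F2~F1"),
        P("F1", "F1", "covariance", "free", label="F1~~F1"),
        P("F2", "F2", "covariance", "free", label="F2~~F2"),
        P("x1", "x1", "covariance", "fixed", 0.5),
        P("x2", "x2", "covariance", "fixed", 0.5),
        P("y1", "y1", "covariance", "fixed", 0.5),
        P("y2", "y2", "covariance", "fixed", 0.5),
    )
    return cs.ModelSpec(variables, paths)


@pytest.fixture(scope="session")
def mini_truth():
    return {"F1=~x2": 0.8, "F2~F1": 0.6, "F1~~F1": 2.0, "F2~~F2": 1.0}


def moments_from_cov(cov, n=1000, names=None, means=None):
    """Build a MomentSet carrying an exact covariance matrix."""
    cov = np.asarray(cov, float)
    p = cov.shape[0]
    names = names or tuple(f"v{i}" for i in range(p))
    sds = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sds, sds)
    np.fill_diagonal(corr, 1.0)
    return cs.MomentSet(
        variable_names=tuple(names),
        means=np.zeros(p) if means is None else np.asarray(means, float),
        sds=sds,
        correlations=corr,
        n=n,
    )


@pytest.fixture(scope="session")
def exact_moments_for(mini_model, mini_truth):
    """MomentSet whose covariance is exactly the mini model's implied one."""
    cov = cs.implied_covariance(mini_model, mini_truth)
    return moments_from_cov(cov, n=500, names=mini_model.observed_names)
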