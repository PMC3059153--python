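import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.optimize import minimize

from unifyexpr import fa_core

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def negative_discrepancy(lam: np.ndarray, R: np.ndarray, psi_floor: float = 1e-3) -> float:
    """-2/n times the profile log-likelihood (up to constants): the objective
    a direct optimizer minimizes over loadings with psi = 1 - lambda^2."""
    psi = np.clip(1.0 - lam**2, psi_floor, 1.0)
    a = lam / psi
    c = 1.0 + lam @ a
    return float(np.sum(np.log(psi)) + np.log(c) + np.sum(np.diag(R) / psi) - (a @ R @ a) / c)


def direct_ml_loadings(R: np.ndarray, psi_floor: float = 1e-3) -> np.ndarray:
    """Independent likelihood oracle: multi-start bounded quasi-Newton
    maximization of the same Gaussian likelihood the EM fit maximizes,
    parameterized by the loadings alone."""
    p = R.shape[0]
    cap = np.sqrt(1.0 - psi_floor)
    w, v = np.linalg.eigh(R)
    starts = [
        np.sign(v[:, -1]) * 0.5,
        np.clip(v[:, -1] * np.sqrt(max(w[-1], 0.0)), -0.9, 0.9),
        np.full(p, 0.3),
    ]
    best = None
    for s in starts:
        res = minimize(
            negative_discrepancy,
            s,
            args=(R, psi_floor),
            method="L-BFGS-B",
            bounds=[(-cap, cap)] * p,
            options=dict(ftol=1e-15, gtol=1e-12, maxiter=5000),
        )
        if best is None or res.fun < best.fun:
            best = res
    lam = best.x
    return lam if lam.sum() >= 0 else -lam


@pytest.fixture
def direct_ml():
    return direct_ml_loadings


@pytest.fixture
def rng_factory():
    return np.random.default_rng


@pytest.fixture
def strong_factor_data():
    """p=3 dataset with a clear single-factor structure."""
    from unifyexpr import simulator

    rng = np.random.default_rng(12345)
    y, f = simulator.simulate_from_loadings([0.9, 0.85, 0.7], 300, rng)
    return fa_core.standardize(y), f
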