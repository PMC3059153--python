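"""Single-gene maximum-likelihood single-factor analysis.

A gene measured on ``p`` platforms (or probes) across ``n`` samples is modelled
as

    y = lambda * f + e,    f ~ N(0, 1),    e ~ N(0, Psi),

where ``f`` is the latent per-sample expression level (the common factor),
``lambda`` is the vector of loadings and ``Psi`` is diagonal.  The observed
rows are standardized to mean 0 / variance 1, so the implied covariance

    Sigma = lambda lambda' + Psi

is a correlation matrix with unit diagonal, i.e. ``psi_j = 1 - lambda_j**2``
and each loading is the correlation between platform ``j`` and the factor.

The maximum-likelihood estimates are obtained by an EM algorithm on the sample
correlation matrix; the unified expression measure is the Thomson (regression)
factor score ``E[f | y] = lambda' Sigma^{-1} y``, a weighted average of the
platform measurements whose weight for a platform increases with its loading.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "StandardizedVectorSet",
    "FactorModel",
    "FactorScores",
    "standardize",
    "correlation_matrix",
    "fit_em",
    "fit_correlation",
    "loglik",
    "thomson_scores",
    "conditional_expectation_scores",
    "fix_sign",
    "DEFAULT_XTOL",
    "DEFAULT_MAX_ITER",
    "DEFAULT_PSI_FLOOR",
]

# EM stopping rule: estimated max-abs error of the loadings, extrapolated
# from the plain-EM contraction rate.  A parameter-based criterion is used
# (not a log-likelihood one) because near a perfect 1-factor fit the
# likelihood surface is too flat for a likelihood rule to pin the loadings
# down to the accuracy the Thomson weights deserve.
DEFAULT_XTOL = 1e-8
DEFAULT_MAX_ITER = 2000
# Floor on each uniqueness; a psi at the floor marks a Heywood case (the
# optimizer pushing a uniqueness to 0 / a loading to 1, an improper solution).
DEFAULT_PSI_FLOOR = 1e-3


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StandardizedVectorSet:
    """p x n matrix of standardized measurements with feature/platform labels.

    Each row has sample mean 0 and sample variance 1 (denominator n-1).
    ``platforms[j]`` is the platform label of feature ``j``; in gene-level mode
    features are platforms themselves, in probe-level mode they are probes.
    """

    values: np.ndarray
    feature_ids: tuple[str, ...]
    platforms: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D (features x samples) array")
        if v.shape[0] != len(self.feature_ids) or v.shape[0] != len(self.platforms):
            raise ValueError("feature_ids/platforms length must match row count")
        object.__setattr__(self, "values", v)

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def platform_of(self) -> Mapping[str, str]:
        return dict(zip(self.feature_ids, self.platforms))


@dataclass(frozen=True)
class FactorModel:
    """Fitted single-factor model for one gene.

    ``loadings[j]**2 + uniquenesses[j] == 1`` for every feature, so the implied
    matrix ``lambda lambda' + Psi`` is a proper correlation matrix.
    ``loglik`` is the Gaussian log-likelihood at the estimate with the sample
    correlation matrix as scatter (the quantity EM maximizes); ``loglik_trace``
    records it at every EM iteration and is non-decreasing.
    """

    loadings: np.ndarray
    uniquenesses: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    heywood: np.ndarray
    p: int
    n: int
    loglik_trace: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))

    def implied_correlation(self) -> np.ndarray:
        """The model correlation matrix Sigma = lambda lambda' + Psi."""
        lam = self.loadings
        return np.outer(lam, lam) + np.diag(self.uniquenesses)


@dataclass(frozen=True)
class FactorScores:
    """Thomson scores (the unified expression measure) and platform weights.

    ``scores = weights @ data.values``.  Weights need not sum to 1 and can be
    negative when a loading is negative.
    """

    scores: np.ndarray
    weights: np.ndarray


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


def standardize(
    raw: np.ndarray,
    feature_ids: Sequence[str] | None = None,
    platforms: Sequence[str] | None = None,
) -> StandardizedVectorSet:
    """Center and scale each row to sample mean 0 and sample variance 1.

    Parameters
    ----------
    raw
        features x samples matrix of log2 expression values.
    feature_ids, platforms
        Optional labels; default to ``f0..f{p-1}`` and a single platform "".

    Raises
    ------
    ValueError
        If any value is missing/non-finite, any row has zero sample variance
        (the offending features are named), or fewer than 2 samples are given.
    """
    x = np.asarray(raw, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    p, n = x.shape
    if feature_ids is None:
        feature_ids = tuple(f"f{j}" for j in range(p))
    if platforms is None:
        platforms = ("",) * p
    if n < 2:
        raise ValueError("standardization requires at least 2 samples")
    if not np.all(np.isfinite(x)):
        bad = np.argwhere(~np.isfinite(x))[0]
        raise ValueError(
            f"missing or non-finite value at feature {feature_ids[bad[0]]!r}, "
            f"sample column {bad[1]}"
        )
    sd = x.std(axis=1, ddof=1)
    zero = sd == 0.0
    if np.any(zero):
        names = [feature_ids[j] for j in np.flatnonzero(zero)]
        raise ValueError(f"zero variance for feature(s): {', '.join(map(repr, names))}")
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return StandardizedVectorSet(z, tuple(feature_ids), tuple(platforms))


def correlation_matrix(data: StandardizedVectorSet) -> np.ndarray:
    """Sample correlation matrix R = YY'/(n-1) of standardized rows."""
    y = data.values
    return (y @ y.T) / (data.n - 1)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def _woodbury_loglik(lam: np.ndarray, psi: np.ndarray, scatter: np.ndarray, n: int) -> float:
    """n-sample Gaussian log-likelihood with Sigma = lam lam' + diag(psi).

    ``scatter`` is the average outer-product matrix paired with ``n``.  Uses
    the rank-one Woodbury/determinant identities, so the cost is O(p^2).
    """
    a = lam / psi  # Psi^{-1} lambda
    c = 1.0 + lam @ a
    logdet = np.sum(np.log(psi)) + np.log(c)
    tr = np.sum(np.diag(scatter) / psi) - (a @ scatter @ a) / c
    p = lam.shape[0]
    return -0.5 * n * (p * np.log(2.0 * np.pi) + logdet + tr)


def loglik(model: FactorModel, data: StandardizedVectorSet) -> float:
    """Exact Gaussian log-likelihood of the observed vectors under the model.

    Evaluates ``sum_i log N(y_i; 0, Sigma)`` with ``Sigma`` the model's implied
    correlation matrix.  Invariant to a global sign flip of the loadings.
    """
    if model.p != data.p:
        raise ValueError("model and data dimensions do not match")
    psi = model.uniquenesses
    if np.any(psi <= 0):
        raise ValueError("singular Sigma: non-positive uniqueness")
    scatter = (data.values @ data.values.T) / data.n
    return _woodbury_loglik(model.loadings, psi, scatter, data.n)


# ---------------------------------------------------------------------------
# EM fit
# ---------------------------------------------------------------------------


def _polish_profile(
    lam: np.ndarray,
    R: np.ndarray,
    psi_floor: float,
    xtol: float,
    max_steps: int = 400,
) -> tuple[np.ndarray, bool]:
    """Monotone projected-gradient refinement of the profile likelihood.

    Minimizes the discrepancy F(lambda) = log det Sigma + tr(Sigma^{-1} R)
    with psi = 1 - lambda^2 and |lambda_j| box-bounded away from 1, using
    Barzilai-Borwein steps with backtracking.  Used to finish the rare fits
    where EM's linear rate degenerates (uniquenesses near the floor), where
    its per-iteration progress becomes negligible.  Returns the refined
    loadings and a convergence flag.
    """
    cap = np.sqrt(1.0 - psi_floor)

    def value(l: np.ndarray) -> float:
        psi = np.clip(1.0 - l**2, psi_floor, 1.0)
        a = l / psi
        c = 1.0 + l @ a
        return float(np.sum(np.log(psi)) + np.log(c) + np.sum(np.diag(R) / psi) - (a @ R @ a) / c)

    def grad(l: np.ndarray) -> np.ndarray:
        psi = np.clip(1.0 - l**2, psi_floor, 1.0)
        sigma = np.outer(l, l) + np.diag(psi)
        sinv = np.linalg.inv(sigma)
        A = sinv - sinv @ R @ sinv
        return 2.0 * (A @ l - l * np.diag(A))

    f0, g = value(lam), grad(lam)
    t = 1.0 / (np.max(np.abs(g)) + 1.0)
    converged = False
    for _ in range(max_steps):
        lam_new = np.clip(lam - t * g, -cap, cap)
        f_new = value(lam_new)
        while f_new > f0 and t > 1e-15:
            t *= 0.5
            lam_new = np.clip(lam - t * g, -cap, cap)
            f_new = value(lam_new)
        s = lam_new - lam
        if np.max(np.abs(s)) < xtol:
            lam, f0 = lam_new, f_new
            converged = True
            break
        g_new = grad(lam_new)
        y = g_new - g
        sy = float(s @ y)
        t = float(s @ s) / sy if sy > 1e-18 else t * 2.0
        lam, f0, g = lam_new, f_new, g_new
    return lam, converged


def fit_correlation(
    R: np.ndarray,
    n: int,
    *,
    xtol: float = DEFAULT_XTOL,
    max_iter: int = DEFAULT_MAX_ITER,
    psi_floor: float = DEFAULT_PSI_FLOOR,
) -> FactorModel:
    """ML single-factor fit to a correlation matrix by EM.

    Maximizes the Gaussian likelihood with ``R`` as the scatter matrix for
    ``n`` observations.  Initialization is the leading principal component of
    ``R`` scaled to the unit-diagonal parameterization and clipped to
    magnitude 0.9 (deterministic; avoids symmetric stalls).  Uniquenesses are
    floored at ``psi_floor``; coordinates at the floor are flagged as Heywood
    cases rather than raising.  Non-convergence within ``max_iter`` returns
    the last iterate with ``converged=False``.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if R.shape != (p, p):
        raise ValueError("R must be square")
    if p < 2:
        raise ValueError("at least 2 features are required for a factor fit")
    if not np.all(np.isfinite(R)):
        raise ValueError("correlation matrix has non-finite entries")

    lam_cap = np.sqrt(1.0 - psi_floor)

    def em_step(lam: np.ndarray, psi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a = lam / psi                              # Psi^{-1} lambda
        delta = a / (1.0 + lam @ a)                # Sigma^{-1} lambda (Woodbury)
        g = R @ delta                              # E-step cross moment
        b = 1.0 - lam @ delta + delta @ g          # E-step factor second moment
        lam_new = np.clip(g / b, -lam_cap, lam_cap)
        psi_new = np.clip(1.0 - lam_new * g, psi_floor, 1.0)
        return lam_new, psi_new

    def ll_of(lam: np.ndarray, psi: np.ndarray) -> float:
        return _woodbury_loglik(lam, psi, R, n)

    # PC1 start: eigenvector scaled by sqrt(eigenvalue) approximates loadings.
    w, v = np.linalg.eigh(R)
    lam0 = v[:, -1] * np.sqrt(max(w[-1], 0.0))
    lam0 = np.sign(lam0) * np.minimum(np.abs(lam0), 0.9)
    lam0 = np.where(lam0 == 0.0, 1e-6, lam0)
    psi0 = np.clip(1.0 - lam0**2, psi_floor, 1.0)

    # Safeguarded squared-extrapolation (SQUAREM-style) EM: each cycle takes
    # two plain EM steps, extrapolates along the observed contraction, then
    # stabilizes with one more EM step; the extrapolated iterate is accepted
    # only if it does not decrease the likelihood, so every recorded value is
    # an EM-or-better ascent and the fixed point is the plain-EM one.  This
    # removes EM's slow crawl for weak loadings and near-boundary (Heywood)
    # solutions.  Convergence is declared when the loading error estimated
    # from the plain-EM contraction rate drops below ``xtol``.
    trace = [ll_of(lam0, psi0)]
    converged = False
    it = 0
    ok_cycles = 0  # consecutive cycles meeting the error criterion
    cycle = 0
    while it < max_iter:
        cycle += 1
        lam1, psi1 = em_step(lam0, psi0)
        lam2, psi2 = em_step(lam1, psi1)
        it += 2
        trace.append(ll_of(lam1, psi1))
        ll2 = ll_of(lam2, psi2)
        trace.append(ll2)
        # Periodic boundary test: approach to a Heywood solution (psi -> 0)
        # is sublinear for EM, so when a uniqueness is small, propose pinning
        # it at the floor outright and keep the pin only if the likelihood
        # improves.  This preserves the ascent property and turns the slow
        # boundary crawl into a single jump.
        if cycle % 8 == 0:
            j = int(np.argmin(psi2))
            if psi2[j] < 0.3 and abs(lam2[j]) > 0.7:
                cand_l, cand_p = lam2.copy(), psi2.copy()
                cand_l[j] = np.sign(lam2[j]) * lam_cap
                cand_p[j] = psi_floor
                cand_l, cand_p = em_step(cand_l, cand_p)
                it += 1
                ll_cand = ll_of(cand_l, cand_p)
                if ll_cand > ll2:
                    lam2, psi2, ll2 = cand_l, cand_p, ll_cand
                    trace.append(ll2)
        r_l, r_p = lam1 - lam0, psi1 - psi0
        v_l, v_p = (lam2 - lam1) - r_l, (psi2 - psi1) - r_p
        r_norm = np.sqrt(r_l @ r_l + r_p @ r_p)
        s_norm = np.sqrt((lam2 - lam1) @ (lam2 - lam1) + (psi2 - psi1) @ (psi2 - psi1))
        step = float(np.max(np.abs(lam2 - lam1)))
        # Conservative error estimate: the contraction rate observed in one
        # cycle can be transiently optimistic right after an extrapolation
        # jump, so the rate is bounded below and the criterion must hold on
        # three consecutive cycles before convergence is declared.
        rho = min(max(s_norm / r_norm if r_norm > 0 else 0.0, 0.5), 1.0 - 1e-6)
        est_err = step * rho / (1.0 - rho)
        ok_cycles = ok_cycles + 1 if (r_norm == 0.0 or est_err <= xtol) else 0
        if ok_cycles >= 3:
            lam0, psi0 = lam2, psi2
            converged = True
            break
        v_norm = np.sqrt(v_l @ v_l + v_p @ v_p)
        if v_norm == 0.0:
            lam0, psi0 = lam2, psi2
            continue
        alpha = min(-1.0, -r_norm / v_norm)
        lam_acc = np.clip(lam0 - 2 * alpha * r_l + alpha**2 * v_l, -lam_cap, lam_cap)
        psi_acc = np.clip(psi0 - 2 * alpha * r_p + alpha**2 * v_p, psi_floor, 1.0)
        lam3, psi3 = em_step(lam_acc, psi_acc)
        it += 1
        ll3 = ll_of(lam3, psi3)
        if ll3 >= ll2 - 1e-12 * (1.0 + abs(ll2)):
            lam0, psi0 = lam3, psi3
            trace.append(ll3)
        else:  # extrapolation overshot: keep the plain EM iterate
            lam0, psi0 = lam2, psi2
    lam, psi = lam0, psi0
    if not converged:
        # EM left unconverged (degenerate linear rate near a small
        # uniqueness): finish with the monotone profile-likelihood polish.
        lam, converged = _polish_profile(lam, R, psi_floor, xtol)
        psi = np.clip(1.0 - lam**2, psi_floor, 1.0)
        ll_polished = _woodbury_loglik(lam, psi, R, n)
        if ll_polished >= trace[-1]:
            trace.append(ll_polished)

    # Project onto the unit-diagonal parameterization: psi = 1 - lambda^2,
    # floored.  A coordinate at the floor (loading pinned near 1) is a
    # Heywood case.
    heywood = (psi <= psi_floor * (1.0 + 1e-9)) | (lam**2 >= 1.0 - psi_floor * (1.0 + 1e-9))
    lam = np.where(heywood, np.sign(lam) * lam_cap, lam)
    psi = np.where(heywood, psi_floor, 1.0 - lam**2)
    ll = _woodbury_loglik(lam, psi, R, n)
    trace = np.asarray(trace)

    model = FactorModel(
        loadings=lam,
        uniquenesses=psi,
        loglik=ll,
        n_iter=it,
        converged=converged,
        heywood=heywood,
        p=p,
        n=n,
        loglik_trace=trace,
    )
    return fix_sign(model)


def fit_em(
    data: StandardizedVectorSet,
    *,
    xtol: float = DEFAULT_XTOL,
    max_iter: int = DEFAULT_MAX_ITER,
    psi_floor: float = DEFAULT_PSI_FLOOR,
) -> FactorModel:
    """Fit the single-factor model to standardized data by EM.

    Requires more samples than features (``n > p``).
    """
    if data.n <= data.p:
        raise ValueError(
            f"n > p required: {data.n} samples for {data.p} features"
        )
    R = correlation_matrix(data)
    return fit_correlation(R, data.n, xtol=xtol, max_iter=max_iter, psi_floor=psi_floor)


# ---------------------------------------------------------------------------
# Scores and sign convention
# ---------------------------------------------------------------------------


def thomson_scores(model: FactorModel, data: StandardizedVectorSet) -> FactorScores:
    """Thomson (regression) factor scores: the unified expression measure.

    Computes ``E[f | y] = lambda' Sigma^{-1} y`` through the low-dimensional
    form ``(1 + lambda' Psi^{-1} lambda)^{-1} lambda' Psi^{-1} y``, which only
    inverts the diagonal ``Psi`` rather than the p x p matrix ``Sigma``.
    """
    if model.p != data.p:
        raise ValueError("model and data dimensions do not match")
    a = model.loadings / model.uniquenesses
    weights = a / (1.0 + model.loadings @ a)
    return FactorScores(scores=weights @ data.values, weights=weights)


def conditional_expectation_scores(model: FactorModel, data: StandardizedVectorSet) -> np.ndarray:
    """E[f | y] via explicit inversion of the full p x p Sigma.

    Algebraically identical to :func:`thomson_scores`; kept as the direct form
    of the conditional expectation for cross-checking.
    """
    if model.p != data.p:
        raise ValueError("model and data dimensions do not match")
    sigma = model.implied_correlation()
    return np.linalg.solve(sigma, model.loadings) @ data.values


def fix_sign(model: FactorModel, scores: FactorScores | None = None):
    """Resolve the sign non-identifiability of the loadings deterministically.

    The likelihood is invariant to ``lambda -> -lambda``; the convention here
    is ``sum(lambda) >= 0``, with ties (sum exactly 0) broken by making the
    first nonzero loading positive.  Scores, if given, are flipped with the
    loadings so that ``scores = weights @ data`` is preserved.
    """
    lam = model.loadings
    s = lam.sum()
    flip = s < 0
    if s == 0:
        nz = lam[lam != 0]
        flip = nz.size > 0 and nz[0] < 0
    if not flip:
        return model if scores is None else (model, scores)
    flipped = replace(model, loadings=-lam)
    if scores is None:
        return flipped
    return flipped, FactorScores(scores=-scores.scores, weights=-scores.weights)
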