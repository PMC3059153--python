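"""Bootstrap standard errors for the fitted loadings.

The resampling unit is the sample (a column of the standardized matrix): a
bootstrap replicate redraws n samples with replacement, keeping the pairing
of platform measurements within a sample intact, then re-standardizes and
refits the factor model.  Because the factor sign is not identified, each
replicate's loadings are aligned to the point estimate by the sign of their
dot product before taking per-coordinate standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import fa_core
from .fa_core import DEFAULT_MAX_ITER, DEFAULT_PSI_FLOOR, DEFAULT_XTOL, StandardizedVectorSet

__all__ = ["BootstrapResult", "bootstrap_loading_se"]

DEFAULT_N_BOOT = 100


@dataclass(frozen=True)
class BootstrapResult:
    """Per-coordinate bootstrap SE of the loadings.

    ``n_failed`` counts replicates whose refit failed (a resampled row with
    zero variance, or EM not converging); they are excluded from the SE.
    """

    se: np.ndarray
    n_boot: int
    n_failed: int
    seed: int


def bootstrap_loading_se(
    data: StandardizedVectorSet,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    *,
    xtol: float = DEFAULT_XTOL,
    max_iter: int = DEFAULT_MAX_ITER,
    psi_floor: float = DEFAULT_PSI_FLOOR,
) -> BootstrapResult:
    """Nonparametric bootstrap SE of each loading.

    Raises ``ValueError`` if fewer than 2 replicates succeed (an SE needs at
    least 2 points) or if preconditions (n > p, n_boot >= 2) fail.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if data.n <= data.p:
        raise ValueError("n > p required for bootstrap refits")
    em_kwargs = dict(xtol=xtol, max_iter=max_iter, psi_floor=psi_floor)
    point = fa_core.fit_em(data, **em_kwargs)
    rng = np.random.default_rng(seed)
    draws: list[np.ndarray] = []
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, data.n, size=data.n)
        try:
            resampled = fa_core.standardize(
                data.values[:, idx], data.feature_ids, data.platforms
            )
            model = fa_core.fit_em(resampled, **em_kwargs)
        except ValueError:
            n_failed += 1
            continue
        if not model.converged:
            n_failed += 1
            continue
        lam = model.loadings
        if float(lam @ point.loadings) < 0:
            lam = -lam
        draws.append(lam)
    if len(draws) < 2:
        raise ValueError(f"bootstrap failed: only {len(draws)} of {n_boot} replicates refit")
    se = np.std(np.vstack(draws), axis=0, ddof=1)
    return BootstrapResult(se=se, n_boot=n_boot, n_failed=n_failed, seed=seed)
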