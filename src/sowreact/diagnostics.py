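"""Single-chain MCMC convergence diagnostics.

Two criteria are used to accept a chain: the Geweke comparison of the
first and last windows of the chain (a chain passes when the two-sided
p-value exceeds 0.05) and the effective sample size (ESS).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DegenerateChainError

__all__ = ["geweke", "effective_sample_size", "diagnose_chains"]


def _autocovariances(x: np.ndarray, max_lag: int) -> np.ndarray:
    # FFT-based biased autocovariance estimates gamma_0..gamma_max_lag
    n = len(x)
    xc = x - x.mean()
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1] / n
    return acov


def _spectral_variance(x: np.ndarray, window_frac: float = 0.04) -> float:
    """Spectral density at frequency zero via Bartlett-windowed
    autocovariances (window = 4% of the segment length)."""
    n = len(x)
    K = max(int(window_frac * n), 1)
    acov = _autocovariances(x, K)
    w = 1.0 - np.arange(1, K + 1) / (K + 1)
    return float(acov[0] + 2.0 * (w @ acov[1:]))


def geweke(chain, first_frac: float = 0.1, last_frac: float = 0.5
           ) -> tuple[float, float]:
    """Geweke convergence z-score and two-sided p-value.

    Compares the mean of the first ``first_frac`` of the chain with the
    mean of the last ``last_frac``, standardized by spectral-variance
    estimates of each segment; under stationarity z ~ N(0, 1).
    """
    x = np.asarray(chain, dtype=float)
    n = len(x)
    if n < 100:
        raise DegenerateChainError(f"chain too short ({n} < 100)")
    if not (0 < first_frac and 0 < last_frac
            and first_frac + last_frac <= 1):
        raise ValueError("window fractions must be positive and sum to <= 1")
    if np.var(x) == 0:
        raise DegenerateChainError("constant chain: Geweke undefined")
    n1 = int(first_frac * n)
    n2 = int(last_frac * n)
    x1, x2 = x[:n1], x[n - n2:]
    s1 = _spectral_variance(x1)
    s2 = _spectral_variance(x2)
    z = (x1.mean() - x2.mean()) / np.sqrt(s1 / n1 + s2 / n2)
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(p)


def effective_sample_size(chain) -> float:
    """ESS = n / (1 + 2 sum rho_k), autocorrelations truncated by the
    initial-positive-sequence rule on paired lags.

    For negatively autocorrelated (antithetic) chains the estimate may
    exceed n; that is allowed and left to the caller to flag.
    """
    x = np.asarray(chain, dtype=float)
    n = len(x)
    if n < 100:
        raise DegenerateChainError(f"chain too short ({n} < 100)")
    if np.var(x) == 0:
        raise DegenerateChainError("constant chain: ESS undefined")
    acov = _autocovariances(x, n - 2)
    rho = acov / acov[0]
    # Geyer initial positive sequence on paired lags:
    # Gamma_m = rho_{2m} + rho_{2m+1}; tau = -1 + 2 * sum(Gamma_m),
    # summed while Gamma_m stays positive (Gamma_0 always included).
    tau = -1.0
    m = 0
    while 2 * m + 1 < len(rho):
        gamma_m = rho[2 * m] + rho[2 * m + 1]
        if m > 0 and gamma_m <= 0:
            break
        tau += 2.0 * gamma_m
        m += 1
    tau = max(tau, 1.0 / n)  # antithetic chains: ESS may exceed n
    return float(n / tau)


def diagnose_chains(samples: pd.DataFrame, alpha: float = 0.05
                    ) -> pd.DataFrame:
    """Geweke and ESS for every column of a posterior-sample table.

    Returns one row per parameter with z, p, ESS and a pass flag
    (p > alpha); degenerate (constant) chains are marked as failed.
    """
    rows = []
    n = len(samples)
    for col in samples.columns:
        x = samples[col].to_numpy()
        try:
            z, p = geweke(x)
            ess = effective_sample_size(x)
            rows.append({"parameter": col, "geweke_z": z, "geweke_p": p,
                         "ess": ess, "ess_exceeds_n": ess > n,
                         "passed": bool(p > alpha)})
        except DegenerateChainError as exc:
            rows.append({"parameter": col, "geweke_z": np.nan,
                         "geweke_p": np.nan, "ess": np.nan,
                         "ess_exceeds_n": False, "passed": False,
                         "note": str(exc)})
    return pd.DataFrame(rows)
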