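"""Fixed-bandwidth Gaussian kernel density estimation on a shared grid.

All density curves in this package (whole-genome-duplication fraction
histogramming and SV size spectra) are Gaussian KDEs evaluated on a fixed
grid with an explicitly chosen bandwidth, so that curves being compared
share both grid and smoothing. The "auto" bandwidth is the classical
Silverman rule of thumb (R's bw.nrd0):

    h = 0.9 * min(sd, IQR / 1.34) * n^(-1/5)
"""

from __future__ import annotations

import numpy as np

__all__ = ["silverman_bandwidth", "kde_evaluate"]


def silverman_bandwidth(data: np.ndarray) -> float:
    """Silverman rule-of-thumb bandwidth; falls back to a small positive
    value for (near-)degenerate data so that point masses still render."""
    x = np.asarray(data, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("bandwidth needs >= 2 observations")
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        return 1e-2
    return 0.9 * spread * n ** (-0.2)


def kde_evaluate(data: np.ndarray, grid: np.ndarray, bandwidth: float) -> np.ndarray:
    """Gaussian KDE of ``data`` evaluated at ``grid`` points."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    x = np.asarray(data, dtype=float)
    g = np.asarray(grid, dtype=float)
    if len(x) == 0:
        raise ValueError("KDE needs at least one observation")
    z = (g[:, None] - x[None, :]) / bandwidth
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (len(x) * bandwidth * np.sqrt(2 * np.pi))
    return dens
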