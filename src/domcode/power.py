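"""Analytic power of the 1-df dominance association test across allele
frequencies.

Under the alternative, the Wald statistic of a marker with regression
coefficient beta follows a noncentral chi-square with one degree of freedom
and noncentrality NCP = N var(X) beta^2 / sigma^2, where var(X) is the HWE
variance of the coded marker.  Power is the upper tail of that distribution
beyond the central chi-square critical value at level alpha:

    t = F^{-1}(1 - alpha; df=1),   power = 1 - F(t; df=1, NCP).

Only var(X) differs between encodings, so the power curves over allele
frequency directly trace each coding's marker-variance profile.  Defaults
follow a dense-panel regime: alpha = 0.05 / 47257 markers, N = 1000,
beta = 1, phenotype variance 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .encodings import get_scheme, theoretical_moments

__all__ = ["PowerSpec", "marker_variance", "ncp", "power_at", "power_curve"]

DEFAULT_N_MARKERS = 47257


def _default_grid():
    return np.round(np.arange(0.01, 0.9905, 0.001), 10)


@dataclass
class PowerSpec:
    """Parameters of the noncentral chi-square power calculation."""

    alpha: float = 0.05 / DEFAULT_N_MARKERS
    N: int = 1000
    beta: float = 1.0
    sigma2: float = 1.0
    p_grid: np.ndarray = field(default_factory=_default_grid)

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.sigma2 <= 0.0:
            raise ValueError("sigma2 must be positive")
        self.p_grid = np.asarray(self.p_grid, dtype=float)


def marker_variance(scheme, p):
    """HWE variance of the coded marker; the frequency-dependent factor of
    the noncentrality parameter."""
    return theoretical_moments(get_scheme(scheme), p)[1]


def ncp(spec: PowerSpec, var_x):
    """NCP = N var(X) beta^2 / sigma^2."""
    var_x = np.asarray(var_x, dtype=float)
    if np.any(var_x < 0):
        raise ValueError("var(X) must be non-negative")
    return spec.N * var_x * spec.beta**2 / spec.sigma2


def power_at(spec: PowerSpec, ncp_value):
    """Tail probability of chi-square(1, ncp) beyond the alpha critical value."""
    lam = np.asarray(ncp_value, dtype=float)
    t = sps.chi2.isf(spec.alpha, df=1)
    out = np.where(lam > 0, sps.ncx2.sf(t, 1, np.maximum(lam, 1e-300)), spec.alpha)
    return float(out) if out.ndim == 0 else out


def power_curve(spec: PowerSpec, schemes=("het", "carrier", "orthogonal")) -> pd.DataFrame:
    """Power at each (allele frequency, scheme): columns p, scheme, var_x,
    ncp, power."""
    frames = []
    for name in schemes:
        scheme = get_scheme(name)
        vx = marker_variance(scheme, spec.p_grid)
        lam = ncp(spec, vx)
        frames.append(
            pd.DataFrame(
                {
                    "p": spec.p_grid,
                    "scheme": scheme.name,
                    "var_x": vx,
                    "ncp": lam,
                    "power": power_at(spec, lam),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
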