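"""Turbulence statistics: Reynolds decomposition, TKE, spectra, Kolmogorov scales.

Velocity series are decomposed into a time mean and fluctuations,
``u(x,t) = U(x) + u'(x,t)``; the turbulent kinetic energy is half the sum of
the fluctuation variances.  Spectral content is expressed against the
Strouhal number ``St = f d / u`` and estimated with Welch's periodogram.
Kolmogorov microscales are computed from the time-averaged invariant
``S = 2 s'_ij s'_ij`` of the fluctuating rate-of-strain tensor
(nondimensionalized by the throat mean velocity and diameter):

    eta   = (1 / (Re^2 S))^(1/4)
    tau   = S^(-1/2)
    u_eta = (S / Re^2)^(1/4)

so that ``eta * u_eta * Re = 1`` and ``tau = eta / u_eta`` hold identically.
Resolution quality is reported as ``l+ = dx / eta`` and ``t+ = dt / tau``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal


class CharacterizationError(ValueError):
    pass


@dataclass
class ReynoldsStats:
    mean: np.ndarray          # (...,) or (..., 3)
    fluct: np.ndarray         # (nt, ...) same trailing shape
    window: tuple[int, int]   # sample index range used


@dataclass
class SpectrumResult:
    """One-sided PSD against frequency and Strouhal number."""

    f: np.ndarray
    st: np.ndarray
    psd: np.ndarray
    window: str
    nperseg: int
    noverlap: int
    n_segments: int
    meta: dict = field(default_factory=dict)

    def integral(self) -> float:
        """Integral of the PSD over frequency (Parseval check)."""
        return float(np.trapezoid(self.psd, self.f))


@dataclass(frozen=True)
class KolmogorovScales:
    """Nondimensional microscales plus the resolution-quality ratios."""

    eta: float
    tau: float
    u_eta: float
    re: float

    def dimensional(self, d: float, u_mean: float) -> tuple[float, float, float]:
        """(eta [m], tau [s], u_eta [m/s]) using length d and velocity u_mean."""
        return self.eta * d, self.tau * d / u_mean, self.u_eta * u_mean


def reynolds_decompose(series: np.ndarray, window: tuple[int, int] | None = None,
                       axis: int = 0) -> ReynoldsStats:
    """Split a time series into mean and fluctuation over a sample window."""
    series = np.asarray(series, dtype=float)
    if window is None:
        window = (0, series.shape[axis])
    a, b = window
    if b - a < 2:
        raise CharacterizationError("averaging window needs at least 2 samples")
    sl = [slice(None)] * series.ndim
    sl[axis] = slice(a, b)
    seg = series[tuple(sl)]
    mean = seg.mean(axis=axis)
    return ReynoldsStats(mean=mean, fluct=seg - np.expand_dims(mean, axis), window=(a, b))


def tke(stats: ReynoldsStats, axis: int = 0) -> np.ndarray:
    """Turbulent kinetic energy ``½ <u'_x² + u'_y² + u'_z²>`` per point.

    The fluctuation array's last dimension holds the velocity components.
    """
    var = (stats.fluct**2).mean(axis=axis)
    return 0.5 * var.sum(axis=-1)


def strouhal(f: np.ndarray | float, d: float, u_mean: float):
    """Dimensionless frequency ``f d / u``."""
    if u_mean <= 0:
        raise CharacterizationError("u_mean must be positive")
    return np.asarray(f, dtype=float) * d / u_mean


def welch_psd(
    series: np.ndarray,
    fs: float,
    *,
    d: float = 1.0,
    u_mean: float = 1.0,
    n_segments: int = 8,
    overlap: float = 0.5,
    window: str = "hann",
    detrend: str = "constant",
) -> SpectrumResult:
    """Welch PSD of a scalar series on a Strouhal abscissa.

    Defaults: Hann window, 8 segments, 50% overlap.  With density scaling the
    integral of the one-sided PSD approximates the series variance.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    denom = 1.0 + (n_segments - 1) * (1.0 - overlap)
    nperseg = int(n / denom)
    if nperseg < 2:
        raise CharacterizationError("series shorter than one segment")
    noverlap = int(nperseg * overlap)
    f, psd = signal.welch(
        series, fs=fs, window=window, nperseg=nperseg, noverlap=noverlap,
        detrend=detrend, scaling="density",
    )
    return SpectrumResult(
        f=f,
        st=strouhal(f, d, u_mean),
        psd=psd,
        window=window,
        nperseg=nperseg,
        noverlap=noverlap,
        n_segments=n_segments,
        meta={"fs": fs, "n": n, "d": d, "u_mean": u_mean},
    )


def fit_spectral_slope(spec: SpectrumResult, band: tuple[float, float],
                       margin: float = 1.5) -> float:
    """Log-log slope of the PSD fitted inside ``band`` (frequency units)."""
    lo, hi = band[0] * margin, band[1] / margin
    sel = (spec.f >= lo) & (spec.f <= hi) & (spec.psd > 0)
    if sel.sum() < 3:
        raise CharacterizationError("band too narrow for a slope fit")
    p = np.polyfit(np.log(spec.f[sel]), np.log(spec.psd[sel]), 1)
    return float(p[0])


def fluctuating_strain(uprime: np.ndarray, dx: float = 1.0):
    """Fluctuating rate-of-strain tensor and its invariant ``S = 2 s'_ij s'_ij``.

    ``uprime`` has shape (nx, ny, nz, 3) (one snapshot) and is assumed
    nondimensional; derivatives are second-order central with one-sided
    closure at array boundaries.

    Returns (s, S): the symmetric tensor (..., 3, 3) and the scalar field.
    """
    uprime = np.asarray(uprime, dtype=float)
    if any(n < 3 for n in uprime.shape[:3]):
        raise CharacterizationError("need at least 3 cells per direction")
    grads = [np.gradient(uprime[..., a], dx, axis=(0, 1, 2)) for a in range(3)]
    s = np.empty(uprime.shape[:3] + (3, 3))
    for a in range(3):
        for b in range(3):
            s[..., a, b] = 0.5 * (grads[a][b] + grads[b][a])
    S = 2.0 * (s * s).sum(axis=(-2, -1))
    return s, S


def kolmogorov_scales(S_mean: float, re: float) -> KolmogorovScales:
    """Nondimensional Kolmogorov scales from the mean strain invariant."""
    if re <= 0:
        raise CharacterizationError("Re must be positive")
    if S_mean <= 0:
        raise CharacterizationError("zero strain invariant: scales undefined")
    eta = (1.0 / (re * re * S_mean)) ** 0.25
    tau = S_mean**-0.5
    u_eta = (S_mean / (re * re)) ** 0.25
    return KolmogorovScales(eta=eta, tau=tau, u_eta=u_eta, re=re)


def average_strain_over_stations(
    S_series: np.ndarray,
    z: np.ndarray,
    z_lo: float,
    z_hi: float,
) -> float:
    """Average the strain invariant over a station band, then over time.

    ``S_series`` has shape (nt, nz) — the invariant sampled along the
    centreline — and ``z`` the axial positions of those samples.
    """
    z = np.asarray(z, dtype=float)
    sel = (z >= z_lo) & (z <= z_hi)
    if not sel.any():
        raise CharacterizationError(f"no samples in band [{z_lo}, {z_hi}]")
    S_series = np.atleast_2d(np.asarray(S_series, dtype=float))
    return float(S_series[:, sel].mean())


def resolution_quality(dx: float, dt: float, eta: float, tau: float) -> tuple[float, float]:
    """Grid-quality ratios ``l+ = dx/eta`` and ``t+ = dt/tau`` (dimensional)."""
    if min(dx, dt, eta, tau) <= 0:
        raise CharacterizationError("all inputs must be positive")
    return dx / eta, dt / tau
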