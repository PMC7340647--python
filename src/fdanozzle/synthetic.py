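"""Synthetic inputs: analytic flows, PIV-like datasets, spectra, strain fields.

Everything the pipeline consumes can be generated here without downloads:
laminar pipe profiles as solver oracles, multi-laboratory PIV-style datasets
with reproducible between-lab offsets and pointwise noise, stationary
signals with a prescribed spectral power law, and linear shear fields whose
fluctuating strain invariant is known exactly.  All generators are pure
functions of their parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .comparison import PIVDataset


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    """Reproducible noise model for emulated PIV experiments.

    ``noise_sd`` is the pointwise additive noise as a fraction of the truth
    profile's RMS; ``interlab_offset_sd`` the standard deviation of the
    multiplicative lab-level offset.  Defaults emulate the qualitative
    spread between the benchmark's five laboratory datasets.
    """

    seed: int
    noise_sd: float = 0.03
    interlab_offset_sd: float = 0.05
    n_labs: int = 5

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.interlab_offset_sd < 0:
            raise SyntheticError("noise parameters must be non-negative")
        if self.n_labs < 1:
            raise SyntheticError("need at least one lab")


def poiseuille_pipe(R: float, u_mean: float, n_r: int = 101):
    """Analytic laminar pipe profile ``u(r) = 2 u_mean (1 - (r/R)^2)``.

    Returns (r, u) on ``n_r`` radii spanning [0, R].
    """
    if R <= 0 or u_mean <= 0:
        raise SyntheticError("R and u_mean must be positive")
    r = np.linspace(0.0, R, n_r)
    return r, 2.0 * u_mean * (1.0 - (r / R) ** 2)


def synthetic_piv(
    truth: pd.DataFrame,
    spec: SyntheticSpec,
    experiment_ids: list[str] | None = None,
) -> list[PIVDataset]:
    """Emulated multi-laboratory datasets around a truth table.

    ``truth`` is a long-format table (experiment column ignored) whose
    ``value`` column is perturbed per lab as
    ``truth * (1 + offset_lab) + noise`` with ``offset_lab ~ N(0, offset_sd)``
    and ``noise ~ N(0, noise_sd * rms(truth))`` drawn per point.
    """
    rng = np.random.default_rng(spec.seed)
    if experiment_ids is None:
        experiment_ids = [str(243 + 101 * k) for k in range(spec.n_labs)]
    if len(experiment_ids) != spec.n_labs:
        raise SyntheticError("experiment_ids length must equal n_labs")
    rms = float(np.sqrt(np.mean(truth["value"].to_numpy() ** 2)))
    out = []
    for lab_id in experiment_ids:
        offset = rng.normal(0.0, spec.interlab_offset_sd)
        noise = rng.normal(0.0, spec.noise_sd * rms, size=len(truth))
        t = truth.copy()
        t["experiment"] = lab_id
        t["value"] = truth["value"].to_numpy() * (1.0 + offset) + noise
        t = t[["experiment", "quantity", "z_m", "r_m", "value"]]
        out.append(PIVDataset(experiment=lab_id, table=t.reset_index(drop=True)))
    return out


def spectral_signal(
    slope: float,
    band: tuple[float, float],
    fs: float,
    n: int,
    seed: int,
) -> np.ndarray:
    """Stationary random signal with ``PSD ~ f^slope`` inside ``band``.

    Built by shaping white Gaussian noise in the Fourier domain with random
    phases; the spectrum is zero outside the band.
    """
    f_lo, f_hi = band
    if not 0.0 < f_lo < f_hi < fs / 2.0:
        raise SyntheticError(f"band {band} must lie inside (0, fs/2)")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    sel = (freqs >= f_lo) & (freqs <= f_hi)
    amp[sel] = (freqs[sel] / f_lo) ** (slope / 2.0)
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def strain_fixture(S0: float, shape: tuple[int, int, int], rotation: float = 0.0):
    """Linear shear field whose strain invariant equals ``S0`` exactly.

    ``u'_x = k y`` with ``k = sqrt(S0)`` gives ``s'_xy = k/2`` and
    ``S = 2 s'_ij s'_ij = k^2 = S0``.  An optional rigid rotation about z
    (rate ``rotation``) is purely antisymmetric and leaves S unchanged.
    Coordinates are cell indices (unit spacing).
    """
    if S0 < 0:
        raise SyntheticError("S0 must be non-negative")
    nx, ny, nz = shape
    k = float(np.sqrt(S0))
    x = np.arange(nx, dtype=float)[:, None, None]
    y = np.arange(ny, dtype=float)[None, :, None]
    u = np.zeros(shape + (3,))
    u[..., 0] = k * y
    if rotation:
        u[..., 0] += -rotation * (y - y.mean())
        u[..., 1] = rotation * (x - x.mean()) * np.ones((1, ny, 1))
    return u
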