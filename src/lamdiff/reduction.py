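"""2D powder image reduction and q-axis calibration.

Radial (azimuthal) integration converts detector images into 1D intensity
vs q profiles; the q axis is calibrated against a lamellar standard
(silver behenate) by a one-parameter multiplicative fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import PowderImage, SampleMeta, ScatteringProfile

__all__ = ["CalibrationStandard", "QScale", "azimuthal_integrate", "calibrate_q"]


@dataclass(frozen=True)
class CalibrationStandard:
    """Lamellar calibration standard with known first-order spacing.

    The default d_001 of 58.83 Angstrom is the value used upstream of this
    pipeline; note the more common silver behenate reference is 58.38
    Angstrom — the default is config-overridable rather than silently
    corrected.
    """

    name: str = "silver behenate"
    d_001: float = 58.83  # Angstrom

    def __post_init__(self):
        if self.d_001 <= 0:
            raise ValueError("d_001 must be > 0")

    def ring_positions(self, n_orders: int) -> np.ndarray:
        """Expected ring positions 2 pi h / d_001 for h = 1..n_orders."""
        return 2.0 * np.pi * np.arange(1, n_orders + 1) / self.d_001


@dataclass(frozen=True)
class QScale:
    """Multiplicative q-axis correction: q_true = scale * q_observed."""

    scale: float
    residual: float  # RMS misfit in 1/Angstrom
    warning: bool = False  # scale more than 10% away from unity

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    def apply(self, profile: ScatteringProfile) -> ScatteringProfile:
        return ScatteringProfile(
            q=profile.q * self.scale,
            intensity=profile.intensity,
            uncertainty=profile.uncertainty,
            meta=profile.meta,
            mode=profile.mode,
        )


def azimuthal_integrate(
    image: PowderImage,
    n_bins: int = 400,
    meta: SampleMeta | None = None,
    mode: str = "SAXS",
) -> ScatteringProfile:
    """Radially integrate a powder image into a 1D profile.

    Pixels are assigned to uniform half-open q bins [q_k, q_k+1) spanning
    the pixel q-range (the final bin is closed so every pixel lands in a
    bin).  The bin statistic is the *mean* count so profiles are comparable
    across detector geometries; empty bins are reported as NaN rather than
    zero-filled.  The per-bin uncertainty is sqrt(sum counts) / n_pixels,
    i.e. Poisson error on the mean.
    """
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    qpix = image.pixel_q().ravel()
    counts = image.counts.ravel().astype(float)
    lo, hi = float(qpix.min()), float(qpix.max())
    if not hi > lo:
        raise ValueError("degenerate geometry: all pixels share one q value")
    dq = (hi - lo) / n_bins
    idx = np.minimum(((qpix - lo) / dq).astype(int), n_bins - 1)
    npix = np.bincount(idx, minlength=n_bins)
    csum = np.bincount(idx, weights=counts, minlength=n_bins)
    if not np.any(npix > 0):
        raise ValueError("all bins empty: geometry does not match the image")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(npix > 0, csum / np.maximum(npix, 1), np.nan)
        unc = np.where(npix > 0, np.sqrt(csum) / np.maximum(npix, 1), np.nan)
    centers = lo + dq * (np.arange(n_bins) + 0.5)
    profile = ScatteringProfile(
        q=centers,
        intensity=mean,
        uncertainty=unc,
        meta=meta or SampleMeta(),
        mode=mode,
    )
    profile.bin_npix = npix  # pixels per bin, for count-conservation checks
    return profile


def calibrate_q(
    observed_ring_positions,
    standard: CalibrationStandard | None = None,
    max_orders: int = 12,
) -> QScale:
    """Fit the q-axis scale factor from observed standard-ring positions.

    Expected positions are q_h = 2 pi h / d_001 for h = 1..n rings; the
    single multiplicative factor minimizing sum (scale * q_obs - q_exp)^2
    is the least-squares fit through the origin.  A scale deviating more
    than 10% from unity raises a warning flag (likely mis-indexed rings).
    """
    standard = standard or CalibrationStandard()
    obs = np.asarray(list(observed_ring_positions), dtype=float)
    if obs.size == 0:
        raise ValueError("need at least one observed ring position")
    if np.any(obs <= 0):
        raise ValueError("ring positions must be positive")
    if obs.size > max_orders:
        raise ValueError(
            f"{obs.size} observed rings exceed the {max_orders} available orders"
        )
    expected = standard.ring_positions(obs.size)
    scale = float(np.dot(expected, obs) / np.dot(obs, obs))
    residual = float(np.sqrt(np.mean((scale * obs - expected) ** 2)))
    return QScale(scale=scale, residual=residual, warning=abs(scale - 1.0) > 0.10)
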