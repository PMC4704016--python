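"""Baseline estimation, Bragg-peak detection and nonlinear peak fitting.

The chain is: asymmetric-least-squares baseline -> prominence-thresholded
local-maximum detection -> windowed nonlinear least squares (Gaussian or
pseudo-Voigt line shapes via lmfit), with joint fits for overlapping
windows.  Noise is estimated robustly (median absolute deviation) so the
module works on arbitrary text profiles, not only Poisson-counted ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from lmfit.models import ConstantModel, GaussianModel, PseudoVoigtModel
from scipy import signal, sparse
from scipy.sparse.linalg import spsolve

from .forward import ScatteringProfile

__all__ = ["Peak", "Baseline", "estimate_baseline", "detect_peaks", "fit_peaks"]

log = logging.getLogger(__name__)

MAD_TO_SIGMA = 1.4826  # consistency factor for Gaussian noise


@dataclass
class Peak:
    """One fitted Bragg reflection."""

    q0: float  # center, 1/Angstrom
    area: float  # integrated area, counts * 1/Angstrom
    fwhm: float  # 1/Angstrom
    height: float  # counts above baseline
    shape: str = "gaussian"
    stderr: dict = field(default_factory=dict)  # per-parameter 1-sigma errors
    miller_label: str | None = None  # e.g. "d20"/"d11" for WAXS reflections

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        if self.area <= 0:
            raise ValueError("area must be > 0")


@dataclass
class Baseline:
    """Smooth background estimate aligned with a profile's q grid."""

    y: np.ndarray
    method: str = "asls"
    smoothness: float = 1e7
    asymmetry: float = 1e-4
    converged: bool = True
    n_iter: int = 0


def estimate_baseline(
    profile: ScatteringProfile,
    smoothness: float = 1e7,
    asymmetry: float = 1e-4,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> Baseline:
    """Asymmetric-least-squares (Whittaker) baseline.

    Minimizes sum w_i (y_i - b_i)^2 + smoothness * sum (delta^2 b)^2 with
    weights asymmetry for points above the baseline and (1 - asymmetry)
    below, so peaks are mostly ignored while the smooth background is
    followed.  Non-convergence inside ``max_iter`` is reported on the
    returned object, not raised.
    """
    y = np.asarray(profile.intensity, dtype=float)
    n = y.size
    if n < 50:
        raise ValueError("baseline estimation needs at least 50 points")
    if not np.all(np.isfinite(y)):
        raise ValueError("profile contains non-finite intensities")
    d = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    penalty = smoothness * (d.T @ d)
    w = np.ones(n)
    z = y.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        wmat = sparse.diags(w)
        z = spsolve((wmat + penalty).tocsc(), w * y)
        w_new = np.where(y > z, asymmetry, 1.0 - asymmetry)
        if np.mean(np.abs(w_new - w)) < tol:
            w = w_new
            converged = True
            break
        w = w_new
    if not converged:
        log.warning("baseline did not converge in %d iterations", max_iter)
    return Baseline(
        y=z,
        smoothness=smoothness,
        asymmetry=asymmetry,
        converged=converged,
        n_iter=it,
    )


def noise_sigma(residual: np.ndarray) -> float:
    """Robust noise scale: scaled median absolute deviation of the residual."""
    r = residual[np.isfinite(residual)]
    return MAD_TO_SIGMA * float(np.median(np.abs(r - np.median(r))))


def detect_peaks(
    profile: ScatteringProfile,
    baseline: Baseline,
    min_prominence_sigmas: float = 5.0,
    min_distance_bins: int = 8,
) -> list[int]:
    """Candidate peak positions as indices into the profile grid.

    Local maxima of (intensity - baseline) with both height and prominence
    of at least ``min_prominence_sigmas`` times the robust noise scale (the
    height criterion suppresses wide-base noise excursions whose prominence
    alone can reach several sigma).  An empty list is a valid result.
    Raising the threshold can only remove candidates, never add them.
    """
    resid = profile.intensity - baseline.y
    resid = resid - np.median(resid)  # recentre: baseline convention offset
    sigma = noise_sigma(resid)
    if sigma <= 0:  # noiseless profile: fall back to any positive excursion
        sigma = max(1e-12, float(np.max(np.abs(resid))) * 1e-9)
    idx, _ = signal.find_peaks(
        resid,
        height=min_prominence_sigmas * sigma,
        prominence=min_prominence_sigmas * sigma,
        distance=min_distance_bins,
    )
    return sorted(int(i) for i in idx)


def _fit_window(q, y, dy, group, widths_bins, shape, bin_w):
    """Jointly fit one window containing one or more candidate peaks."""
    mk = GaussianModel if shape == "gaussian" else PseudoVoigtModel
    # free constant absorbs any local offset left by the envelope-style
    # baseline, which would otherwise bias weak-peak areas upward
    model = ConstantModel(prefix="bg_")
    params = model.make_params(c=0.0)
    for k, (i0, wbins) in enumerate(zip(group, widths_bins)):
        comp = mk(prefix=f"p{k}_")
        sig0 = max(wbins * bin_w / 2.355, bin_w / 2.0)
        p = comp.make_params()
        p[f"p{k}_center"].set(value=q[i0], min=q[i0] - 5 * sig0, max=q[i0] + 5 * sig0)
        p[f"p{k}_sigma"].set(value=sig0, min=bin_w / 4.0, max=(q[-1] - q[0]))
        p[f"p{k}_amplitude"].set(
            value=max(y[i0], 1e-9) * sig0 * np.sqrt(2 * np.pi), min=1e-12
        )
        model = model + comp
        params.update(p)
    lo = max(0, min(group) - int(6 * max(widths_bins)))
    hi = min(len(q), max(group) + int(6 * max(widths_bins)) + 1)
    sl = slice(lo, hi)
    weights = None
    if dy is not None:
        weights = 1.0 / np.maximum(dy[sl], 1e-9)
    return model.fit(y[sl], params, x=q[sl], weights=weights), model


# Peak windows are fitted unweighted by default: with resolution-limited
# peaks only a few bins wide, inverse-variance (Poisson) weights let the
# background-level flanks dominate and bias areas low; ordinary least
# squares recovers areas without bias at these signal levels.


def fit_peaks(
    profile: ScatteringProfile,
    baseline: Baseline,
    candidates: list[int],
    shape: str = "gaussian",
    window_overlap: float = 0.25,
    use_weights: bool = False,
) -> list[Peak]:
    """Nonlinear least-squares fit of the candidate peaks.

    Each candidate gets a local window of six estimated widths; windows
    overlapping by more than ``window_overlap`` of their extent are merged
    and fitted jointly as a sum of line shapes.  Integrated areas come
    analytically from the fitted parameters.  Failed or singular fits are
    dropped and logged, never kept silently.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    if shape not in ("gaussian", "pseudo-voigt"):
        raise ValueError("shape must be 'gaussian' or 'pseudo-voigt'")
    q = profile.q
    y = profile.intensity - baseline.y
    bin_w = profile.bin_width
    widths = signal.peak_widths(
        np.maximum(y, 0.0), candidates, rel_height=0.5
    )[0]
    widths = np.maximum(widths, 1.5)  # bins

    # merge candidates whose windows overlap by more than the threshold
    half = 3.0 * widths  # half-window in bins
    groups: list[list[int]] = [[0]]
    for k in range(1, len(candidates)):
        prev = groups[-1][-1]
        lo_k = candidates[k] - half[k]
        hi_prev = candidates[prev] + half[prev]
        overlap = hi_prev - lo_k
        extent = min(2 * half[k], 2 * half[prev])
        if overlap > window_overlap * extent:
            groups[-1].append(k)
        else:
            groups.append([k])

    peaks: list[Peak] = []
    for grp in groups:
        idxs = [candidates[k] for k in grp]
        wbins = [widths[k] for k in grp]
        try:
            result, _ = _fit_window(
                q, y, profile.uncertainty if use_weights else None,
                idxs, wbins, shape, bin_w,
            )
        except Exception as exc:  # singular matrix, nan in data, ...
            log.warning("peak fit failed near q=%s: %s", [q[i] for i in idxs], exc)
            continue
        for k in range(len(grp)):
            pre = f"p{k}_"
            pv = result.params
            area = float(pv[pre + "amplitude"].value)
            fwhm = float(pv[pre + "fwhm"].value)
            height = float(pv[pre + "height"].value)
            center = float(pv[pre + "center"].value)
            if not (np.isfinite(area) and area > 0 and np.isfinite(fwhm) and fwhm > 0):
                log.warning("dropping degenerate peak near q=%.4f", center)
                continue
            stderr = {
                name.removeprefix(pre): (
                    float(pv[name].stderr) if pv[name].stderr else float("nan")
                )
                for name in (pre + "center", pre + "amplitude", pre + "sigma")
            }
            peaks.append(
                Peak(
                    q0=center,
                    area=area,
                    fwhm=fwhm,
                    height=height,
                    shape=shape,
                    stderr=stderr,
                )
            )
    peaks.sort(key=lambda p: p.q0)
    return peaks
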