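"""Lamellar indexing, d-spacing, phase classification and phase diagrams.

Fitted Bragg peaks are grouped into lamellar series (orders at integer
multiples of a fundamental), each series gets a repeat distance
d = 2 pi / q1, and the gel (L_beta') versus fluid (L_alpha) signature is
read off the number of orders, peak sharpness and the presence of the
wide-angle chain-packing peak.  Two accepted series with distinct repeat
distances mark gel/fluid coexistence; assembling many (composition,
temperature) points yields the binary phase diagram with per-composition
melting temperatures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forward import NM_TO_ANG, SampleMeta, ScatteringProfile
from .peakfit import Peak, detect_peaks, estimate_baseline, fit_peaks

__all__ = [
    "OrderAssignment",
    "LamellarSeries",
    "PhasePoint",
    "PhaseDiagram",
    "AnalysisSettings",
    "group_series",
    "dspacing",
    "classify_phase",
    "assess_point",
    "build_phase_diagram",
]

log = logging.getLogger(__name__)

WAXS_CHAIN_WINDOW = (1.45, 1.65)  # 1/Angstrom


@dataclass
class OrderAssignment:
    h: int
    peak: Peak
    residual: float  # q0 - h * q1, 1/Angstrom

    def __post_init__(self):
        if self.h < 1:
            raise ValueError("order h must be >= 1")


@dataclass
class LamellarSeries:
    """A set of Bragg orders sharing one lamellar repeat distance."""

    q1: float  # refined fundamental, 1/Angstrom
    orders: list[OrderAssignment]
    q1_err: float = float("nan")
    phase: str = "unknown"

    @property
    def n_orders(self) -> int:
        return len(self.orders)

    @property
    def d(self) -> float:
        """Repeat distance in nm (q in 1/Angstrom)."""
        return 2.0 * np.pi / self.q1 / NM_TO_ANG

    @property
    def d_err(self) -> float:
        if not np.isfinite(self.q1_err):
            return float("nan")
        return self.d * self.q1_err / self.q1

    def order_areas(self) -> dict[int, float]:
        return {o.h: o.peak.area for o in self.orders}


@dataclass
class AnalysisSettings:
    """Tunables of the full profile -> phase-point chain."""

    baseline_smoothness: float = 1e7
    baseline_asymmetry: float = 1e-4
    min_prominence_sigmas: float = 5.0
    rel_tolerance: float = 0.015  # indexing tolerance, relative
    max_order: int = 6
    max_fundamental_divisor: int = 3
    coexist_min_d_rel_diff: float = 0.05
    sharp_fwhm_bins: float = 3.0  # sharp/broad split at this many bin widths
    peak_shape_saxs: str = "gaussian"
    peak_shape_waxs: str = "pseudo-voigt"


@dataclass
class PhasePoint:
    """Phase assessment of one sample at one temperature."""

    meta: SampleMeta
    state: str  # gel | fluid | coexistence | unknown
    series: list[LamellarSeries] = field(default_factory=list)
    waxs_gel_peak: Peak | None = None
    trace: list[str] = field(default_factory=list)

    def series_by_phase(self, phase: str) -> LamellarSeries | None:
        for s in self.series:
            if s.phase == phase:
                return s
        return None


def _match_candidate(peaks, q1, rel_tolerance, max_order):
    """Assign peaks to integer orders of candidate fundamental q1.

    Returns (assignments, rms).  At most one peak per order; the closest
    wins.  A peak matches order h when |q0 - h q1| <= rel_tolerance * h q1.
    """
    by_order: dict[int, tuple[float, Peak]] = {}
    for p in peaks:
        h = int(round(p.q0 / q1))
        if not 1 <= h <= max_order:
            continue
        resid = p.q0 - h * q1
        if abs(resid) > rel_tolerance * h * q1:
            continue
        if h not in by_order or abs(resid) < abs(by_order[h][0]):
            by_order[h] = (resid, p)
    if not by_order:
        return [], float("inf")
    # keep only the consecutive run h = 1, 2, ... (an isolated high order
    # beyond a gap is more plausibly another series or an artifact)
    run = []
    for h in range(1, max_order + 1):
        if h not in by_order:
            break
        run.append(h)
    if not run:
        return [], float("inf")
    assignments = [
        OrderAssignment(h=h, peak=by_order[h][1], residual=by_order[h][0])
        for h in run
    ]
    rms = float(np.sqrt(np.mean([a.residual**2 for a in assignments])))
    return assignments, rms


def _refine_q1(assignments):
    """Weighted least-squares fundamental from q_h ~ h * q1.

    Weights are inverse-variance from the per-peak center errors when
    available, else unity.  Returns (q1, q1_err).
    """
    h = np.array([a.h for a in assignments], dtype=float)
    qv = np.array([a.peak.q0 for a in assignments])
    sig = np.array(
        [
            a.peak.stderr.get("center", float("nan"))
            for a in assignments
        ]
    )
    w = np.where(np.isfinite(sig) & (sig > 0), 1.0 / sig**2, np.nan)
    if not np.all(np.isfinite(w)):
        w = np.ones_like(h)
    q1 = float(np.sum(w * h * qv) / np.sum(w * h**2))
    q1_err = float(1.0 / np.sqrt(np.sum(w * h**2))) if np.all(np.isfinite(sig)) else float("nan")
    return q1, q1_err


def group_series(
    peaks: list[Peak],
    rel_tolerance: float = 0.015,
    max_order: int = 6,
    max_fundamental_divisor: int = 3,
) -> list[LamellarSeries]:
    """Greedy indexing of peaks into lamellar series.

    Candidate fundamentals are q0 / h for every peak and h up to
    ``max_fundamental_divisor``; each candidate is scored by the number of
    peaks it matches at integer multiples within the relative tolerance,
    ties broken by the smaller RMS residual.  A series must be a
    consecutive run of orders starting at the fundamental (a d-spacing
    inferred from gapped high orders is ambiguous).
    The best candidate is accepted, its peaks removed, and the search
    repeats.  Leftover single peaks are returned as one-order series with
    phase 'unknown' (orphans).
    """
    remaining = sorted(peaks, key=lambda p: p.q0)
    series: list[LamellarSeries] = []
    while len(remaining) >= 2:
        best = None
        for p in remaining:
            for hdiv in range(1, max_fundamental_divisor + 1):
                q1c = p.q0 / hdiv
                assigned, rms = _match_candidate(
                    remaining, q1c, rel_tolerance, max_order
                )
                if len(assigned) < 2 or assigned[0].h != 1:
                    continue
                key = (len(assigned), -rms)
                if best is None or key > best[0]:
                    best = (key, assigned)
        if best is None:
            break
        assigned = best[1]
        q1, q1_err = _refine_q1(assigned)
        # re-snap assignments to the refined fundamental
        assigned = [
            OrderAssignment(h=a.h, peak=a.peak, residual=a.peak.q0 - a.h * q1)
            for a in assigned
        ]
        series.append(LamellarSeries(q1=q1, orders=assigned, q1_err=q1_err))
        matched = {id(a.peak) for a in assigned}
        remaining = [p for p in remaining if id(p) not in matched]
    for p in remaining:  # orphans become single-order series
        series.append(
            LamellarSeries(
                q1=p.q0,
                orders=[OrderAssignment(h=1, peak=p, residual=0.0)],
                q1_err=p.stderr.get("center", float("nan")),
            )
        )
    series.sort(key=lambda s: (-s.n_orders, s.q1))
    return series


def dspacing(series: LamellarSeries) -> tuple[float, float]:
    """Lamellar repeat distance (nm) and its propagated uncertainty."""
    if series.n_orders < 1:
        raise ValueError("series has no orders")
    return series.d, series.d_err


def classify_phase(
    series: LamellarSeries,
    waxs_peaks: list[Peak] | None = None,
    sharp_fwhm_threshold: float = 0.002,
) -> str:
    """Gel/fluid signature of one indexed series.

    gel: >= 3 orders, or >= 2 sharp orders confirmed by a wide-angle
    chain-packing peak in [1.45, 1.65] 1/Angstrom; fluid: <= 2 broad
    orders; otherwise unknown.  The decision depends only on peak count,
    width and the WAXS window — never on absolute intensity.
    """
    waxs_hit = any(
        WAXS_CHAIN_WINDOW[0] <= p.q0 <= WAXS_CHAIN_WINDOW[1]
        for p in (waxs_peaks or [])
    )
    fwhm1 = series.orders[0].peak.fwhm
    sharp = fwhm1 < sharp_fwhm_threshold
    if series.n_orders >= 3:
        return "gel"
    if series.n_orders >= 2 and waxs_hit and sharp:
        return "gel"
    if series.n_orders == 2 and not sharp:
        return "fluid"
    return "unknown"


def _analyze_profile(profile, settings, shape):
    base = estimate_baseline(
        profile,
        smoothness=settings.baseline_smoothness,
        asymmetry=settings.baseline_asymmetry,
    )
    cand = detect_peaks(
        profile, base, min_prominence_sigmas=settings.min_prominence_sigmas
    )
    if not cand:
        return base, []
    peaks = fit_peaks(profile, base, cand, shape=shape)
    return base, peaks


def assess_point(
    saxs: ScatteringProfile,
    waxs: ScatteringProfile | None = None,
    settings: AnalysisSettings | None = None,
) -> PhasePoint:
    """Full chain baseline -> detect -> fit -> index -> classify for one sample.

    Coexistence requires at least two multi-order series whose repeat
    distances differ by more than the configured relative threshold
    (default 5%), guarding against one series split by fit jitter.
    """
    settings = settings or AnalysisSettings()
    if waxs is not None and waxs.meta.label and saxs.meta.label:
        if waxs.meta.label != saxs.meta.label:
            raise ValueError("SAXS and WAXS profiles carry different sample labels")
    trace: list[str] = []
    _, peaks = _analyze_profile(saxs, settings, settings.peak_shape_saxs)
    trace.append(f"saxs: {len(peaks)} fitted peaks")
    waxs_peaks: list[Peak] = []
    if waxs is not None:
        _, wpk = _analyze_profile(waxs, settings, settings.peak_shape_waxs)
        waxs_peaks = [
            p for p in wpk if WAXS_CHAIN_WINDOW[0] <= p.q0 <= WAXS_CHAIN_WINDOW[1]
        ]
        for p in waxs_peaks:
            p.miller_label = "d20"
        trace.append(f"waxs: {len(waxs_peaks)} chain-window peaks")
    series = group_series(
        peaks,
        rel_tolerance=settings.rel_tolerance,
        max_order=settings.max_order,
        max_fundamental_divisor=settings.max_fundamental_divisor,
    )
    sharp_thr = settings.sharp_fwhm_bins * saxs.bin_width
    for s in series:
        s.phase = classify_phase(s, waxs_peaks, sharp_fwhm_threshold=sharp_thr)
        trace.append(
            f"series q1={s.q1:.4f} d={s.d:.3f} nm n={s.n_orders} -> {s.phase}"
        )
    multi = [s for s in series if s.n_orders >= 2]
    state = "unknown"
    if multi:
        distinct = any(
            abs(a.d - b.d) / max(a.d, b.d) > settings.coexist_min_d_rel_diff
            for i, a in enumerate(multi)
            for b in multi[i + 1 :]
        )
        if len(multi) >= 2 and distinct:
            state = "coexistence"
        else:
            state = multi[0].phase if multi[0].phase != "unknown" else "unknown"
    trace.append(f"state: {state}")
    return PhasePoint(
        meta=saxs.meta,
        state=state,
        series=series,
        waxs_gel_peak=waxs_peaks[0] if waxs_peaks else None,
        trace=trace,
    )


@dataclass
class PhaseDiagram:
    """(composition, temperature) -> state grid with per-composition T_m."""

    points: list[PhasePoint]
    table: pd.DataFrame
    tm: dict[float, float | None]
    contiguity_violations: list[str] = field(default_factory=list)


def _tm_for_column(states: pd.Series) -> tuple[float | None, str]:
    """Melting temperature for one composition column (sorted by T).

    Midpoint between the warmest non-fluid temperature and the coolest
    fluid-only temperature when both exist; the boundary sample otherwise.
    """
    fluid_ts = states.index[states == "fluid"]
    nonfluid_ts = states.index[states.isin(["gel", "coexistence"])]
    if len(fluid_ts) and len(nonfluid_ts):
        return (max(nonfluid_ts) + min(fluid_ts)) / 2.0, "bracketed"
    if len(fluid_ts):
        return float(min(fluid_ts)), "unbounded below"
    return None, "above sampled range"


def build_phase_diagram(points: list[PhasePoint]) -> PhaseDiagram:
    """Assemble assessed points into a phase diagram.

    Checks the expected monotonic ordering gel -> coexistence -> fluid with
    temperature per composition; violations are flagged in
    ``contiguity_violations``, never hidden.
    """
    if not points:
        raise ValueError("no phase points supplied")
    rows = [
        {
            "dha_molpercent": p.meta.dha_molpercent,
            "temperature": p.meta.temperature,
            "state": p.state,
            "d_gel": (s.d if (s := p.series_by_phase("gel")) else np.nan),
            "d_fluid": (s.d if (s := p.series_by_phase("fluid")) else np.nan),
        }
        for p in points
    ]
    table = pd.DataFrame(rows).sort_values(["dha_molpercent", "temperature"])
    comps = sorted(table["dha_molpercent"].unique())
    if len(table.groupby("dha_molpercent")) < 1 or all(
        len(g) < 2 for _, g in table.groupby("dha_molpercent")
    ):
        log.warning("phase diagram built from fewer than 2 temperatures per composition")
    tm: dict[float, float | None] = {}
    violations: list[str] = []
    rank = {"gel": 0, "coexistence": 1, "fluid": 2, "unknown": -1}
    for c in comps:
        col = table[table["dha_molpercent"] == c].set_index("temperature")["state"]
        col = col.sort_index()
        tmc, flag = _tm_for_column(col)
        tm[c] = tmc
        known = col[col != "unknown"]
        ranks = [rank[s] for s in known]
        if any(b < a for a, b in zip(ranks, ranks[1:])):
            violations.append(
                f"non-monotonic state sequence at {c:g} mol%: {list(known)}"
            )
        if flag != "bracketed" and tmc is not None:
            log.info("T_m at %g mol%% is %s", c, flag)
    return PhaseDiagram(
        points=points, table=table.reset_index(drop=True), tm=tm,
        contiguity_violations=violations,
    )
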