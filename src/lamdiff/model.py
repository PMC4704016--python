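"""Model/Results interface over the profile-analysis chain.

``LamellarModel`` wraps one SAXS profile (optionally with its WAXS
companion) the way a statistical model wraps a dataset: construction
validates the inputs, ``fit()`` runs baseline estimation, peak detection,
nonlinear peak fitting, lamellar indexing and phase classification, and
returns a ``LamellarResults`` carrying the indexed series, their repeat
distances with uncertainties, the phase state and a ``summary()`` table.
Electron-density reconstruction and tilt estimates hang off the results
object.
"""

from __future__ import annotations

import numpy as np

from .edp import EDProfile, edp_from_series
from .forward import ScatteringProfile
from .geometry import DPPC_REFERENCE, TiltEstimate, TiltReference, tilt_from_dpp
from .lamellar import AnalysisSettings, PhasePoint, assess_point

__all__ = ["LamellarModel", "LamellarResults"]


class LamellarModel:
    """Lamellar diffraction model for one powder profile."""

    def __init__(
        self,
        saxs: ScatteringProfile,
        waxs: ScatteringProfile | None = None,
        settings: AnalysisSettings | None = None,
    ):
        if saxs.mode != "SAXS":
            raise ValueError("primary profile must be in SAXS mode")
        if waxs is not None and waxs.mode != "WAXS":
            raise ValueError("companion profile must be in WAXS mode")
        self.saxs = saxs
        self.waxs = waxs
        self.settings = settings or AnalysisSettings()

    @classmethod
    def from_files(cls, saxs_path, waxs_path=None, settings=None) -> "LamellarModel":
        from .io import read_profile

        saxs = read_profile(saxs_path)
        waxs = read_profile(waxs_path) if waxs_path else None
        return cls(saxs, waxs, settings)

    def fit(self) -> "LamellarResults":
        point = assess_point(self.saxs, self.waxs, self.settings)
        return LamellarResults(self, point)


class LamellarResults:
    """Fitted lamellar series, phase state and derived structural lengths."""

    def __init__(self, model: LamellarModel, phase_point: PhasePoint):
        self.model = model
        self.phase_point = phase_point

    @property
    def state(self) -> str:
        return self.phase_point.state

    @property
    def series(self):
        return self.phase_point.series

    @property
    def d_spacings(self) -> dict[str, float]:
        """Repeat distance (nm) per classified phase label."""
        out = {}
        for s in self.series:
            key = s.phase if s.phase != "unknown" else f"unknown@{s.q1:.3f}"
            out.setdefault(key, s.d)
        return out

    def edp(
        self,
        phase: str | int = 0,
        signs=None,
        factor_table=None,
        n_z: int = 513,
    ) -> EDProfile:
        """Electron-density profile of one series (by phase label or index)."""
        if isinstance(phase, str):
            s = self.phase_point.series_by_phase(phase)
            if s is None:
                raise ValueError(f"no series classified as {phase!r}")
        else:
            s = self.series[phase]
        return edp_from_series(s, signs=signs, factor_table=factor_table, n_z=n_z)

    def tilt(
        self, phase: str = "gel", reference: TiltReference = DPPC_REFERENCE
    ) -> TiltEstimate:
        """Chain tilt of the gel fraction from its corrected d_pp."""
        prof = self.edp(phase)
        return tilt_from_dpp(prof.d_pp, reference)

    def summary(self) -> str:
        m = self.phase_point.meta
        lines = [
            "Lamellar diffraction analysis",
            "=" * 60,
            f"sample: {m.label or '(unlabelled)'}   "
            f"{m.dha_molpercent:g} mol%   {m.temperature:g} C",
            f"phase state: {self.state}",
            "",
            f"{'phase':<10}{'d (nm)':>8}{'+/-':>8}{'orders':>8}{'q1 (1/A)':>11}",
            "-" * 45,
        ]
        for s in self.series:
            err = f"{s.d_err:.3f}" if np.isfinite(s.d_err) else "--"
            lines.append(
                f"{s.phase:<10}{s.d:>8.3f}{err:>8}{s.n_orders:>8}{s.q1:>11.4f}"
            )
        if self.phase_point.waxs_gel_peak is not None:
            p = self.phase_point.waxs_gel_peak
            lines += [
                "",
                f"WAXS chain peak: q = {p.q0:.3f} 1/A "
                f"(d20 = {2 * np.pi / p.q0:.3f} A)",
            ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Quick-look plot of the profile with indexed order positions."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        p = self.model.saxs
        ax.plot(p.q, p.intensity, lw=0.8, color="k", label="data")
        colors = {"gel": "tab:blue", "fluid": "tab:red", "unknown": "tab:gray"}
        for s in self.series:
            for o in s.orders:
                ax.axvline(
                    o.h * s.q1, color=colors.get(s.phase, "tab:gray"),
                    ls="--", lw=0.7, alpha=0.7,
                )
        ax.set_xlabel(r"q ($\mathrm{\AA}^{-1}$)")
        ax.set_ylabel("intensity (counts)")
        ax.set_title(f"{p.meta.label}: {self.state}")
        return ax
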