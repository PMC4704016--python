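"""Chain-tilt geometry of the gel phase and WAXS chain-packing spacings.

The tilt model is reference-calibrated: a known bilayer (repeat distance
d_ref, water layer d_w_ref, tilt theta_ref) fixes the effective chain span
L_eff = (d_ref - d_w_ref) / cos(theta_ref); a measured head-to-head
distance then implies theta = arccos(d_pp / L_eff).  Tilt increases as the
bilayer thins at fixed chain length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TiltReference",
    "TiltEstimate",
    "DPPC_REFERENCE",
    "make_reference",
    "tilt_from_dpp",
    "waxs_spacing",
]


@dataclass(frozen=True)
class TiltReference:
    """Reference bilayer geometry fixing the effective chain span."""

    d_ref: float  # nm
    d_w_ref: float  # nm
    theta_ref: float  # degrees
    l_eff: float  # nm, derived

    def __post_init__(self):
        if not 0.0 <= self.theta_ref < 90.0:
            raise ValueError("reference tilt must lie in [0, 90) degrees")


@dataclass(frozen=True)
class TiltEstimate:
    theta: float  # degrees
    d_pp: float  # nm
    reference: TiltReference


def make_reference(d_ref: float, d_w_ref: float, theta_ref: float) -> TiltReference:
    """Build a tilt reference; L_eff = (d_ref - d_w_ref) / cos(theta_ref)."""
    if d_w_ref >= d_ref:
        raise ValueError("water layer must be thinner than the repeat distance")
    c = np.cos(np.radians(theta_ref))
    if c <= 0.0 or not 0.0 <= theta_ref < 90.0:
        raise ValueError("reference tilt must lie in [0, 90) degrees")
    return TiltReference(
        d_ref=float(d_ref), d_w_ref=float(d_w_ref), theta_ref=float(theta_ref),
        l_eff=float((d_ref - d_w_ref) / c),
    )


# Fully hydrated DPPC gel bilayer: d = 6.4 nm, d_w = 1.83 nm, tilt 32.6 deg.
DPPC_REFERENCE = make_reference(6.40, 1.83, 32.6)


def tilt_from_dpp(d_pp: float, reference: TiltReference = DPPC_REFERENCE) -> TiltEstimate:
    """Chain tilt implied by a head-to-head distance: theta = arccos(d_pp/L_eff)."""
    if d_pp <= 0:
        raise ValueError("d_pp must be > 0")
    ratio = d_pp / reference.l_eff
    if ratio > 1.0 + 1e-12:
        raise ValueError(
            f"d_pp = {d_pp:.3f} nm exceeds the effective chain span "
            f"{reference.l_eff:.3f} nm: no real tilt angle exists"
        )
    theta = float(np.degrees(np.arccos(min(ratio, 1.0))))
    return TiltEstimate(theta=theta, d_pp=d_pp, reference=reference)


def waxs_spacing(q_chain: float) -> float:
    """Real-space chain-packing spacing d = 2 pi / q (both in Angstrom units)."""
    if q_chain <= 0:
        raise ValueError("q must be > 0")
    return 2.0 * np.pi / q_chain
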