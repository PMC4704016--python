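"""Reading and writing the pipeline's on-disk formats.

1D profiles are two-column whitespace-delimited text (q in 1/Angstrom,
intensity in counts) with a commented header carrying the sample metadata;
detector images are 16-bit grayscale TIFF; ground-truth labels and result
tables are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .forward import (
    InstrumentConfig,
    PhaseGridPoint,
    PowderImage,
    SampleMeta,
    ScatteringProfile,
)

__all__ = [
    "write_profile",
    "read_profile",
    "write_image",
    "read_image",
    "write_truth_labels",
    "read_truth_labels",
    "write_edp_result",
]


def write_profile(profile: ScatteringProfile, path) -> Path:
    path = Path(path)
    header = [
        f"# mode = {profile.mode}",
        f"# dha_molpercent = {profile.meta.dha_molpercent:g}",
        f"# temperature_C = {profile.meta.temperature:g}",
        f"# label = {profile.meta.label}",
        "# columns = q_invA intensity_counts"
        + (" uncertainty_counts" if profile.uncertainty is not None else ""),
    ]
    cols = [profile.q, profile.intensity]
    if profile.uncertainty is not None:
        cols.append(profile.uncertainty)
    body = np.column_stack(cols)
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        np.savetxt(fh, body, fmt="%.8g")
    return path


def read_profile(path) -> ScatteringProfile:
    path = Path(path)
    meta_kv: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                k, v = line.lstrip("# ").split("=", 1)
                meta_kv[k.strip()] = v.strip()
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path} is not a two-column profile")
    meta = SampleMeta(
        dha_molpercent=float(meta_kv.get("dha_molpercent", 0.0)),
        temperature=float(meta_kv.get("temperature_C", 20.0)),
        label=meta_kv.get("label", path.stem),
    )
    unc = data[:, 2] if data.shape[1] > 2 else None
    return ScatteringProfile(
        q=data[:, 0],
        intensity=data[:, 1],
        uncertainty=unc,
        meta=meta,
        mode=meta_kv.get("mode", "SAXS"),
    )


def write_image(image: PowderImage, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, image.counts.astype(np.uint16))
    return path


def read_image(path, geometry: InstrumentConfig) -> PowderImage:
    counts = tifffile.imread(Path(path))
    return PowderImage(counts=counts, geometry=geometry)


def write_truth_labels(points: list[PhaseGridPoint], path) -> Path:
    path = Path(path)
    rows = [
        {
            "dha_molpercent": p.meta.dha_molpercent,
            "temperature": p.meta.temperature,
            "label": p.meta.label,
            "state": p.state,
            "d_gel": p.d_gel if p.d_gel is not None else "",
            "d_fluid": p.d_fluid if p.d_fluid is not None else "",
            "ripple_flag": p.ripple_flag,
        }
        for p in points
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_truth_labels(path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def write_edp_result(profile, path_prefix) -> tuple[Path, Path]:
    """Write an EDP as CSV (z, rho) plus a JSON sidecar of derived lengths."""
    prefix = Path(path_prefix)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    pd.DataFrame({"z_nm": profile.z, "rho": profile.rho}).to_csv(
        csv_path, index=False
    )
    sidecar = {
        "d_nm": profile.d,
        "d_pp_raw_nm": profile.d_pp_raw,
        "correction_factor": profile.correction_factor,
        "d_pp_nm": profile.d_pp,
        "d_w_nm": profile.d_w,
        "signs": list(profile.signs),
        "n_orders": profile.n_orders_used,
        "boundary_flag": profile.boundary_flag,
    }
    json_path.write_text(json.dumps(sidecar, indent=2))
    return csv_path, json_path
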