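"""Writing and reading sweep outputs: tidy CSV, surfaces, manifest, compliance."""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import dosimetry
from .montecarlo import SweepConfig, SweepSummary

__all__ = [
    "write_summary",
    "read_summary",
    "export_surface",
    "build_manifest",
    "write_manifest",
    "compliance_report",
    "SURFACE_QUANTITIES",
]

#: exportable surface quantities → summary column (APD_db is derived)
SURFACE_QUANTITIES = {
    "T_mean": "t_mean",
    "APD_mean": "apd_mean_wm2",
    "APD_db": None,
    "ratio": "apd_ratio",
}


def write_summary(summary: SweepSummary, path) -> Path:
    """Write the per-cell table as RFC-4180 CSV at full double precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    summary.data.to_csv(path, index=False)
    return path


def read_summary(path, config: SweepConfig | None = None) -> SweepSummary:
    df = pd.read_csv(path, keep_default_na=False,
                     na_values=[""], dtype={"error": str})
    if "error" in df.columns:
        df["error"] = df["error"].fillna("")
    return SweepSummary(df, config if config is not None else SweepConfig())


def export_surface(summary: SweepSummary, quantity: str, material: str,
                   polarization: str) -> pd.DataFrame:
    """Long-form θ0 × z_air surface for one material and polarization.

    ``APD_db`` is the mean APD normalized to the surface maximum,
    10·log10(APD/APD_max), so the peak cell is exactly 0 dB.
    """
    if quantity not in SURFACE_QUANTITIES:
        raise ValueError(f"unknown quantity {quantity!r}; choose from {sorted(SURFACE_QUANTITIES)}")
    df = summary.data
    sub = df[(df["material"] == material) & (df["polarization"] == polarization)]
    if sub.empty:
        raise KeyError(f"no cells for material={material!r}, polarization={polarization!r}")
    sub = sub.sort_values(["theta0_deg", "z_air_mm"])
    if quantity == "APD_db":
        values = dosimetry.normalized_apd_db(sub["apd_mean_wm2"].to_numpy())
        col = "apd_norm_db"
    else:
        src = SURFACE_QUANTITIES[quantity]
        values = sub[src].to_numpy()
        col = {"t_mean": "transmittance_mean",
               "apd_mean_wm2": "apd_mean_wm2",
               "apd_ratio": "apd_ratio_clothed_over_bare"}[src]
    return pd.DataFrame({
        "theta0_deg": sub["theta0_deg"].to_numpy(),
        "z_air_mm": sub["z_air_mm"].to_numpy(),
        col: values,
    })


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(summary: SweepSummary, outputs: dict[str, Path]) -> dict:
    """Everything needed to re-run the identical sweep, plus file inventory."""
    return {
        "package": "mmwdosim",
        "version": __version__,
        "config": summary.config.to_dict(),
        "seed": summary.config.seed,
        "n_cells": int(len(summary.data)),
        "runtime_s": round(summary.runtime_s, 3),
        "outputs": {name: {"path": str(p), "sha256": _sha256(Path(p))}
                    for name, p in outputs.items()},
    }


def write_manifest(manifest: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def compliance_report(summary: SweepSummary,
                      basic_restriction: float = dosimetry.BASIC_RESTRICTION_WM2) -> dict:
    """Check every cell's mean (and mean+SD) APD against the basic restriction."""
    df = summary.data
    res = dosimetry.compliance_check(df["apd_mean_wm2"].to_numpy(), basic_restriction)
    worst = df.loc[df["apd_mean_wm2"].idxmax()]
    return {
        "basic_restriction_wm2": basic_restriction,
        "passed": res.passed,
        "max_mean_apd_wm2": res.max_apd_wm2,
        "margin_wm2": res.margin_wm2,
        "worst_cell": {
            "material": str(worst["material"]),
            "polarization": str(worst["polarization"]),
            "theta0_deg": float(worst["theta0_deg"]),
            "z_air_mm": float(worst["z_air_mm"]),
        },
        "n_cells": int(len(df)),
        "n_exceeding": int((df["apd_mean_wm2"] > basic_restriction).sum()),
    }
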