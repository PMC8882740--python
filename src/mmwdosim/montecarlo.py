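"""Monte Carlo sweep engine over (material, polarization, θ0, z_air) cells.

Each cell evaluates ``n_iterations`` thickness realizations of the clothed
stack together with a paired bare-skin stack sharing the identical skin-layer
draws (common random numbers), then aggregates means, standard deviations,
relative SDs and clothed/bare ratios of transmittance and APD.

Seeding: skin draws are keyed by (master seed, θ index) and cloth draws by
(master seed, material index, θ index) through numpy ``SeedSequence`` spawn
keys.  Draws are therefore shared across air-gap values and polarizations,
which (a) makes the bare reference identical for every material and air gap
at a given angle and (b) removes Monte Carlo noise from the air-gap
fluctuation surfaces; sweeps are reproducible independent of evaluation
order.
"""
from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import dosimetry
from .em_core import PlaneWaveExcitation, TE, TM
from .materials import (
    CLOTH_CODES,
    MaterialSpec,
    StackRealization,
    cloth_material,
    default_registry,
    sample_thickness,
)

__all__ = [
    "SweepConfig",
    "SweepSummary",
    "BrewsterResult",
    "parse_grid",
    "run_sweep",
    "brewster_angle",
    "band_statistic",
]

_SAMPLED_SKIN = ("epidermis", "dermis", "fat")  # muscle terminates, unsampled


def parse_grid(spec) -> np.ndarray:
    """Build a grid from ``start:stop:step`` text (stop inclusive), a mapping,
    or an explicit sequence."""
    if isinstance(spec, str):
        start, stop, step = (float(x) for x in spec.split(":"))
    elif isinstance(spec, dict):
        start, stop, step = float(spec["start"]), float(spec["stop"]), float(spec["step"])
    else:
        arr = np.asarray(spec, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("grid must be a nonempty 1-D sequence")
        return arr
    if step <= 0 or stop < start:
        raise ValueError(f"bad grid {spec!r}")
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


@dataclass(frozen=True)
class SweepConfig:
    """Study configuration; defaults reproduce the 60 GHz clothed-skin setup."""

    materials: tuple = CLOTH_CODES
    polarizations: tuple = (TE, TM)
    theta0_deg: tuple = ("0:80:1",)
    z_air_mm: tuple = ("0:5:0.1",)
    n_iterations: int = 10_000
    seed: int = 1
    frequency_hz: float = 60e9
    incident_power_density: float = 26.6

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if len(self.materials) == 0 or len(self.polarizations) == 0:
            raise ValueError("materials and polarizations must be nonempty")
        for p in self.polarizations:
            if p not in (TE, TM):
                raise ValueError(f"unknown polarization {p!r}")
        th = self.theta_grid()
        if np.any(th >= 90.0) or np.any(th < 0.0):
            raise ValueError("theta0 grid must lie in [0, 90)")
        if np.any(self.zair_grid() < 0.0):
            raise ValueError("z_air grid must be >= 0")

    def theta_grid(self) -> np.ndarray:
        spec = self.theta0_deg[0] if (isinstance(self.theta0_deg, tuple)
                                      and len(self.theta0_deg) == 1
                                      and isinstance(self.theta0_deg[0], (str, dict))) \
            else self.theta0_deg
        return parse_grid(spec)

    def zair_grid(self) -> np.ndarray:
        spec = self.z_air_mm[0] if (isinstance(self.z_air_mm, tuple)
                                    and len(self.z_air_mm) == 1
                                    and isinstance(self.z_air_mm[0], (str, dict))) \
            else self.z_air_mm
        return parse_grid(spec)

    def to_dict(self) -> dict:
        return {
            "materials": list(self.materials),
            "polarizations": list(self.polarizations),
            "theta0_deg": (self.theta0_deg[0] if isinstance(self.theta0_deg, tuple)
                           and len(self.theta0_deg) == 1 else list(self.theta0_deg)),
            "z_air_mm": (self.z_air_mm[0] if isinstance(self.z_air_mm, tuple)
                         and len(self.z_air_mm) == 1 else list(self.z_air_mm)),
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "frequency_hz": self.frequency_hz,
            "incident_power_density": self.incident_power_density,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SweepConfig":
        kw = {}
        for key in ("materials", "polarizations"):
            if key in doc:
                kw[key] = tuple(doc[key])
        for key in ("theta0_deg", "z_air_mm"):
            if key in doc:
                v = doc[key]
                kw[key] = (v,) if isinstance(v, (str, dict)) else tuple(v)
        for key in ("n_iterations", "seed"):
            if key in doc:
                kw[key] = int(doc[key])
        for key in ("frequency_hz", "incident_power_density"):
            if key in doc:
                kw[key] = float(doc[key])
        return cls(**kw)

    @classmethod
    def from_file(cls, path) -> "SweepConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(doc)


@dataclass
class SweepSummary:
    """Tidy per-cell statistics plus run metadata."""

    data: pd.DataFrame
    config: SweepConfig
    runtime_s: float = 0.0

    def cell(self, material: str, polarization: str, theta0_deg: float, z_air_mm: float) -> pd.Series:
        df = self.data
        m = (
            (df["material"] == material)
            & (df["polarization"] == polarization)
            & np.isclose(df["theta0_deg"], theta0_deg)
            & np.isclose(df["z_air_mm"], z_air_mm)
        )
        sub = df[m]
        if len(sub) != 1:
            raise KeyError(f"cell ({material}, {polarization}, {theta0_deg}, {z_air_mm}) "
                           f"matched {len(sub)} rows")
        return sub.iloc[0]


def _spawn_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _stats(arr: np.ndarray, axis=0):
    mean = arr.mean(axis=axis)
    if arr.shape[axis] > 1:
        sd = arr.std(axis=axis, ddof=1)
        # degenerate draws (all identical) have exactly zero dispersion
        sd = np.where(arr.max(axis=axis) == arr.min(axis=axis), 0.0, sd)
    else:
        sd = np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = np.where(mean != 0.0, 100.0 * sd / mean, np.nan)
    return mean, sd, rsd


def run_sweep(config: SweepConfig, registry=None, progress: bool = False) -> SweepSummary:
    """Run the full Monte Carlo sweep defined by ``config``."""
    t0 = time.perf_counter()
    reg = default_registry() if registry is None else registry
    theta_grid = config.theta_grid()
    zair = config.zair_grid()
    n = config.n_iterations
    air = reg["air"]
    skin_specs = [reg[name] for name in _SAMPLED_SKIN]
    muscle = reg["muscle"]
    cloths = {code: cloth_material(code, reg) for code in config.materials}
    # canonical material index for seeding, stable across config subsets
    mat_index = {code: (CLOTH_CODES.index(code) if code in CLOTH_CODES else 100 + k)
                 for k, code in enumerate(config.materials)}

    rows = []
    for ti, theta in enumerate(theta_grid):
        rng_skin = _spawn_rng(config.seed, 0, ti)
        skin_draws = [sample_thickness(s, rng_skin, n)[:, None] for s in skin_specs]
        bare = StackRealization.from_layers(
            [("air", air.epsilon, None)]
            + [(s.name, s.epsilon, d) for s, d in zip(skin_specs, skin_draws)]
            + [("muscle", muscle.epsilon, None)],
            skin_interface=1,
        )
        cloth_draws = {
            code: sample_thickness(spec, _spawn_rng(config.seed, 1, mat_index[code], ti), n)[:, None]
            for code, spec in cloths.items()
        }
        for pol in config.polarizations:
            exc = PlaneWaveExcitation(float(theta), pol, config.frequency_hz,
                                      config.incident_power_density)
            res_b = dosimetry.evaluate(bare, exc)
            bt_mean, bt_sd, _ = _stats(np.ravel(res_b.transmittance))
            ba_mean, ba_sd, _ = _stats(np.ravel(res_b.apd))
            for code, spec in cloths.items():
                clothed = StackRealization.from_layers(
                    [("air", air.epsilon, None),
                     (spec.name, spec.epsilon, cloth_draws[code]),
                     ("air_gap", 1.0 + 0.0j, zair[None, :])]
                    + [(s.name, s.epsilon, d) for s, d in zip(skin_specs, skin_draws)]
                    + [("muscle", muscle.epsilon, None)],
                    skin_interface=3,
                )
                err = ""
                try:
                    res = dosimetry.evaluate(clothed, exc)
                    t_mean, t_sd, t_rsd = _stats(np.asarray(res.transmittance))
                    a_mean, a_sd, a_rsd = _stats(np.asarray(res.apd))
                except Exception as exc_err:  # pragma: no cover - defensive
                    err = str(exc_err)
                    nanz = np.full(zair.shape, np.nan)
                    t_mean = t_sd = t_rsd = a_mean = a_sd = a_rsd = nanz
                rows.append(pd.DataFrame({
                    "material": code,
                    "polarization": pol,
                    "theta0_deg": float(theta),
                    "z_air_mm": zair,
                    "t_mean": t_mean,
                    "t_sd": t_sd,
                    "t_rsd_pct": t_rsd,
                    "apd_mean_wm2": a_mean,
                    "apd_sd_wm2": a_sd,
                    "apd_rsd_pct": a_rsd,
                    "bare_t_mean": bt_mean,
                    "bare_t_sd": bt_sd,
                    "bare_apd_mean_wm2": ba_mean,
                    "bare_apd_sd_wm2": ba_sd,
                    "t_ratio": t_mean / bt_mean,
                    "apd_ratio": a_mean / ba_mean,
                    "error": err,
                }))
        if progress:
            print(f"theta {theta:5.1f} deg done "
                  f"({(ti + 1) * len(config.polarizations) * len(cloths) * len(zair)} cells)",
                  flush=True)
    df = pd.concat(rows, ignore_index=True)
    return SweepSummary(df, config, runtime_s=time.perf_counter() - t0)


@dataclass(frozen=True)
class BrewsterResult:
    angle_deg: float
    boundary: bool  # True when the grid maximum sits on the grid edge
    t_max: float


def brewster_angle(summary: SweepSummary, material: str, z_air_mm: float,
                   polarization: str = TM) -> BrewsterResult:
    """Maximum-transmittance angle of the mean-transmittance curve.

    The grid argmax is refined by quadratic interpolation through its two
    neighbours; an edge maximum (no interior peak, e.g. TE curves that fall
    monotonically from normal incidence) is flagged as ``boundary``.
    """
    df = summary.data
    sub = df[(df["material"] == material)
             & (df["polarization"] == polarization)
             & np.isclose(df["z_air_mm"], z_air_mm)].sort_values("theta0_deg")
    if sub.empty:
        raise KeyError(f"no cells for ({material}, {polarization}, z_air={z_air_mm})")
    theta = sub["theta0_deg"].to_numpy()
    y = sub["t_mean"].to_numpy()
    i = int(np.argmax(y))
    if i == 0 or i == len(y) - 1:
        return BrewsterResult(float(theta[i]), True, float(y[i]))
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0.0:
        return BrewsterResult(float(theta[i]), False, float(y[i]))
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    step = theta[i + 1] - theta[i]
    return BrewsterResult(float(theta[i] + delta * step), False, float(y[i]))


def band_statistic(summary: SweepSummary, statistic: str, theta_max_deg: float,
                   polarization: str | None = None,
                   materials: Sequence[str] | None = None) -> float:
    """Aggregate a named statistic over all cells with θ0 < ``theta_max_deg``.

    Statistics: ``max_rel_sd`` (largest APD relative SD, %),
    ``min_db_variation`` (smallest per-surface-normalized mean APD, dB),
    ``max_ratio`` (largest clothed/bare mean-APD ratio).
    """
    df = summary.data
    mask = df["theta0_deg"] < theta_max_deg
    if polarization is not None:
        mask &= df["polarization"] == polarization
    if materials is not None:
        mask &= df["material"].isin(list(materials))
    sub = df[mask]
    if sub.empty:
        raise ValueError("empty band")
    if statistic == "max_rel_sd":
        return float(sub["apd_rsd_pct"].max())
    if statistic == "max_ratio":
        return float(sub["apd_ratio"].max())
    if statistic == "min_db_variation":
        worst = np.inf
        for (_m, _p), grp in sub.groupby(["material", "polarization"]):
            db = dosimetry.normalized_apd_db(grp["apd_mean_wm2"].to_numpy())
            worst = min(worst, float(np.min(db)))
        return worst
    raise ValueError(f"unknown statistic {statistic!r}")
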