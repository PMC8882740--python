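"""Dielectric data for cloth and skin layers, stack templates and thickness sampling.

The registry holds the published 60 GHz complex relative permittivities and
thickness statistics (mean ± SD, in mm) for six textile materials (M1–M6) and
the four-layer abdominal skin model (epidermis, dermis, subcutaneous fat,
muscle).  Thicknesses are modelled as independent normal random variables
truncated to positive values by rejection resampling; permittivities are fixed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "MaterialSpec",
    "StackTemplate",
    "StackRealization",
    "default_registry",
    "cloth_material",
    "clothed_template",
    "bare_template",
    "sample_thickness",
    "sample_stack",
    "registry_to_yaml",
    "registry_from_yaml",
    "CLOTH_CODES",
    "SKIN_LAYERS",
]


@dataclass(frozen=True)
class MaterialSpec:
    """One physical medium: permittivity plus a thickness distribution.

    ``eps_imag`` is stored as a magnitude; the lossy sign convention
    (ε = ε′ − jε″ under e^{+jωt}) is applied by :attr:`epsilon`.
    """

    name: str
    eps_real: float
    eps_imag: float
    thickness_mean_mm: float = 0.0
    thickness_sd_mm: float = 0.0
    semi_infinite: bool = False

    def __post_init__(self) -> None:
        if self.eps_real < 1.0:
            raise ValueError(f"{self.name}: eps_real must be >= 1 for a passive medium")
        if self.eps_imag < 0.0:
            raise ValueError(f"{self.name}: eps_imag is a loss magnitude, must be >= 0")
        if self.thickness_sd_mm < 0.0:
            raise ValueError(f"{self.name}: thickness_sd_mm must be >= 0")
        if self.thickness_mean_mm < 0.0:
            raise ValueError(f"{self.name}: thickness_mean_mm must be >= 0")

    @property
    def epsilon(self) -> complex:
        """Complex relative permittivity ε′ − jε″."""
        return complex(self.eps_real, -self.eps_imag)


#: canonical order of the cloth materials
CLOTH_CODES = ("M1", "M2", "M3", "M4", "M5", "M6")

#: skin layers in anatomical order from the surface inward
SKIN_LAYERS = ("epidermis", "dermis", "fat", "muscle")

_CLOTH_NAMES = {
    "M1": "cotton_M1",
    "M2": "wool_M2",
    "M3": "linen_M3",
    "M4": "leatherette_M4",
    "M5": "polyester_M5",
    "M6": "latex_M6",
}


def default_registry() -> dict[str, MaterialSpec]:
    """Published 60 GHz material table plus a vacuum/air entry."""
    specs = [
        MaterialSpec("air", 1.0, 0.0, 0.0, 0.0, semi_infinite=True),
        MaterialSpec("cotton_M1", 2.0, 0.04, 0.2, 0.02),
        MaterialSpec("wool_M2", 1.22, 0.036, 2.0, 0.02),
        MaterialSpec("linen_M3", 1.25, 0.102, 0.98, 0.1),
        MaterialSpec("leatherette_M4", 2.16, 0.021, 0.91, 0.007),
        MaterialSpec("polyester_M5", 1.22, 0.003, 0.79, 0.194),
        MaterialSpec("latex_M6", 1.11, 0.009, 11.34, 0.241),
        MaterialSpec("epidermis", 8.5, 9.9, 0.0794, 0.0339),
        MaterialSpec("dermis", 10.4, 11.9, 1.25, 0.26),
        MaterialSpec("fat", 5.7, 4.7, 14.3, 7.5),
        # muscle terminates the stack; Table thickness kept for completeness
        MaterialSpec("muscle", 10.7, 13.9, 14.4, 3.5, semi_infinite=True),
    ]
    return {s.name: s for s in specs}


def cloth_material(code: str, registry: Mapping[str, MaterialSpec] | None = None) -> MaterialSpec:
    """Look up a cloth by short code ("M4") or full registry name."""
    reg = default_registry() if registry is None else registry
    if code in reg:
        return reg[code]
    if code in _CLOTH_NAMES and _CLOTH_NAMES[code] in reg:
        return reg[_CLOTH_NAMES[code]]
    # custom registries may use short codes directly
    for spec in reg.values():
        if spec.name.endswith(f"_{code}"):
            return spec
    raise KeyError(f"unknown cloth material {code!r}")


@dataclass(frozen=True)
class StackTemplate:
    """Ordered layer sequence from the incidence half-space to the termination.

    The air gap is a controlled scenario variable (never sampled); it is
    represented by an ``air_gap`` entry whose mean is ``air_gap_mm`` and whose
    SD is zero.
    """

    layers: tuple[MaterialSpec, ...]
    air_gap_mm: float
    clothed: bool
    skin_start: int  # layer index of the epidermis

    def __post_init__(self) -> None:
        if not self.layers[0].semi_infinite:
            raise ValueError("first layer must be the semi-infinite incidence medium")
        if not self.layers[-1].semi_infinite:
            raise ValueError("last layer must be a semi-infinite termination")
        if self.air_gap_mm < 0:
            raise ValueError("air_gap_mm must be >= 0")
        for spec in self.layers:
            if spec.thickness_sd_mm < 0:
                raise ValueError(f"{spec.name}: negative thickness SD")


def clothed_template(
    cloth: MaterialSpec | str,
    air_gap_mm: float,
    registry: Mapping[str, MaterialSpec] | None = None,
) -> StackTemplate:
    """air | cloth | air gap | epidermis | dermis | fat | muscle."""
    reg = default_registry() if registry is None else registry
    if isinstance(cloth, str):
        cloth = cloth_material(cloth, reg)
    gap = MaterialSpec("air_gap", 1.0, 0.0, float(air_gap_mm), 0.0)
    layers = (reg["air"], cloth, gap) + tuple(reg[n] for n in SKIN_LAYERS)
    return StackTemplate(layers, float(air_gap_mm), clothed=True, skin_start=3)


def bare_template(registry: Mapping[str, MaterialSpec] | None = None) -> StackTemplate:
    """air | epidermis | dermis | fat | muscle."""
    reg = default_registry() if registry is None else registry
    layers = (reg["air"],) + tuple(reg[n] for n in SKIN_LAYERS)
    return StackTemplate(layers, 0.0, clothed=False, skin_start=1)


@dataclass(frozen=True)
class StackRealization:
    """One concrete layer stack with sampled thicknesses.

    ``thickness_mm`` entries are ``None`` for the two semi-infinite half-spaces
    and otherwise floats or broadcast-compatible numpy arrays (vectorised
    Monte Carlo draws).
    """

    names: tuple[str, ...]
    epsilon: tuple[complex, ...]
    thickness_mm: tuple
    skin_interface: int  # layer index whose top is z3 (the skin surface)
    provenance: Mapping | None = None

    def __post_init__(self) -> None:
        n = len(self.names)
        if not (len(self.epsilon) == len(self.thickness_mm) == n):
            raise ValueError("names/epsilon/thickness length mismatch")
        if self.thickness_mm[0] is not None or self.thickness_mm[-1] is not None:
            raise ValueError("first and last layers must be semi-infinite (None thickness)")
        if not 1 <= self.skin_interface <= n - 1:
            raise ValueError("skin_interface out of range")

    @property
    def n_layers(self) -> int:
        return len(self.names)

    @property
    def z3_mm(self):
        """Depth of the skin surface below the first interface (z = 0)."""
        total = 0.0
        for t in self.thickness_mm[1 : self.skin_interface]:
            total = total + t
        return total

    @classmethod
    def from_layers(cls, entries: Sequence[tuple], skin_interface: int | None = None,
                    provenance: Mapping | None = None) -> "StackRealization":
        """Build from ``(name, epsilon, thickness_mm-or-None)`` triples."""
        names = tuple(e[0] for e in entries)
        eps = tuple(complex(e[1]) for e in entries)
        th = tuple(e[2] for e in entries)
        if skin_interface is None:
            skin_interface = len(entries) - 1
        return cls(names, eps, th, skin_interface, provenance)


def sample_thickness(spec: MaterialSpec, rng: np.random.Generator, size=None):
    """Draw Normal(mean, SD) thickness in mm, rejection-resampled until > 0.

    A zero SD returns the mean exactly (degenerate distribution; a zero mean
    such as a closed air gap is then legal).
    """
    if spec.thickness_sd_mm == 0.0:
        return spec.thickness_mean_mm if size is None else np.full(size, spec.thickness_mean_mm)
    if size is None:
        x = rng.normal(spec.thickness_mean_mm, spec.thickness_sd_mm)
        while x <= 0.0:
            x = rng.normal(spec.thickness_mean_mm, spec.thickness_sd_mm)
        return x
    x = rng.normal(spec.thickness_mean_mm, spec.thickness_sd_mm, size)
    bad = x <= 0.0
    while bad.any():
        x[bad] = rng.normal(spec.thickness_mean_mm, spec.thickness_sd_mm, int(bad.sum()))
        bad = x <= 0.0
    return x


def sample_stack(
    template: StackTemplate,
    rng: np.random.Generator,
    size=None,
    paired_bare: bool = False,
):
    """Sample one stack realization (or ``size`` vectorised draws).

    Layers are drawn independently in template order.  With ``paired_bare``
    a bare-skin realization sharing the identical skin-layer draws (common
    random numbers) is returned alongside the clothed one.
    """
    entries = []
    for spec in template.layers:
        if spec.semi_infinite:
            entries.append((spec.name, spec.epsilon, None))
        else:
            entries.append((spec.name, spec.epsilon, sample_thickness(spec, rng, size)))
    prov = {"template_clothed": template.clothed, "air_gap_mm": template.air_gap_mm}
    stack = StackRealization.from_layers(entries, template.skin_start, prov)
    if not paired_bare:
        return stack
    bare_entries = [entries[0]] + entries[template.skin_start:]
    bare = StackRealization.from_layers(bare_entries, 1, {"template_clothed": False})
    return stack, bare


# ---------------------------------------------------------------------------
# plain-text (YAML) registry serialization

def registry_to_yaml(registry: Mapping[str, MaterialSpec]) -> str:
    doc = {
        name: {
            "eps_real": spec.eps_real,
            "eps_imag": spec.eps_imag,
            "thickness_mean_mm": spec.thickness_mean_mm,
            "thickness_sd_mm": spec.thickness_sd_mm,
            "semi_infinite": spec.semi_infinite,
        }
        for name, spec in registry.items()
    }
    return yaml.safe_dump(doc, sort_keys=False)


def registry_from_yaml(text: str) -> dict[str, MaterialSpec]:
    doc = yaml.safe_load(text)
    out: dict[str, MaterialSpec] = {}
    for name, rec in doc.items():
        out[name] = MaterialSpec(
            name,
            float(rec["eps_real"]),
            float(rec["eps_imag"]),
            float(rec.get("thickness_mean_mm", 0.0)),
            float(rec.get("thickness_sd_mm", 0.0)),
            bool(rec.get("semi_infinite", False)),
        )
    return out
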