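"""Shared fixtures and helpers for the mmwdosim test suite."""
from __future__ import annotations

import numpy as np
import pytest

from mmwdosim import (
    PlaneWaveExcitation,
    StackRealization,
    default_registry,
)

#: skin-surface transmittance / APD of bare skin at mean thicknesses,
#: normal incidence, 60 GHz, IPD 26.6 W/m² — frozen from the independent
#: direct boundary-condition solve (mmwdosim.validation) before the solver
#: was built; regression anchors.
BARE_SKIN_T_NORMAL = 0.6074282134810755
BARE_SKIN_APD_NORMAL = 16.157590478596607


@pytest.fixture(scope="session")
def registry():
    return default_registry()


def mean_bare_stack(registry=None):
    """Bare skin with mean Table thicknesses."""
    reg = default_registry() if registry is None else registry
    return StackRealization.from_layers(
        [("air", 1 + 0j, None),
         ("epidermis", reg["epidermis"].epsilon, reg["epidermis"].thickness_mean_mm),
         ("dermis", reg["dermis"].epsilon, reg["dermis"].thickness_mean_mm),
         ("fat", reg["fat"].epsilon, reg["fat"].thickness_mean_mm),
         ("muscle", reg["muscle"].epsilon, None)],
        skin_interface=1,
    )


def mean_clothed_stack(code="M4", z_air_mm=1.0, cloth_mm=None, cloth_eps=None, registry=None):
    """Clothed stack with mean Table thicknesses (cloth overridable)."""
    from mmwdosim import cloth_material
    reg = default_registry() if registry is None else registry
    cloth = cloth_material(code, reg)
    eps = cloth.epsilon if cloth_eps is None else cloth_eps
    d = cloth.thickness_mean_mm if cloth_mm is None else cloth_mm
    return StackRealization.from_layers(
        [("air", 1 + 0j, None),
         (cloth.name, eps, d),
         ("air_gap", 1 + 0j, z_air_mm),
         ("epidermis", reg["epidermis"].epsilon, reg["epidermis"].thickness_mean_mm),
         ("dermis", reg["dermis"].epsilon, reg["dermis"].thickness_mean_mm),
         ("fat", reg["fat"].epsilon, reg["fat"].thickness_mean_mm),
         ("muscle", reg["muscle"].epsilon, None)],
        skin_interface=3,
    )


def random_lossy_stack(rng, n_inner=4, max_optical_mm=3.0):
    """Random passive multilayer for oracle cross-checks."""
    entries = [("in", 1 + 0j, None)]
    for i in range(n_inner):
        eps = complex(1.0 + 11.0 * rng.random(), -10.0 * rng.random())
        entries.append((f"layer{i}", eps, 0.02 + max_optical_mm * rng.random()))
    entries.append(("term", complex(1.0 + 11.0 * rng.random(), -10.0 * rng.random()), None))
    return StackRealization.from_layers(entries, skin_interface=n_inner + 1)


def excitations(theta_list=(0.0, 20.0, 45.0, 70.0), ipd=26.6):
    for th in theta_list:
        for pol in ("TE", "TM"):
            yield PlaneWaveExcitation(th, pol, incident_power_density=ipd)
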