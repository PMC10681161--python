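"""Isotropic linear-elastic material tables.

Units are the consistent mm/MPa/N set. Bulk soft tissue is E = 0.1 MPa,
nu = 0.45; hard tissue (skull base, LF1 segment, mandible) is E = 5 GPa,
nu = 0.2. In the homogeneous (H) model every muscle shares the bulk
soft-tissue properties; the sensitivity study instead varies the four
muscle stiffnesses over literature ranges (an order of magnitude softer
than the bulk value).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .regions import BONE_REGIONS, MUSCLE_PARAMETERS, MUSCLE_REGIONS, Region

SOFT_TISSUE_E = 0.1  # MPa
SOFT_TISSUE_NU = 0.45
BONE_E = 5000.0  # MPa (5 GPa)
BONE_NU = 0.2

#: Muscle stiffness ranges [MPa] explored by the design of experiments.
DOE_STIFFNESS_RANGES: dict[str, tuple[float, float]] = {
    "E_buccinator": (6.7e-3, 14.1e-3),
    "E_masseter": (6.7e-3, 14.1e-3),
    "E_orbicularis": (14.6e-3, 22.0e-3),
    "E_zygomaticus": (6.7e-3, 14.1e-3),
}


@dataclass(frozen=True)
class MaterialMap:
    """Region label -> (Young's modulus E [MPa], Poisson's ratio nu)."""

    table: dict[Region, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for region, (E, nu) in self.table.items():
            if not E > 0:
                raise ValueError(f"E must be > 0 for {Region(region).name}, got {E}")
            if not (-1.0 < nu < 0.5):
                raise ValueError(
                    f"nu must lie strictly in (-1, 0.5) for {Region(region).name}, got {nu}"
                )

    def __getitem__(self, region: Region) -> tuple[float, float]:
        return self.table[Region(region)]

    def __contains__(self, region: Region) -> bool:
        return Region(region) in self.table

    def with_muscles(self, stiffness: dict[str, float]) -> "MaterialMap":
        """Return a copy with paired muscle stiffnesses set from DoE parameters.

        ``stiffness`` maps parameter names (``E_masseter`` ...) to Young's
        moduli in MPa; left and right members of a pair receive the same
        value. Poisson's ratio stays at the soft-tissue 0.45.
        """
        table = dict(self.table)
        for name, value in stiffness.items():
            if name not in MUSCLE_PARAMETERS:
                raise KeyError(f"unknown muscle parameter {name!r}")
            for region in MUSCLE_PARAMETERS[name]:
                table[region] = (float(value), SOFT_TISSUE_NU)
        return MaterialMap(table)

    def to_yaml(self, path) -> None:
        data = {Region(r).name: {"E_MPa": E, "nu": nu} for r, (E, nu) in self.table.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "MaterialMap":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        table = {Region[name]: (float(v["E_MPa"]), float(v["nu"])) for name, v in data.items()}
        return cls(table)


def homogeneous_materials() -> MaterialMap:
    """The H model: all soft regions (muscles included) at E=0.1 MPa, nu=0.45."""
    table: dict[Region, tuple[float, float]] = {}
    for region in Region:
        if region in BONE_REGIONS:
            table[region] = (BONE_E, BONE_NU)
        else:
            table[region] = (SOFT_TISSUE_E, SOFT_TISSUE_NU)
    return MaterialMap(table)


def heterogeneous_materials(stiffness: dict[str, float] | None = None) -> MaterialMap:
    """Materials with muscle stiffnesses set per DoE parameter (default mid-range)."""
    if stiffness is None:
        stiffness = {k: 0.5 * (lo + hi) for k, (lo, hi) in DOE_STIFFNESS_RANGES.items()}
    return homogeneous_materials().with_muscles(stiffness)


def _all_muscle_regions_present(materials: MaterialMap) -> bool:
    return all(r in materials for r in MUSCLE_REGIONS)
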