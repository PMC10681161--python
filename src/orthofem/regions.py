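"""Anatomical region labels used on phantom and imported meshes.

The model distinguishes three rigid bone segments (the fixed skull base, the
mobilized LeFort I segment and the fixed mandible), a bulk soft-tissue
envelope (skin, mucosa, fat and minor mimic muscles lumped together) and
seven explicitly labeled muscle volumes: masseter, buccinator and
zygomaticus major in left/right pairs, plus the single midline orbicularis
oris.
"""

from __future__ import annotations

from enum import IntEnum


class Region(IntEnum):
    SKULL_BASE = 1
    LF1 = 2
    MANDIBLE = 3
    SOFT_TISSUE = 4
    MASSETER_L = 5
    MASSETER_R = 6
    BUCCINATOR_L = 7
    BUCCINATOR_R = 8
    ORBICULARIS_ORIS = 9
    ZYGOMATICUS_L = 10
    ZYGOMATICUS_R = 11


BONE_REGIONS = frozenset({Region.SKULL_BASE, Region.LF1, Region.MANDIBLE})

MUSCLE_REGIONS = frozenset(
    {
        Region.MASSETER_L,
        Region.MASSETER_R,
        Region.BUCCINATOR_L,
        Region.BUCCINATOR_R,
        Region.ORBICULARIS_ORIS,
        Region.ZYGOMATICUS_L,
        Region.ZYGOMATICUS_R,
    }
)

SOFT_REGIONS = frozenset({Region.SOFT_TISSUE}) | MUSCLE_REGIONS

#: DoE stiffness parameter -> muscle regions sharing that parameter.
#: Left/right members of a paired muscle share a single stiffness value.
MUSCLE_PARAMETERS: dict[str, tuple[Region, ...]] = {
    "E_masseter": (Region.MASSETER_L, Region.MASSETER_R),
    "E_buccinator": (Region.BUCCINATOR_L, Region.BUCCINATOR_R),
    "E_orbicularis": (Region.ORBICULARIS_ORIS,),
    "E_zygomaticus": (Region.ZYGOMATICUS_L, Region.ZYGOMATICUS_R),
}

LANDMARK_NAMES = ("N", "UL", "LC", "RC")
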