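"""Region dictionary for the four parietal subdivisions.

Codes follow the Hammers_mith numbering, in which odd codes designate the
right hemisphere throughout: 32/33 angular gyrus (AG), 60/61 postcentral
gyrus (postCG), 62/63 superior parietal lobe (supPL), 84/85 supramarginal
gyrus (SMG).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class RegionEntry:
    """One entry of the region dictionary."""

    code: int
    name: str
    side: str  # "L" or "R"

    def __post_init__(self) -> None:
        if self.side not in ("L", "R"):
            raise ValueError(f"side must be 'L' or 'R', got {self.side!r}")
        # odd codes are right-sided by convention
        expected = "R" if self.code % 2 else "L"
        if self.side != expected:
            raise ValueError(
                f"code {self.code} parity implies side {expected!r}, got {self.side!r}"
            )


#: The eight parietal regions (code -> entry).
PARIETAL_REGIONS: dict[int, RegionEntry] = {
    32: RegionEntry(32, "AG", "L"),
    33: RegionEntry(33, "AG", "R"),
    60: RegionEntry(60, "postCG", "L"),
    61: RegionEntry(61, "postCG", "R"),
    62: RegionEntry(62, "supPL", "L"),
    63: RegionEntry(63, "supPL", "R"),
    84: RegionEntry(84, "SMG", "L"),
    85: RegionEntry(85, "SMG", "R"),
}

#: Background code in label volumes.
BACKGROUND = 0


def codes_for_side(side: str) -> list[int]:
    """Return the four ipsilateral parietal region codes for one hemisphere."""
    if side not in ("L", "R"):
        raise ValueError(f"side must be 'L' or 'R', got {side!r}")
    return sorted(c for c, e in PARIETAL_REGIONS.items() if e.side == side)


def contralateral(code: int) -> int:
    """Return the homologous code in the opposite hemisphere."""
    if code not in PARIETAL_REGIONS:
        raise KeyError(f"unknown region code {code}")
    return code + 1 if code % 2 == 0 else code - 1
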