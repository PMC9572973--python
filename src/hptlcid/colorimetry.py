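"""RGB -> hue conversion and colour-family binning for HPTLC band colours.

Plate images yield band colours as RGB triples; a single hue angle H°
(in [0, 360)) is a more convenient descriptor for comparing bands, and
twelve contiguous 30° bins name the colour families (Red, Orange, ...).
Hue is computed from the chromatic plane only:

    H = atan2(sqrt(3) * (G - B), 2R - G - B)   (degrees, +360 if negative)

so it depends on channel differences alone; brightness and saturation are
discarded. Grey pixels (R = G = B) sit at the origin of that plane and
have no defined hue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import AchromaticColourError

__all__ = [
    "ColourFamily",
    "COLOUR_FAMILIES",
    "rgb_to_hue",
    "hue_family",
    "hue_distance",
]


@dataclass(frozen=True)
class ColourFamily:
    """One of the twelve 30°-wide hue bins, half-open [lower, upper)."""

    name: str
    abbreviation: str
    lower: float
    upper: float

    def __contains__(self, hue: float) -> bool:
        return self.lower <= hue < self.upper


_FAMILY_NAMES = [
    ("Red", "R"),
    ("Orange", "O"),
    ("Yellow", "Y"),
    ("YellowGreen", "YG"),
    ("Green", "G"),
    ("Turquoise", "T"),
    ("CyanBlue", "CB"),
    ("Blue", "B"),
    ("Violet", "V"),
    ("Purple", "P"),
    ("Magenta", "M"),
    ("Scarlet", "S"),
]

#: The twelve families tiling [0, 360) in contiguous 30° bins.
COLOUR_FAMILIES: tuple[ColourFamily, ...] = tuple(
    ColourFamily(name, abbr, 30.0 * i, 30.0 * (i + 1))
    for i, (name, abbr) in enumerate(_FAMILY_NAMES)
)


def _check_channel(value: int, name: str) -> None:
    if not (isinstance(value, (int,)) and 0 <= value <= 255):
        raise ValueError(f"{name} channel must be an integer in [0, 255], got {value!r}")


def rgb_to_hue(red: int, green: int, blue: int) -> float:
    """Convert an RGB triple to a hue angle in degrees, in [0, 360).

    Raises
    ------
    AchromaticColourError
        If R == G == B: a grey pixel has no hue. Returning 0 instead would
        spuriously match red-hued standards.
    """
    for value, name in ((red, "red"), (green, "green"), (blue, "blue")):
        _check_channel(value, name)
    if red == green == blue:
        raise AchromaticColourError(
            f"hue undefined for grey (R=G=B={red})"
        )
    hue = math.degrees(math.atan2(math.sqrt(3.0) * (green - blue), 2 * red - green - blue))
    if hue < 0:
        hue += 360.0
    return hue % 360.0


def hue_family(hue: float) -> ColourFamily:
    """Return the unique colour family whose bin contains ``hue``."""
    if not 0.0 <= hue < 360.0:
        raise ValueError(f"hue must lie in [0, 360), got {hue}")
    return COLOUR_FAMILIES[int(hue // 30.0)]


def hue_distance(a: float, b: float, wrap: bool = True) -> float:
    """Angular separation of two hues in degrees.

    With ``wrap`` (the default) the distance is measured around the colour
    circle, min(|a-b|, 360-|a-b|), and never exceeds 180; without it the
    plain absolute difference is returned (kept for sensitivity analysis).
    """
    for hue in (a, b):
        if not 0.0 <= hue < 360.0:
            raise ValueError(f"hue must lie in [0, 360), got {hue}")
    diff = abs(a - b)
    if wrap:
        return min(diff, 360.0 - diff)
    return diff
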