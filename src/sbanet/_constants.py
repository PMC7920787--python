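"""Closed vocabularies and small shared helpers."""

from __future__ import annotations

import math

REGIMES = ("R1", "R2")
HABITATS = ("BG", "DW", "GL", "SW", "MF")
ACTIVITIES = ("forage", "roost")
SHORT_BEHAVIORS = ("competition", "aggression", "courtship")
BEHAVIOR_CLASSES = ACTIVITIES + SHORT_BEHAVIORS
GUILDS = ("G1", "G2", "G3", "G4", "G5")

NODES_PER_SPECIES = len(BEHAVIOR_CLASSES)


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (0.05 -> 0.1, -0.05 -> -0.1).

    Python's built-in round uses banker's rounding; reported percentages
    and test statistics here follow the conventional half-away rule.
    """
    factor = 10.0**ndigits
    scaled = x * factor
    rounded = math.floor(abs(scaled) + 0.5)
    return math.copysign(rounded, scaled) / factor
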