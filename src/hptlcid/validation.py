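"""Recorded validation fixtures: the spiked artificial-honey control runs.

The screening method was validated by spiking known standards into
artificial honey and running the full cascade against each database view.
This module transcribes those recorded control runs so the package can
re-execute them: the query attributes of each test band, the candidate
roster that survived the Rf stage on that plate together with the
plate-specific Rf measurements, the stage-count bookkeeping of the fully
self-consistent run, the recorded consolidation sets for the negative
control, and the recorded overlay score pairs.

Plate-specific Rf values are query-side measurements: the canonical
library keeps its own Rf values, and a control run substitutes the values
measured on its plate via ``DatabaseView.subset(..., rf_overrides=...)``.

Test compound A (a hydroxybenzoic-acid derivative, syringic acid) and
test compound B (a flavonol, kaempferol) are positive controls present in
the library; test compound C (acetylsalicylic acid) is a negative control
absent from it.
"""

from __future__ import annotations

from types import MappingProxyType

from .cascade import BandObservation
from .library import StandardLibrary, DatabaseView, select_view

__all__ = [
    "TEST_A_1A_BAND", "TEST_A_1A_RUN_RF", "TEST_A_1A_STAGE_COUNTS",
    "TEST_A_1B_BAND", "TEST_A_1B_RUN_RF", "TEST_A_1B_FINAL_CODES",
    "CONSOLIDATION_C", "OVERLAY_SCORES_A", "OVERLAY_SCORES_B_MPA",
    "OVERLAY_SCORES_C_MPA",
    "control_view",
]

# ---------------------------------------------------------------- test A, 1A
#: Query band for test compound A on the MPA / NP-PEG plate.
TEST_A_1A_BAND = BandObservation(
    rf=0.608, hue_dev254=139.3, hue_dev366=180.0, hue_np366=209.2,
    fl_pre_max=225.0, fl_pre_min=258.0, uv_pre=(276.0,),
    fl_np_max=239.0, uv_np_max=288.0, label="1A",
)

#: The 42 standards surviving the Rf +/-0.05 stage on that plate, with the
#: plate's measured Rf per candidate.
TEST_A_1A_RUN_RF = MappingProxyType({
    36: 0.589, 43: 0.617, 48: 0.610, 58: 0.577, 67: 0.633, 103: 0.598,
    12: 0.651, 14: 0.654, 55: 0.577, 59: 0.623, 70: 0.646, 39: 0.594,
    45: 0.626, 50: 0.644, 52: 0.589, 54: 0.637, 56: 0.630, 61: 0.589,
    62: 0.609, 65: 0.616, 66: 0.600, 71: 0.630, 31: 0.600, 32: 0.637,
    74: 0.630, 79: 0.654, 82: 0.620, 84: 0.616, 87: 0.630, 98: 0.594,
    99: 0.637, 3: 0.649, 4: 0.617, 15: 0.587, 16: 0.617, 25: 0.591,
    37: 0.602, 72: 0.650, 73: 0.630, 94: 0.602, 7: 0.653, 8: 0.584,
})

#: Recorded survivor count after each of the ten 1A stages.
TEST_A_1A_STAGE_COUNTS = (42, 42, 40, 31, 31, 25, 11, 6, 5, 5)

#: Final potential matches: 2,3,4-THBA, eudesmic acid, methyl syringate,
#: syringic acid, m-coumaric acid.
TEST_A_1A_FINAL_CODES = frozenset({36, 43, 48, 58, 67})

# ---------------------------------------------------------------- test A, 1B
#: Query band for test compound A on the MPA / VSA plate.
TEST_A_1B_BAND = BandObservation(
    rf=0.580, hue_dev254=137.0, hue_dev366=180.0, hue_vsa366=204.0,
    hue_vsa_white=14.0, fl_pre_max=224.0, fl_pre_min=257.0, uv_pre=(277.0,),
    fl_vs_max=251.0, uv_vs_max=354.0, label="1B",
)

#: The 32 Rf-stage survivors on the 1B plate with their measured Rf.
TEST_A_1B_RUN_RF = MappingProxyType({
    48: 0.610, 58: 0.577, 36: 0.589, 43: 0.617, 4: 0.617, 10: 0.540,
    59: 0.623, 15: 0.587, 16: 0.617, 31: 0.600, 37: 0.602, 39: 0.594,
    45: 0.626, 52: 0.589, 55: 0.577, 56: 0.630, 61: 0.589, 65: 0.616,
    71: 0.630, 73: 0.630, 74: 0.630, 25: 0.591, 78: 0.545, 84: 0.616,
    87: 0.630, 98: 0.594, 62: 0.609, 66: 0.600, 77: 0.556, 82: 0.620,
    103: 0.598, 8: 0.584,
})

#: Final recorded 1B matches: methyl syringate and syringic acid.
TEST_A_1B_FINAL_CODES = frozenset({48, 58})

# ------------------------------------------------------- test C consolidation
#: Recorded per-view survivor code sets for the negative control, and the
#: recorded consolidated ("Match") sets per mobile phase.
CONSOLIDATION_C = MappingProxyType({
    "1A": frozenset({18, 20, 40, 43, 51, 53, 67, 79, 82, 85}),
    "1B": frozenset({18, 20, 25, 40, 51, 67, 85}),
    "match_MPA": frozenset({18, 20, 40, 51, 67, 85}),
    "2A": frozenset({43, 67, 82, 84, 85, 87}),
    "2B": frozenset({67, 85}),
    "match_MPB": frozenset({67, 85}),
})

# ------------------------------------------------------ recorded score pairs
#: Overlay scores (pearson r, percent-within) for test compound A against
#: its two consolidated candidates, methyl syringate (48) and syringic
#: acid (58), per spectrum kind.
OVERLAY_SCORES_A = MappingProxyType({
    "uv_pre": {48: (0.993, 95.5), 58: (0.994, 100.0)},
    "uv_np": {48: (0.939, 78.9), 58: (0.986, 100.0)},
    "uv_vs": {48: (0.669, 60.5), 58: (0.870, 84.3)},
})

#: Test compound B, MPA database pair: isorhamnetin (12) vs kaempferol (14).
OVERLAY_SCORES_B_MPA = MappingProxyType({
    "uv_pre": {12: (0.989, 82.9), 14: (0.996, 100.0)},
    "uv_np": {12: (0.941, 72.5), 14: (0.986, 100.0)},
    "uv_vs": {12: (0.986, 94.66), 14: (0.997, 100.0)},
})

#: Test compound C, MPA database pair: all six consolidated candidates
#: score poorly; the recorded verdict is "none".
OVERLAY_SCORES_C_MPA = MappingProxyType({
    "uv_pre": {18: (0.251, 5.5), 20: (0.229, 6.6), 40: (0.922, 41.8),
               51: (0.920, 42.9), 67: (0.814, 24.2), 85: (0.877, 45.1)},
    "uv_np": {18: (0.076, 31.0), 20: (0.281, 27.8), 40: (0.294, 18.3),
              51: (-0.09, 27.5), 67: (0.239, 27.0), 85: (-0.17, 20.6)},
    "uv_vs": {18: (0.275, 45.6), 20: (0.203, 35.9), 40: (-0.08, 59.1),
              51: (0.743, 82.6), 67: (-0.02, 20.3), 85: (0.494, 79.7)},
})

_RUN_RF = {"1A": TEST_A_1A_RUN_RF, "1B": TEST_A_1B_RUN_RF}


def control_view(library: StandardLibrary, label: str) -> DatabaseView:
    """The view a recorded test-compound-A control run screened against:
    the full view restricted to that plate's Rf-stage roster, with the
    plate's measured Rf values substituted."""
    run_rf = _RUN_RF[label]
    return select_view(library, label).subset(run_rf, rf_overrides=dict(run_rf))
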