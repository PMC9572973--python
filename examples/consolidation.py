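"""Consolidate candidate sets across reagents and mobile phases.

Within one mobile phase a compound must survive both derivatisation
views (NP-PEG and VSA) to count as a consolidated match — shown here
with the recorded negative-control sets, where ten and seven per-view
survivors reduce to six. Across mobile phases, compounds found in both
database sets are "double identified" (strong evidence); compounds found
in only one set are still reported, since a band that separates cleanly
in one solvent system may overlap with others in the second.
"""

from hptlcid import consolidate_pair, cross_solvent_report, load_reference_library
from hptlcid.validation import CONSOLIDATION_C

library = load_reference_library()


def names(codes):
    return ", ".join(f"({c}) {library[c].name}" for c in sorted(codes)) or "none"


match_mpa = consolidate_pair(CONSOLIDATION_C["1A"], CONSOLIDATION_C["1B"])
print(f"MPA: {len(CONSOLIDATION_C['1A'])} (NP-PEG view) and "
      f"{len(CONSOLIDATION_C['1B'])} (VSA view) survivors consolidate to "
      f"{len(match_mpa)}:")
print(" ", names(match_mpa))

match_mpb = consolidate_pair(CONSOLIDATION_C["2A"], CONSOLIDATION_C["2B"])
print(f"MPB: consolidated matches: {names(match_mpb)}")

report = cross_solvent_report(match_mpa, match_mpb)
print(f"double identified (both solvent systems): {names(report.double_identified)}")
print(f"single identified (one system only):      {names(report.single_identified)}")
print("\nNote: these candidates were all later rejected by overlay scoring "
      "- the band is a negative control absent from the library.")
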