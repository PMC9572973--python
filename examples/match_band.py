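"""Run the filter cascade for an unknown band (the recorded positive
control: syringic acid spiked into artificial honey).

The band's measured attributes — Rf 0.608, hues 139.3/180/209.2 deg,
fluorescence lambda-max/min 225/258 nm, one UV maximum at 276 nm, and
post-NP-PEG maxima 239/288 nm — are screened against the MPA/NP-PEG view.
Each stage keeps only candidates within its tolerance; the recorded counts
are the shrinking shortlist, and the final survivors are the "potential
matches" that overlay scoring would then confirm or reject.
"""

from hptlcid import load_reference_library, run_cascade
from hptlcid.validation import TEST_A_1A_BAND, control_view

library = load_reference_library()
trace = run_cascade(TEST_A_1A_BAND, control_view(library, "1A"))

print("stage              tolerance   surviving candidates")
for stage in trace.stages:
    tol = "-" if stage.threshold is None else f"+/-{stage.threshold:g}"
    print(f"{stage.name:<18} {tol:>9}   {stage.count}")

print("\npotential matches:")
for entry in trace.final_entries:
    print(f"  ({entry.code}) {entry.name} [{entry.compound_class}]")
print("\nFive structurally related phenolic acids survive; spectral "
      "overlays are needed to single out syringic acid.")
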