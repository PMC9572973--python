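"""Confirm a shortlisted candidate by spectral overlay scoring.

Two routes are shown. First, the recorded score pairs for the positive
control (methyl syringate vs syringic acid) are fed to the decision
engine: the pre-derivatisation UV spectra cannot separate the pair, the
NP-PEG overlay separates them by percent-within-band, and the VSA overlay
by correlation. Second, a fully synthetic end-to-end run: Gaussian
spectra are generated for both candidates, a noisy copy of syringic
acid's spectra plays the unknown, and the engine recovers it.
"""

from hptlcid import decide, decide_scores, load_reference_library, make_entry_spectra
from hptlcid.validation import OVERLAY_SCORES_A

# -- recorded score pairs -------------------------------------------------
for state in ("uv_pre", "uv_np", "uv_vs"):
    d = decide_scores({state: dict(OVERLAY_SCORES_A[state])})
    scores = ", ".join(f"candidate {c}: r={r:.3f}, {p:.1f}% in band"
                       for c, (r, p) in OVERLAY_SCORES_A[state].items())
    verdict = f"matched ({d.candidate})" if d.status == "matched" else d.status
    print(f"{state}: {scores} -> {verdict}")

full = decide_scores({k: dict(v) for k, v in OVERLAY_SCORES_A.items()})
print(f"full sequence decision: {full.status} -> candidate {full.candidate} "
      f"on {full.state} ({full.reason})")

# -- synthetic end-to-end --------------------------------------------------
library = load_reference_library()
candidates = {code: make_entry_spectra(library[code]) for code in (48, 58)}
unknown = make_entry_spectra(library[58], seed=11, noise_sd=0.01)
d = decide(unknown, candidates)
print(f"\nsynthetic unknown built from ({58}) {library[58].name}: "
      f"{d.status} -> candidate {d.candidate} ({d.reason})")
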