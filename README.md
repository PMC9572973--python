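# hptlcid — HPTLC-derived identification of phenolic compounds

`hptlcid` identifies phenolic compounds (and a few related markers) in
honey and similar complex natural-product matrices from high-performance
thin-layer chromatography (HPTLC) data. It is written for analytical
chemists who have an HPTLC workflow — plate development in one or two
mobile phases, imaging at 254/366 nm, derivatisation with NP-PEG
(natural-product reagent + polyethylene glycol) and/or VSA
(vanillin–sulfuric acid), and densitometric scanning — and want to match
unknown bands against a reference library instead of eyeballing Rf values
and colours.

The package ships a reference library of 107 standards, each profiled by:

* retention factors **Rf₁** (mobile phase MPA, toluene:ethyl
  acetate:formic acid 2:8:1) and **Rf₂** (MPB, 6:5:1);
* colour hue **H°** under five imaging conditions, computed from RGB as

  H° = atan2(√3·(G − B), 2R − G − B) · 180/π  (+360° if negative),

  binned into twelve 30° colour families (0–29.99° Red, 30–59.99° Orange, …);
* fluorescence λ_max / λ_min and 1–3 UV-Vis λ_max values before
  derivatisation, and the fluorescence/UV-Vis λ_max after each reagent.

## Method

**Cascade filtering.** An unknown band is screened against one of four
database views (1A = MPA/NP-PEG, 1B = MPA/VSA, 2A = MPB/NP-PEG,
2B = MPB/VSA) by an ordered sequence of boundary-inclusive tolerance
filters: Rf ± 0.05 → hues ± 60° (circular) → fluorescence λ_max and λ_min
± 15 nm → UV-Vis λ_max ± 15 nm and peak count → post-derivatisation
fluorescence ± 15 nm and UV-Vis ± 60 nm (wider, to absorb reagent-induced
bathochromic/hypsochromic shifts). Every stage is audited in a trace that
mirrors a manual "number of potential matches" tally.

**Overlay confirmation.** Surviving candidates are confirmed against
densitometer spectra. Both curves are clipped to a comparison window
(UV-Vis 250–500 nm pre-derivatisation and after NP-PEG, 230–600 nm after
VSA, fluorescence 210–270 nm), normalised to a windowed maximum of 1
(ABS_norm = ABS / ABS(λ_max)), and compared by Pearson correlation r and
by the percentage of the unknown's points lying within ± 0.125 AU of the
reference curve. A candidate wins only if it separates from the runner-up
by > 0.100 in r or > 10 percentage points in percent-within, consulting
UV-Vis pre → NP-PEG → VSA → fluorescence in order, and additionally
clears acceptance floors (default r ≥ 0.8, percent-within ≥ 50) — which
is what rejects compounds that are merely the least-bad candidates.

**Consolidation.** Within a mobile phase, matches must survive both
reagent views (set intersection); across mobile phases, compounds found
in both database sets are "double identified" while single-set finds are
still reported, since bands can overlap in one solvent system yet
separate in the other.

## Worked example

Screening the positive-control band (syringic acid spiked into artificial
honey; Rf 0.608, hues 139.3°/180°/209.2°, fluorescence 225/258 nm, one UV
maximum at 276 nm, post-NP-PEG 239/288 nm) against view 1A:

```
$ python examples/match_band.py
stage              tolerance   surviving candidates
rf                   +/-0.05   42
hue_dev254             +/-60   42
hue_dev366             +/-60   40
hue_np366              +/-60   31
fl_pre_max             +/-15   31
fl_pre_min             +/-15   25
uv_pre_lambda          +/-15   11
uv_pre_peakcount           -   6
fl_np_max              +/-15   5
uv_np_max              +/-60   5

potential matches:
  (36) 2,3,4-Trihydroxybenzoic Acid [HBAD]
  (43) Eudesmic Acid [HBAD]
  (48) Methyl Syringate [HBAD]
  (58) Syringic Acid [HBAD]
  (67) m-Coumaric Acid [HCAD]
```

42 candidates shrink to five structurally related phenolic acids. The
overlay engine then separates the final pair (`examples/overlay_decision.py`):
the pre-derivatisation UV spectra are inconclusive (r 0.993 vs 0.994),
but after NP-PEG derivatisation 100.0% of the unknown's points track
syringic acid against 78.9% for methyl syringate — a 21.1-point gap —
and the VSA overlay agrees (r 0.870 vs 0.669), so the band is matched to
syringic acid (58).

Other capabilities are demonstrated one per script in `examples/`
(library statistics, consolidation, synthetic positive controls), and the
same operations are scriptable from the shell via the `hptlc-id` CLI
(`summary`, `match`, `overlay`, `consolidate`, `synth`, `validate`).

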