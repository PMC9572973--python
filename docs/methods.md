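# Methods

This note documents the models, parameters, numerical choices and known
limitations of `hptlcid`. It is the package's own account of its science;
every number quoted here is computed by the test suite or the examples.

## The identification model

HPTLC produces, for each separated band, a small vector of cheap,
reproducible descriptors: a retention factor per mobile phase, a colour
hue per imaging condition, and wavelength summaries (λ_max, λ_min, peak
count) of fluorescence and UV-Vis scans before and after chemical
derivatisation. None of these descriptors is individually identifying —
hundreds of phenolics share an Rf within measurement error, and most
quench green at 254 nm — but their conjunction is highly selective. The
package therefore treats identification as *conjunctive interval
matching* against a curated library, followed by *curve-shape
confirmation* on the full spectra, followed by *consolidation* across
independent experimental conditions.

The model's central assumptions:

1. **Within-tolerance reproducibility.** Repeated measurements of the
   same compound fall within fixed, attribute-specific tolerances of the
   library value. Rf drifts run-to-run with humidity and plate batch
   (hence ± 0.05); hues drift with derivatiser timing (± 60°); λ values
   are stable to roughly ±2%, covered by ± 15 nm; post-derivatisation
   UV-Vis maxima can shift bathochromically/hypsochromically with pH and
   reagent kinetics, hence the wide ± 60 nm.
2. **Independence of filters.** Each filter is a predicate on one
   attribute; the final candidate set is their conjunction and is
   invariant to filter order (the per-stage counts are not). This is
   verified against a brute-force conjunction oracle.
3. **Shape, not amplitude.** Spectral confirmation compares normalised
   curves; application volume and band intensity carry no identification
   weight.

## Filter cascade

Stage order follows the bookkeeping of a manual database search: Rf,
hue at 254 nm, hue at 366 nm, post-derivatisation hue(s), fluorescence
λ_max then λ_min, UV-Vis maxima, UV-Vis peak count, post-derivatisation
fluorescence λ_max, post-derivatisation UV-Vis λ_max. NP-PEG views have
ten stages; VSA views eleven (366 nm plus white-light transmittance hue).

| parameter | default | unit | role |
|---|---|---|---|
| `rf_tol` | 0.05 | Rf | primary filter; absorbs run-to-run development drift |
| `hue_tol` | 60 | degrees | colour filters, circular by default |
| `lambda_tol` | 15 | nm | all pre-derivatisation λ filters and post-derivatisation fluorescence |
| `uv_post_tol` | 60 | nm | post-derivatisation UV-Vis λ_max |
| `wrap_hue` | true | — | measure hue gaps around the colour circle |

Design choices in the cascade:

* **Inclusive boundaries.** All tolerances use ≤. A candidate sitting at
  exactly 15 nm or exactly 60° survives; the validated control screens
  depend on this.
* **Circular hue distance.** Hue is an angle; 345° and 36° are 51° apart,
  not 309°. Library standards with scarlet/red white-light hues would
  otherwise be unmatchable by red-hued bands. A non-circular mode is kept
  as a switch for sensitivity analysis.
* **UV peak matching.** The maxima lists are compared positionally on
  ascending-sorted lists in two stages, matching the audit shape of a
  manual search: a λ stage comparing the shared positions within
  ± 15 nm, then a peak-count stage requiring equal length. Their
  conjunction is the contract `passes_uv_peaks`: equal count and every
  same-rank pair within tolerance, so a one-maximum band can never match
  a two- or three-maximum standard.
* **Missing values.** A query attribute that was not measured skips its
  stage (logged); a *library* attribute that does not exist (e.g. no
  post-VSA UV λ_max was recordable) fails the stage when the query
  supplies a value — a signature that could not be recorded cannot
  support a match.
* **Per-run Rf.** The library's Rf values are canonical; a matching run
  against a given plate may substitute that plate's measured Rf values as
  `rf_overrides` on the view. Overrides are query-side and never mutate
  the store.

## Spectral overlay

Spectra are clipped to a comparison window — UV-Vis 250–500 nm before
derivatisation and after NP-PEG, 230–600 nm after VSA (the reagent's
chromophores extend the informative region), fluorescence 210–270 nm —
then each is normalised by its own *windowed* maximum (the comparison is
windowed, so normalising by a global maximum outside the window would be
inconsistent), and the reference is linearly interpolated onto the
unknown's wavelength grid over their overlap; the unknown is never
resampled. Scores per candidate and spectrum kind:

* Pearson r of the paired normalised intensities (scale-invariant, so
  identical whether computed before or after per-spectrum normalisation);
* percent-within: the share of the unknown's grid points whose
  normalised intensity lies within ± 0.125 AU of the reference curve.
  The denominator is the unknown's points inside the window.

**Decision rules.** Spectrum kinds are consulted in a fixed sequence
(UV-Vis pre, NP-PEG, VSA; then the fluorescence spectra as an optional
fallback). At each kind, the leader must separate from the runner-up by
strictly more than 0.100 in correlation — consulted first — or, failing
that, strictly more than 10 percentage points in percent-within. A
separated winner must additionally clear absolute acceptance floors
(default r ≥ 0.8 and percent-within ≥ 50 on the decisive kind):
comparative gaps alone cannot reject a band whose best candidate is
merely the least bad, which is exactly the negative-control scenario the
floors handle. If the sequence is exhausted without separation the
engine returns the ambiguous set (restricted, when floors are set, to
candidates clearing them somewhere); if no candidate ever clears the
floors it returns no-match. Ties in a score are broken deterministically
by candidate key, making the decision invariant to candidate order.

The floors are deliberately configurable: they are a policy layer on top
of the comparative rules, chosen to pass clear positive controls while
rejecting high-r/low-coverage impostors, and real laboratory practice
also applies visual inspection that no scalar threshold fully captures.

## Synthetic data generator

Real densitometer exports cannot be redistributed, so the test suite and
examples synthesise their inputs:

* `make_spectrum` evaluates a sum of Gaussian peaks (centre, height,
  sigma) on a regular grid with optional seeded Gaussian noise. Gaussian
  shape is the simplest smooth unimodal stand-in for an absorbance band;
  the scoring contracts under test (normalisation, interpolation,
  correlation, banded coverage) are shape-agnostic.
* `jitter_band` derives a query band from a library standard by
  perturbing each attribute uniformly within ± fraction × tolerance —
  the synthetic analogue of spiking a known standard into artificial
  honey. For fraction < 1 recovery is guaranteed by construction
  (inclusive boundaries); the suite uses fraction 0.49 across 20 seeds
  and all four views. The default study conditions mirror the validated
  screens: tolerances as above, noise σ of 0.01–0.02 AU on unit-height
  synthetic spectra.

What passing these tests shows — and does not show. They demonstrate the
*machinery* is correct: filters honour their tolerances, scores equal a
direct-summation re-computation, decisions follow the stated rules, and
the recorded control screens are reproduced exactly. They do not
demonstrate chemical validity on real honey extracts: synthetic Gaussians
lack baselines, solvent artefacts, overlapping bands and detector
saturation, and the library's discriminating power on a new matrix
depends on which compounds that matrix actually contains.

## Numerical choices

* **Boundary guard.** Recorded data are decimal; binary floats are not.
  |0.580 − 0.630| evaluates to 0.0500…044, which would break the
  inclusive ± 0.05 boundary, so all interval and hue comparisons allow a
  1 × 10⁻⁹ absolute guard — far below the precision of any measured
  attribute.
* **Zero placeholders.** Data tables print "0" for an absent second or
  third UV maximum; the store records absence, never 0 nm.
* **Hue 0° is a value.** Red bands legitimately measure 0°; only R=G=B
  pixels are hue-less, and those raise a typed error rather than
  returning 0 (which would spuriously match red standards).
* **Degenerate spectra.** Constant curves have undefined correlation and
  raise; all-zero curves cannot be normalised and raise.
* **Interpolation.** Linear, reference-onto-unknown; requires ≥ 2 of the
  unknown's samples in the overlap and ≥ 2 samples in any window.

## Known limitations

* The cascade intermediate counts of one recorded VSA control table are
  internally inconsistent with its own listed rows; the package
  reproduces the self-consistent NP-PEG control table stage-by-stage and
  the VSA screen at its final candidate set.
* The reference verdicts for real Manuka honey bands cannot be
  recomputed from the summary data alone (the raw scanner spectra are
  unavailable, and those verdicts mixed quantitative rules with visual
  inspection); the package reports scores and applies its configurable
  rules instead of claiming to reproduce them.
* No peak picking, baseline correction, smoothing or plate-image
  processing: inputs are already-reduced band attributes and two-column
  spectrum exports.
* Identification is qualitative; no quantification or detection limits.
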