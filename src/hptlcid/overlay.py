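"""Spectral overlay scoring and match-decision rules.

Shortlisted candidates from the filter cascade are confirmed or rejected
by overlaying densitometer spectra of the unknown band on the reference
spectra of each candidate. Both spectra are clipped to a comparison
window, normalised so the windowed maximum equals 1, and paired on the
unknown's wavelength grid (the reference is linearly interpolated).
Two scores are computed per candidate and spectrum:

* Pearson correlation r of the paired normalised intensities;
* percent-within: the share of the unknown's points whose normalised
  intensity lies within ±0.125 AU of the reference curve.

The decision engine walks a fixed sequence of spectrum kinds (UV-Vis
before derivatisation, after NP-PEG, after VSA, then the fluorescence
spectra as an optional fallback). At each step the top candidate is
accepted only if it separates from the runner-up by more than 0.100 in
correlation or, failing that, by more than 10 percentage points in
percent-within; otherwise the next spectrum kind is consulted. A winner
must additionally clear configurable absolute floors (default r >= 0.8
and percent-within >= 50) — weak best-in-class scores are rejected rather
than matched, which is what keeps compounds absent from the library from
producing false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import SpectrumError, WindowError

__all__ = [
    "Spectrum",
    "ComparisonWindow",
    "OverlayResult",
    "DecisionConfig",
    "Decision",
    "DEFAULT_WINDOWS",
    "DEFAULT_SEQUENCE",
    "read_spectrum",
    "write_spectrum",
    "clip",
    "normalise",
    "align",
    "score_overlay",
    "decide",
    "decide_scores",
]

MODALITIES = ("uv-vis", "fluorescence")
STATES = ("pre", "np-peg", "vsa")

#: Spectrum kinds in the order the decision engine consults them.
#: Fluorescence overlays are a fallback, consulted only when the three
#: UV-Vis spectra fail to separate the candidates.
DEFAULT_SEQUENCE: tuple[str, ...] = (
    "uv_pre", "uv_np", "uv_vs", "fl_pre", "fl_np", "fl_vs",
)

_KEYS = {
    ("uv-vis", "pre"): "uv_pre",
    ("uv-vis", "np-peg"): "uv_np",
    ("uv-vis", "vsa"): "uv_vs",
    ("fluorescence", "pre"): "fl_pre",
    ("fluorescence", "np-peg"): "fl_np",
    ("fluorescence", "vsa"): "fl_vs",
}


@dataclass(frozen=True)
class ComparisonWindow:
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise WindowError(f"window low {self.low} must be < high {self.high}")


#: Default comparison windows per spectrum kind (nm). Mobile-phase solvents
#: absorb below 250 nm, hence the clipped UV windows; the VSA chromophores
#: extend the usable region to 600 nm. Fluorescence emission was recorded
#: at 190-270 nm, of which 210-270 nm is the informative region.
DEFAULT_WINDOWS: Mapping[str, ComparisonWindow] = {
    "uv_pre": ComparisonWindow(250.0, 500.0),
    "uv_np": ComparisonWindow(250.0, 500.0),
    "uv_vs": ComparisonWindow(230.0, 600.0),
    "fl_pre": ComparisonWindow(210.0, 270.0),
    "fl_np": ComparisonWindow(210.0, 270.0),
    "fl_vs": ComparisonWindow(210.0, 270.0),
}


@dataclass(frozen=True)
class Spectrum:
    """A sampled wavelength/intensity curve.

    ``modality`` is "uv-vis" or "fluorescence"; ``state`` is "pre",
    "np-peg" or "vsa" (derivatisation state). Wavelengths must be strictly
    increasing with at least two finite samples.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    modality: str = "uv-vis"
    state: str = "pre"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", ab)
        if wl.ndim != 1 or ab.shape != wl.shape:
            raise SpectrumError("wavelengths and intensities must be equal-length 1-D")
        if wl.size < 2:
            raise SpectrumError("a spectrum needs at least 2 samples")
        if not np.all(np.diff(wl) > 0):
            raise SpectrumError("wavelengths must be strictly increasing")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(ab))):
            raise SpectrumError("spectrum contains non-finite values")
        if self.modality not in MODALITIES:
            raise SpectrumError(f"modality must be one of {MODALITIES}")
        if self.state not in STATES:
            raise SpectrumError(f"state must be one of {STATES}")

    @property
    def key(self) -> str:
        """Short kind key, e.g. 'uv_np', used for windows and sequencing."""
        return _KEYS[(self.modality, self.state)]

    def __len__(self) -> int:
        return int(self.wavelengths.size)


def read_spectrum(source, modality: str = "uv-vis", state: str = "pre") -> Spectrum:
    """Read a two-column delimited spectrum file (wavelength nm, AU).

    Accepts comma-, tab- or whitespace-separated columns and tolerates a
    single non-numeric header line. Duplicate wavelengths are rejected;
    samples are sorted by wavelength.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source, "r", encoding="utf-8") as handle:
            lines = handle.read().splitlines()
    pairs: list[tuple[float, float]] = []
    for lineno, line in enumerate(lines, start=1):
        text = line.strip()
        if not text:
            continue
        tokens = [t for t in text.replace(",", " ").replace("\t", " ").split() if t]
        try:
            values = [float(t) for t in tokens]
        except ValueError:
            if lineno == 1 and not pairs:
                continue  # header line
            raise SpectrumError(f"line {lineno}: non-numeric row {line!r}")
        if len(values) != 2:
            raise SpectrumError(f"line {lineno}: expected 2 columns, got {len(values)}")
        pairs.append((values[0], values[1]))
    if len(pairs) < 2:
        raise SpectrumError("spectrum file must contain at least 2 data rows")
    pairs.sort(key=lambda p: p[0])
    wl = np.array([p[0] for p in pairs])
    if np.any(np.diff(wl) == 0):
        dup = wl[np.where(np.diff(wl) == 0)[0][0]]
        raise SpectrumError(f"duplicate wavelength {dup:g} nm")
    ab = np.array([p[1] for p in pairs])
    return Spectrum(wl, ab, modality=modality, state=state)


def write_spectrum(spectrum: Spectrum, path: str | PathLike,
                   delimiter: str = ",") -> None:
    """Write a spectrum as a two-column delimited file (round-trips with
    :func:`read_spectrum`)."""
    with open(path, "w", encoding="utf-8") as handle:
        for wl, ab in zip(spectrum.wavelengths, spectrum.intensities):
            handle.write(f"{float(wl)!r}{delimiter}{float(ab)!r}\n")


def clip(spectrum: Spectrum, window: ComparisonWindow) -> Spectrum:
    """Restrict a spectrum to wavelengths in [low, high], inclusive."""
    mask = (spectrum.wavelengths >= window.low) & (spectrum.wavelengths <= window.high)
    if int(mask.sum()) < 2:
        raise WindowError(
            f"window [{window.low}, {window.high}] overlaps the sampled range "
            f"[{spectrum.wavelengths[0]:g}, {spectrum.wavelengths[-1]:g}] in "
            f"{int(mask.sum())} samples (need >= 2)")
    return Spectrum(spectrum.wavelengths[mask], spectrum.intensities[mask],
                    modality=spectrum.modality, state=spectrum.state)


def normalise(spectrum: Spectrum) -> Spectrum:
    """Scale intensities so the maximum becomes exactly 1 (idempotent)."""
    peak = float(np.max(spectrum.intensities))
    if peak <= 0.0:
        raise SpectrumError("cannot normalise: maximum intensity is not positive")
    return Spectrum(spectrum.wavelengths, spectrum.intensities / peak,
                    modality=spectrum.modality, state=spectrum.state)


def align(unknown: Spectrum, standard: Spectrum) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pair the two spectra on the unknown's grid over their overlap.

    Returns (wavelengths, unknown intensities, interpolated standard
    intensities). The standard is linearly interpolated; the unknown is
    never resampled.
    """
    low = max(unknown.wavelengths[0], standard.wavelengths[0])
    high = min(unknown.wavelengths[-1], standard.wavelengths[-1])
    mask = (unknown.wavelengths >= low) & (unknown.wavelengths <= high)
    if int(mask.sum()) < 2:
        raise WindowError("spectra overlap in fewer than 2 of the unknown's samples")
    grid = unknown.wavelengths[mask]
    return (grid, unknown.intensities[mask],
            np.interp(grid, standard.wavelengths, standard.intensities))


@dataclass(frozen=True)
class OverlayResult:
    """Scores for one candidate spectrum against the unknown band."""

    candidate: int | str | None
    state: str
    pearson_r: float
    percent_within: float
    n_points: int
    window: ComparisonWindow


def score_overlay(unknown: Spectrum, standard: Spectrum,
                  window: ComparisonWindow | None = None,
                  band: float = 0.125,
                  candidate: int | str | None = None) -> OverlayResult:
    """Score one unknown/reference pair inside a comparison window.

    Each spectrum is normalised to its own windowed maximum before
    pairing, so the scores compare curve shape, not amplitude.
    """
    if window is None:
        window = DEFAULT_WINDOWS[unknown.key]
    u = normalise(clip(unknown, window))
    s = normalise(clip(standard, window))
    _, u_vals, s_vals = align(u, s)
    if np.ptp(u_vals) == 0.0 or np.ptp(s_vals) == 0.0:
        raise SpectrumError("correlation undefined for a constant spectrum")
    r = float(stats.pearsonr(u_vals, s_vals).statistic)
    within = float(np.mean(np.abs(u_vals - s_vals) <= band) * 100.0)
    return OverlayResult(candidate=candidate, state=unknown.key, pearson_r=r,
                         percent_within=within, n_points=int(u_vals.size),
                         window=window)


@dataclass(frozen=True)
class DecisionConfig:
    """Decision-rule settings: the ±0.125 AU band, the comparative gaps
    (correlation 0.100, percent-within 10 points, both strict), the
    spectrum-kind sequence, and optional absolute floors for a winner."""

    band: float = 0.125
    corr_diff: float = 0.100
    pct_diff: float = 10.0
    sequence: tuple[str, ...] = DEFAULT_SEQUENCE
    floors: tuple[float, float] | None = (0.8, 50.0)

    def __post_init__(self) -> None:
        if self.band <= 0:
            raise ValueError("band must be > 0")
        if self.corr_diff < 0 or self.pct_diff < 0:
            raise ValueError("decision gaps must be >= 0")


@dataclass(frozen=True)
class Decision:
    """Outcome of the decision engine.

    ``status`` is "matched", "ambiguous" or "no_match"; ``state`` names
    the spectrum kind that settled a match (None otherwise)."""

    status: str
    candidate: int | str | None = None
    candidates: tuple = ()
    state: str | None = None
    reason: str = ""
    scores: Mapping[str, Mapping] = field(default_factory=dict)


def _meets_floors(score: tuple[float, float], floors: tuple[float, float] | None) -> bool:
    if floors is None:
        return True
    return score[0] >= floors[0] and score[1] >= floors[1]


def decide_scores(scores_by_state: Mapping[str, Mapping[object, tuple[float, float]]],
                  config: DecisionConfig | None = None) -> Decision:
    """Apply the decision rules to precomputed (r, percent-within) scores.

    ``scores_by_state`` maps a spectrum kind (e.g. "uv_np") to a mapping
    of candidate -> (pearson_r, percent_within). States are consulted in
    ``config.sequence`` order; unknown states are ignored.
    """
    config = config or DecisionConfig()
    available = [s for s in config.sequence if scores_by_state.get(s)]
    if not available:
        raise SpectrumError("no spectra scores available for any state in the sequence")

    def finish(winner, state, reason) -> Decision:
        if _meets_floors(scores_by_state[state][winner], config.floors):
            return Decision(status="matched", candidate=winner, state=state,
                            reason=reason, scores=scores_by_state)
        return Decision(
            status="no_match", state=state, scores=scores_by_state,
            reason=f"{reason}, but best candidate fails acceptance floors "
                   f"{config.floors}")

    for state in available:
        scores = scores_by_state[state]
        # deterministic tie-break by repr(candidate) => permutation-invariant
        by_r = sorted(scores, key=lambda c: (-scores[c][0], repr(c)))
        if len(by_r) == 1:
            return finish(by_r[0], state, "single candidate")
        gap_r = scores[by_r[0]][0] - scores[by_r[1]][0]
        if gap_r > config.corr_diff:
            return finish(by_r[0], state,
                          f"correlation gap {gap_r:.3f} > {config.corr_diff}")
        by_p = sorted(scores, key=lambda c: (-scores[c][1], repr(c)))
        gap_p = scores[by_p[0]][1] - scores[by_p[1]][1]
        if gap_p > config.pct_diff:
            return finish(by_p[0], state,
                          f"percent-within gap {gap_p:.1f} > {config.pct_diff}")

    candidates = sorted({c for s in available for c in scores_by_state[s]}, key=repr)
    if config.floors is not None:
        candidates = [c for c in candidates
                      if any(_meets_floors(scores_by_state[s][c], config.floors)
                             for s in available if c in scores_by_state[s])]
    if not candidates:
        return Decision(status="no_match", scores=scores_by_state,
                        reason="no candidate meets the acceptance floors in any state")
    if len(candidates) == 1:
        return Decision(status="matched", candidate=candidates[0],
                        reason="only candidate meeting the acceptance floors",
                        scores=scores_by_state)
    return Decision(status="ambiguous", candidates=tuple(candidates),
                    reason="no state separates the leading candidates",
                    scores=scores_by_state)


def decide(unknown_spectra: Mapping[str, Spectrum],
           candidate_spectra: Mapping[object, Mapping[str, Spectrum]],
           config: DecisionConfig | None = None,
           windows: Mapping[str, ComparisonWindow] | None = None) -> Decision:
    """Score every candidate against the unknown and decide.

    ``unknown_spectra`` and each candidate's spectra are keyed by spectrum
    kind ("uv_pre", "uv_np", ...). Only kinds present for both the unknown
    and a candidate are scored.
    """
    config = config or DecisionConfig()
    windows = windows or DEFAULT_WINDOWS
    if not candidate_spectra:
        raise ValueError("need at least one candidate")
    scores_by_state: dict[str, dict[object, tuple[float, float]]] = {}
    for state in config.sequence:
        if state not in unknown_spectra:
            continue
        for code, spectra in candidate_spectra.items():
            if state not in spectra:
                continue
            result = score_overlay(unknown_spectra[state], spectra[state],
                                   window=windows.get(state), band=config.band,
                                   candidate=code)
            scores_by_state.setdefault(state, {})[code] = (
                result.pearson_r, result.percent_within)
    return decide_scores(scores_by_state, config)
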