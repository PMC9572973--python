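"""Reference library of HPTLC standard-compound signatures.

Each of the 107 packaged standards carries the full chromatographic and
spectral signature recorded on silica HPTLC plates: retention factors in
two mobile phases (MPA = toluene:ethyl acetate:formic acid 2:8:1, MPB =
6:5:1), hue angles under five imaging conditions (254 nm and 366 nm after
development; 366 nm after NP-PEG derivatisation; 366 nm and white-light
transmittance after vanillin-sulfuric-acid derivatisation), fluorescence
lambda-max/lambda-min and 1-3 UV-Vis lambda-max values before
derivatisation, and the post-derivatisation lambda maxima for each reagent.

Four database views pair a mobile phase with a derivatisation reagent:

    1A = (MPA, NP-PEG)   1B = (MPA, VSA)
    2A = (MPB, NP-PEG)   2B = (MPB, VSA)

Views project the attribute slots relevant to their reagent; they never
drop entries. The on-disk format is a flat, diffable TSV with pipe-
separated UV peak lists; a "0" in a UV column is a recorded placeholder for
an absent peak and is never stored as a wavelength.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from importlib import resources
from os import PathLike
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .errors import LibraryValidationError, SchemaError

__all__ = [
    "StandardEntry",
    "StandardLibrary",
    "DatabaseView",
    "LibrarySummary",
    "VIEW_LABELS",
    "load_library",
    "load_reference_library",
    "write_library",
    "select_view",
    "summarise",
]

MOBILE_PHASES = ("MPA", "MPB")
HUE_CONDITIONS = ("dev254", "dev366", "np366", "vsa366", "vsa_white")
VIEW_LABELS: Mapping[str, tuple[str, str]] = {
    "1A": ("MPA", "NP-PEG"),
    "1B": ("MPA", "VSA"),
    "2A": ("MPB", "NP-PEG"),
    "2B": ("MPB", "VSA"),
}

LAMBDA_RANGE = (190.0, 900.0)

_COLUMNS = [
    "code", "name", "abbreviation", "compound_class",
    "rf_mpa", "rf_mpb",
    "hue_dev254", "hue_dev366", "hue_np366", "hue_vsa366", "hue_vsa_white",
    "fl_pre_max", "fl_pre_min", "uv_pre", "fl_np_max", "uv_np",
    "fl_vs_max", "uv_vs_max",
]


def _check_lambda(value: float, where: str) -> float:
    if not (LAMBDA_RANGE[0] <= value <= LAMBDA_RANGE[1]):
        raise LibraryValidationError(
            f"{where}: wavelength {value} nm outside [{LAMBDA_RANGE[0]}, {LAMBDA_RANGE[1]}]"
        )
    return float(value)


@dataclass(frozen=True)
class StandardEntry:
    """Full signature of one reference compound.

    ``uv_pre`` and ``uv_np`` hold 1-3 ascending lambda-max values;
    ``uv_vs_max`` may be absent. ``fl_pre_min`` routinely exceeds
    ``fl_pre_max`` numerically (the spectrum minimum sits at a longer
    wavelength than the maximum); both are simply stored.
    """

    code: int
    name: str
    abbreviation: str
    compound_class: str
    rf: Mapping[str, float]
    hue: Mapping[str, float]
    fl_pre_max: float
    fl_pre_min: float
    uv_pre: tuple[float, ...]
    fl_np_max: float
    uv_np: tuple[float, ...]
    fl_vs_max: float | None = None
    uv_vs_max: float | None = None

    def __post_init__(self) -> None:
        where = f"standard {self.code} ({self.abbreviation})"
        if self.code < 1:
            raise LibraryValidationError(f"{where}: code must be positive")
        for phase in MOBILE_PHASES:
            if phase not in self.rf:
                raise LibraryValidationError(f"{where}: missing Rf for {phase}")
            value = self.rf[phase]
            if not 0.0 <= value <= 1.0:
                raise LibraryValidationError(f"{where}: Rf {value} outside [0, 1]")
        for cond in HUE_CONDITIONS:
            if cond not in self.hue:
                raise LibraryValidationError(f"{where}: missing hue for {cond}")
            value = self.hue[cond]
            if not 0.0 <= value < 360.0:
                raise LibraryValidationError(f"{where}: hue {value} outside [0, 360)")
        for name in ("fl_pre_max", "fl_pre_min", "fl_np_max"):
            _check_lambda(getattr(self, name), f"{where}.{name}")
        for name in ("uv_pre", "uv_np"):
            peaks = getattr(self, name)
            if not 1 <= len(peaks) <= 3:
                raise LibraryValidationError(f"{where}.{name}: need 1-3 peaks, got {len(peaks)}")
            if any(b < a for a, b in zip(peaks, peaks[1:])):
                raise LibraryValidationError(f"{where}.{name}: peaks not ascending: {peaks}")
            for value in peaks:
                _check_lambda(value, f"{where}.{name}")
        for name in ("fl_vs_max", "uv_vs_max"):
            value = getattr(self, name)
            if value is not None:
                _check_lambda(value, f"{where}.{name}")


class StandardLibrary:
    """An ordered, code-indexed collection of :class:`StandardEntry`."""

    def __init__(self, entries: Iterable[StandardEntry]):
        self._entries = tuple(entries)
        self._by_code: dict[int, StandardEntry] = {}
        for entry in self._entries:
            if entry.code in self._by_code:
                raise LibraryValidationError(f"duplicate standard code {entry.code}")
            self._by_code[entry.code] = entry
        codes = sorted(self._by_code)
        if codes and codes != list(range(codes[0], codes[0] + len(codes))):
            raise LibraryValidationError("standard codes are not contiguous")

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[StandardEntry]:
        return iter(self._entries)

    def __getitem__(self, code: int) -> StandardEntry:
        return self._by_code[code]

    def __contains__(self, code: int) -> bool:
        return code in self._by_code

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StandardLibrary):
            return NotImplemented
        return self._entries == other._entries

    @property
    def entries(self) -> tuple[StandardEntry, ...]:
        return self._entries

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(e.code for e in self._entries)


@dataclass(frozen=True)
class DatabaseView:
    """Projection of the library onto one (mobile phase, reagent) pair.

    ``rf_overrides`` substitutes per-run measured Rf values for the stored
    canonical ones; the stored library is never mutated. Plate-to-plate Rf
    drift is a fact of thin-layer chromatography, so a matching run against
    a freshly developed plate uses that plate's Rf measurements.
    """

    label: str
    mobile_phase: str
    derivatisation: str
    entries: tuple[StandardEntry, ...]
    rf_overrides: Mapping[int, float] = field(default_factory=dict)

    def rf_of(self, entry: StandardEntry) -> float:
        if entry.code in self.rf_overrides:
            return self.rf_overrides[entry.code]
        return entry.rf[self.mobile_phase]

    def value(self, entry: StandardEntry, attribute: str):
        """Resolve a stage attribute to this view's concrete entry value.

        Returns ``None`` when the entry has no value for the attribute.
        """
        if attribute == "rf":
            return self.rf_of(entry)
        if attribute.startswith("hue_"):
            return entry.hue[attribute[len("hue_"):]]
        if attribute in ("fl_pre_max", "fl_pre_min", "fl_np_max", "fl_vs_max"):
            return getattr(entry, attribute)
        if attribute in ("uv_pre_lambda", "uv_pre_peakcount"):
            return entry.uv_pre
        if attribute == "uv_np_max":
            return entry.uv_np[0]
        if attribute == "uv_vs_max":
            return entry.uv_vs_max
        raise KeyError(f"unknown view attribute {attribute!r}")

    def subset(self, codes: Iterable[int],
               rf_overrides: Mapping[int, float] | None = None) -> "DatabaseView":
        """Restrict the view to ``codes``, optionally with per-run Rf values."""
        wanted = set(codes)
        missing = wanted - {e.code for e in self.entries}
        if missing:
            raise KeyError(f"codes not in view: {sorted(missing)}")
        merged = dict(self.rf_overrides)
        if rf_overrides:
            merged.update(rf_overrides)
        return DatabaseView(
            label=self.label,
            mobile_phase=self.mobile_phase,
            derivatisation=self.derivatisation,
            entries=tuple(e for e in self.entries if e.code in wanted),
            rf_overrides=merged,
        )


@dataclass(frozen=True)
class LibrarySummary:
    """Descriptive statistics over a library."""

    n_entries: int
    rf_range: Mapping[str, tuple[float, float]]
    uv_peak_histogram: Mapping[int, int]
    hue_range: Mapping[str, tuple[float, float]]
    n_hue254_above_150: int


def _parse_peaks(cell: str, where: str) -> tuple[float, ...]:
    peaks = []
    for token in cell.split("|"):
        token = token.strip()
        if not token:
            continue
        try:
            value = float(token)
        except ValueError as exc:
            raise LibraryValidationError(f"{where}: non-numeric peak {token!r}") from exc
        if value == 0.0:  # recorded placeholder for an absent peak
            continue
        peaks.append(value)
    return tuple(sorted(peaks))


def _parse_scalar(cell, where: str) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    text = str(cell).strip()
    if not text:
        return None
    try:
        value = float(text)
    except ValueError as exc:
        raise LibraryValidationError(f"{where}: non-numeric value {text!r}") from exc
    if value == 0.0 and where.endswith(("uv_vs_max",)):
        return None
    return value


def load_library(source) -> StandardLibrary:
    """Load a library from a TSV path, file object, or string buffer."""
    frame = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"library file missing columns: {missing}")
    entries = []
    for idx, row in frame.iterrows():
        where = f"row {idx + 2}"  # 1-based, after header
        try:
            code = int(row["code"])
        except ValueError as exc:
            raise LibraryValidationError(f"{where}: bad code {row['code']!r}") from exc

        def need(column: str) -> float:
            value = _parse_scalar(row[column], f"{where}.{column}")
            if value is None:
                raise LibraryValidationError(f"{where}: missing required {column}")
            return value

        entries.append(StandardEntry(
            code=code,
            name=row["name"].strip(),
            abbreviation=row["abbreviation"].strip(),
            compound_class=row["compound_class"].strip(),
            rf={"MPA": need("rf_mpa"), "MPB": need("rf_mpb")},
            hue={cond: need(f"hue_{cond}") for cond in HUE_CONDITIONS},
            fl_pre_max=need("fl_pre_max"),
            fl_pre_min=need("fl_pre_min"),
            uv_pre=_parse_peaks(row["uv_pre"], f"{where}.uv_pre"),
            fl_np_max=need("fl_np_max"),
            uv_np=_parse_peaks(row["uv_np"], f"{where}.uv_np"),
            fl_vs_max=_parse_scalar(row["fl_vs_max"], f"{where}.fl_vs_max"),
            uv_vs_max=_parse_scalar(row["uv_vs_max"], f"{where}.uv_vs_max"),
        ))
    return StandardLibrary(entries)


def load_reference_library() -> StandardLibrary:
    """Load the packaged 107-standard reference library."""
    data = resources.files("hptlcid.data").joinpath("standards_library.tsv").read_text()
    return load_library(io.StringIO(data))


def _fmt(value: float | None) -> str:
    if value is None:
        return ""
    return f"{value:g}"


def write_library(library: StandardLibrary, path: str | PathLike) -> None:
    """Write a library back to TSV; inverse of :func:`load_library`."""
    rows = []
    for e in library:
        rows.append([
            str(e.code), e.name, e.abbreviation, e.compound_class,
            f"{e.rf['MPA']:.3f}", f"{e.rf['MPB']:.3f}",
            *(_fmt(e.hue[c]) for c in HUE_CONDITIONS),
            _fmt(e.fl_pre_max), _fmt(e.fl_pre_min),
            "|".join(_fmt(v) for v in e.uv_pre),
            _fmt(e.fl_np_max),
            "|".join(_fmt(v) for v in e.uv_np),
            _fmt(e.fl_vs_max), _fmt(e.uv_vs_max),
        ])
    frame = pd.DataFrame(rows, columns=_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)


def select_view(library: StandardLibrary, label: str) -> DatabaseView:
    """Return the database view for ``label`` in {1A, 1B, 2A, 2B}."""
    if label not in VIEW_LABELS:
        raise KeyError(f"unknown view label {label!r}; expected one of {sorted(VIEW_LABELS)}")
    phase, reagent = VIEW_LABELS[label]
    return DatabaseView(label=label, mobile_phase=phase, derivatisation=reagent,
                        entries=library.entries)


def summarise(library: StandardLibrary) -> LibrarySummary:
    """Exact extrema and UV-peak-count histogram over a non-empty library."""
    if len(library) == 0:
        raise LibraryValidationError("cannot summarise an empty library")
    rf_range = {}
    for phase in MOBILE_PHASES:
        values = [e.rf[phase] for e in library]
        rf_range[phase] = (min(values), max(values))
    hue_range = {}
    for cond in HUE_CONDITIONS:
        values = [e.hue[cond] for e in library]
        hue_range[cond] = (min(values), max(values))
    histogram = {1: 0, 2: 0, 3: 0}
    for e in library:
        histogram[len(e.uv_pre)] += 1
    return LibrarySummary(
        n_entries=len(library),
        rf_range=rf_range,
        uv_peak_histogram=histogram,
        hue_range=hue_range,
        n_hue254_above_150=sum(1 for e in library if e.hue["dev254"] > 150.0),
    )
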