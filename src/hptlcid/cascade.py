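"""Ordered tolerance-filter cascade for matching a band against a view.

An unknown band is characterised by the same attribute slots as a library
standard. Candidates are screened by a fixed sequence of conjunctive
interval filters — Rf first (±0.05), then the hue angles (±60°, circular),
the pre-derivatisation fluorescence lambda-max and lambda-min (±15 nm),
the pre-derivatisation UV-Vis lambda maxima and peak count (±15 nm), and
finally the post-derivatisation fluorescence (±15 nm) and UV-Vis (±60 nm,
wider to absorb bathochromic/hypsochromic shifts caused by the reagent).
Every stage records its survivors, so a trace reproduces the "number of
potential matches" bookkeeping of a manual database search.

All tolerances are boundary-inclusive: a candidate exactly at the edge of
an interval survives. Stages are independent predicates, so the final
survivor set does not depend on stage order (intermediate counts do).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from os import PathLike
from typing import Mapping, Sequence

import pandas as pd

from .colorimetry import hue_distance
from .errors import CascadeError, LibraryValidationError
from .library import DatabaseView, StandardEntry

__all__ = [
    "Thresholds",
    "BandObservation",
    "Stage",
    "StageResult",
    "FilterTrace",
    "stage_sequence",
    "passes_interval",
    "passes_uv_peaks",
    "run_cascade",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """Filter tolerances; defaults are the validated screening settings."""

    rf_tol: float = 0.05
    hue_tol: float = 60.0
    lambda_tol: float = 15.0
    uv_post_tol: float = 60.0
    wrap_hue: bool = True

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "wrap_hue":
                continue
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")


@dataclass(frozen=True)
class BandObservation:
    """Measured attributes of one unknown band; all but ``rf`` optional.

    ``uv_pre`` is the ascending list of pre-derivatisation UV-Vis maxima;
    the post-derivatisation slots hold a single lambda-max each. A stage
    whose band attribute is ``None`` is skipped with a logged warning.
    """

    rf: float
    hue_dev254: float | None = None
    hue_dev366: float | None = None
    hue_np366: float | None = None
    hue_vsa366: float | None = None
    hue_vsa_white: float | None = None
    fl_pre_max: float | None = None
    fl_pre_min: float | None = None
    uv_pre: tuple[float, ...] | None = None
    fl_np_max: float | None = None
    uv_np_max: float | None = None
    fl_vs_max: float | None = None
    uv_vs_max: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.rf is None:
            raise CascadeError("band observation requires an Rf value")
        if not 0.0 <= self.rf <= 1.0:
            raise LibraryValidationError(f"band Rf {self.rf} outside [0, 1]")
        for name in ("hue_dev254", "hue_dev366", "hue_np366",
                     "hue_vsa366", "hue_vsa_white"):
            value = getattr(self, name)
            if value is not None and not 0.0 <= value < 360.0:
                raise LibraryValidationError(f"band {name} {value} outside [0, 360)")
        if self.uv_pre is not None:
            object.__setattr__(self, "uv_pre", tuple(self.uv_pre))

    def value(self, attribute: str):
        if attribute in ("uv_pre_lambda", "uv_pre_peakcount"):
            return self.uv_pre
        return getattr(self, attribute)


@dataclass(frozen=True)
class Stage:
    """One cascade stage: attribute compared and comparison kind."""

    name: str
    attribute: str
    kind: str  # rf | hue | lambda | uv_lambda | uv_count | lambda_post

    def tolerance(self, thresholds: Thresholds) -> float | None:
        return {
            "rf": thresholds.rf_tol,
            "hue": thresholds.hue_tol,
            "lambda": thresholds.lambda_tol,
            "uv_lambda": thresholds.lambda_tol,
            "uv_count": None,
            "lambda_post": thresholds.uv_post_tol,
        }[self.kind]


_COMMON_HEAD = [
    Stage("rf", "rf", "rf"),
    Stage("hue_dev254", "hue_dev254", "hue"),
    Stage("hue_dev366", "hue_dev366", "hue"),
]
_COMMON_MID = [
    Stage("fl_pre_max", "fl_pre_max", "lambda"),
    Stage("fl_pre_min", "fl_pre_min", "lambda"),
    Stage("uv_pre_lambda", "uv_pre_lambda", "uv_lambda"),
    Stage("uv_pre_peakcount", "uv_pre_peakcount", "uv_count"),
]

_SEQUENCES: Mapping[str, tuple[Stage, ...]] = {
    "NP-PEG": tuple(
        _COMMON_HEAD
        + [Stage("hue_np366", "hue_np366", "hue")]
        + _COMMON_MID
        + [Stage("fl_np_max", "fl_np_max", "lambda"),
           Stage("uv_np_max", "uv_np_max", "lambda_post")]
    ),
    "VSA": tuple(
        _COMMON_HEAD
        + [Stage("hue_vsa366", "hue_vsa366", "hue"),
           Stage("hue_vsa_white", "hue_vsa_white", "hue")]
        + _COMMON_MID
        + [Stage("fl_vs_max", "fl_vs_max", "lambda"),
           Stage("uv_vs_max", "uv_vs_max", "lambda_post")]
    ),
}


def stage_sequence(view_label: str) -> tuple[Stage, ...]:
    """The ordered stage list for a view: 10 stages for NP-PEG views
    (1A, 2A), 11 for VSA views (1B, 2B), which add the white-light hue."""
    from .library import VIEW_LABELS

    if view_label not in VIEW_LABELS:
        raise CascadeError(f"unknown view label {view_label!r}")
    return _SEQUENCES[VIEW_LABELS[view_label][1]]


#: Guard for binary representation error in decimal data: recorded values
#: such as 0.580 and 0.630 must sit exactly on the inclusive +/-0.05
#: boundary even though their float difference is 0.0500...044.
_EPS = 1e-9


def passes_interval(query_value: float, candidate_value: float, tol: float) -> bool:
    """Boundary-inclusive interval test: |query - candidate| <= tol."""
    return abs(query_value - candidate_value) <= tol + _EPS


def passes_uv_peaks(query_peaks: Sequence[float], candidate_peaks: Sequence[float],
                    tol: float) -> bool:
    """Positional UV peak-list match: equal peak count and each pair of
    same-rank maxima within ``tol``. A band with one maximum can therefore
    never match a standard showing two or three."""
    if len(query_peaks) != len(candidate_peaks):
        return False
    return all(passes_interval(q, c, tol) for q, c in zip(query_peaks, candidate_peaks))


def _stage_predicate(stage: Stage, query, thresholds: Thresholds):
    tol = stage.tolerance(thresholds)

    def predicate(candidate_value) -> bool:
        if candidate_value is None:
            return False  # a signature that was never recorded cannot match
        if stage.kind == "hue":
            return hue_distance(query, candidate_value, wrap=thresholds.wrap_hue) <= tol + _EPS
        if stage.kind == "uv_lambda":
            shared = min(len(query), len(candidate_value))
            return all(passes_interval(q, c, tol)
                       for q, c in zip(query[:shared], candidate_value[:shared]))
        if stage.kind == "uv_count":
            return len(query) == len(candidate_value)
        return passes_interval(query, candidate_value, tol)

    return predicate


@dataclass(frozen=True)
class StageResult:
    """Audit record of one applied (or skipped) stage."""

    name: str
    attribute: str
    threshold: float | None
    survivors: tuple[int, ...]
    skipped: bool = False

    @property
    def count(self) -> int:
        return len(self.survivors)


@dataclass(frozen=True)
class FilterTrace:
    """Ordered record of every cascade stage and its surviving codes."""

    view_label: str
    stages: tuple[StageResult, ...]
    entries: Mapping[int, StandardEntry] = field(repr=False, default_factory=dict)

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(stage.count for stage in self.stages)

    @property
    def applied_counts(self) -> tuple[int, ...]:
        return tuple(s.count for s in self.stages if not s.skipped)

    @property
    def final_codes(self) -> frozenset[int]:
        return frozenset(self.stages[-1].survivors)

    @property
    def final_entries(self) -> tuple[StandardEntry, ...]:
        return tuple(self.entries[code] for code in sorted(self.final_codes))

    def to_frame(self) -> pd.DataFrame:
        """One row per stage: stage, threshold, count, survivor codes."""
        return pd.DataFrame({
            "stage": [s.name for s in self.stages],
            "threshold": [s.threshold for s in self.stages],
            "skipped": [s.skipped for s in self.stages],
            "count": [s.count for s in self.stages],
            "survivors": [",".join(str(c) for c in s.survivors) for s in self.stages],
        })

    def write_tsv(self, path: str | PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def run_cascade(band: BandObservation, view: DatabaseView,
                thresholds: Thresholds | None = None) -> FilterTrace:
    """Apply the stage sequence of ``view`` to ``band``.

    Stages whose band attribute is absent are skipped (warning logged) and
    recorded in the trace with an unchanged survivor set; candidates
    lacking a value for an applied stage are eliminated at that stage.
    The last stage's survivors are the band's potential matches.
    """
    if not view.entries:
        raise CascadeError("cannot run a cascade against an empty view")
    thresholds = thresholds or Thresholds()
    survivors = list(view.entries)
    results: list[StageResult] = []
    for stage in stage_sequence(view.label):
        query = band.value(stage.attribute)
        if query is None:
            logger.warning("band has no %s; stage skipped", stage.attribute)
            results.append(StageResult(
                name=stage.name, attribute=stage.attribute, threshold=None,
                survivors=tuple(e.code for e in survivors), skipped=True))
            continue
        predicate = _stage_predicate(stage, query, thresholds)
        survivors = [e for e in survivors if predicate(view.value(e, stage.attribute))]
        results.append(StageResult(
            name=stage.name, attribute=stage.attribute,
            threshold=stage.tolerance(thresholds),
            survivors=tuple(e.code for e in survivors)))
    return FilterTrace(view_label=view.label, stages=tuple(results),
                       entries={e.code: e for e in view.entries})
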