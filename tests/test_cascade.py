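"""Filter-cascade behaviour: predicates, traces, and recorded control runs."""

import dataclasses

import numpy as np
import pytest

from hptlcid import validation
from hptlcid.cascade import (
    BandObservation,
    Thresholds,
    passes_interval,
    passes_uv_peaks,
    run_cascade,
    stage_sequence,
)
from hptlcid.errors import CascadeError
from hptlcid.library import select_view
from hptlcid.synth import jitter_band

from conftest import brute_force_matches, random_band


@pytest.mark.parametrize("query, candidate, tol, expected", [
    (276, 261, 15, True),    # survives at exactly the 15 nm boundary
    (258, 243, 15, True),    # boundary-inclusive on the lambda-min side
    (239, 223, 15, False),   # 16 nm off: eliminated
    (288, 306, 60, True),    # wide post-derivatisation tolerance
])
def test_interval_predicate_boundaries(query, candidate, tol, expected):
    assert passes_interval(query, candidate, tol) is expected


def test_interval_predicate_tolerates_decimal_representation():
    # 0.630 - 0.580 is not exactly representable; it must still pass +/-0.05
    assert passes_interval(0.580, 0.630, 0.05)


@pytest.mark.parametrize("query, candidate, expected", [
    ([276], [261, 364], False),        # peak-count mismatch eliminates
    ([269, 369], [269, 371], True),    # two maxima, both within 15 nm
    ([276], [267], True),
    ([269, 369], [269, 325], False),   # second maximum too far
])
def test_uv_peak_list_matching(query, candidate, expected):
    assert passes_uv_peaks(query, candidate, 15) is expected


def test_stage_sequences_per_reagent():
    np_stages = [s.name for s in stage_sequence("1A")]
    vs_stages = [s.name for s in stage_sequence("1B")]
    assert len(np_stages) == 10 and len(vs_stages) == 11
    assert np_stages[0] == vs_stages[0] == "rf"
    assert "hue_np366" in np_stages and "hue_np366" not in vs_stages
    assert {"hue_vsa366", "hue_vsa_white"} <= set(vs_stages)
    assert [s.name for s in stage_sequence("2A")] == np_stages
    with pytest.raises(CascadeError):
        stage_sequence("3C")


def test_positive_control_trace_matches_recorded_counts(library):
    """Test compound A against the MPA/NP-PEG view reproduces the recorded
    per-stage survivor bookkeeping and final five candidates."""
    trace = run_cascade(validation.TEST_A_1A_BAND,
                        validation.control_view(library, "1A"))
    assert trace.counts == validation.TEST_A_1A_STAGE_COUNTS
    assert trace.final_codes == validation.TEST_A_1A_FINAL_CODES
    # nested survivor sets
    for earlier, later in zip(trace.stages, trace.stages[1:]):
        assert set(later.survivors) <= set(earlier.survivors)


def test_survivor_counts_never_increase(library):
    rng = np.random.default_rng(7)
    for label in ("1A", "1B", "2A", "2B"):
        view = select_view(library, label)
        for _ in range(10):
            entry = library[int(rng.integers(1, 108))]
            trace = run_cascade(random_band(rng, entry, label), view)
            counts = trace.counts
            assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_final_set_agrees_with_conjunction_oracle(library):
    """Stages are conjunctive and order-free: the staged result equals a
    direct per-candidate conjunction, whatever the stage order."""
    rng = np.random.default_rng(11)
    for label in ("1A", "1B", "2A", "2B"):
        view = select_view(library, label)
        for _ in range(25):
            band = random_band(rng, library[int(rng.integers(1, 108))], label)
            trace = run_cascade(band, view)
            assert trace.final_codes == brute_force_matches(band, view)


def test_every_standard_survives_its_own_cascade(library):
    for label in ("1A", "2B"):
        view = select_view(library, label)
        for entry in library:
            band = jitter_band(entry, fraction=0.0, view_label=label)
            assert entry.code in run_cascade(band, view).final_codes


def test_missing_attribute_skips_stage(library, caplog):
    band = dataclasses.replace(validation.TEST_A_1A_BAND, hue_np366=None)
    with caplog.at_level("WARNING", logger="hptlcid.cascade"):
        trace = run_cascade(band, validation.control_view(library, "1A"))
    skipped = [s for s in trace.stages if s.skipped]
    assert [s.name for s in skipped] == ["hue_np366"]
    assert "hue_np366" in caplog.text
    # without the NP hue filter the final set can only grow
    assert trace.final_codes >= validation.TEST_A_1A_FINAL_CODES


def test_zero_tolerances_with_perturbed_band_yield_empty_set(library):
    entry = library[58]
    band = jitter_band(entry, fraction=0.0, view_label="1A")
    shifted = dataclasses.replace(
        band, rf=band.rf + 0.001, hue_dev254=band.hue_dev254 + 0.001)
    strict = Thresholds(rf_tol=0.0, hue_tol=0.0, lambda_tol=0.0, uv_post_tol=0.0)
    trace = run_cascade(shifted, select_view(library, "1A"), strict)
    assert trace.final_codes == frozenset()


def test_wraparound_hue_keeps_antipodal_neighbours(library):
    """4-methylpyrocatechol (white-light hue 345 deg) must survive a query
    hue of 36 deg: the circular gap is 51 deg <= 60."""
    entry = library[90]
    band = dataclasses.replace(
        jitter_band(entry, fraction=0.0, view_label="1B"), hue_vsa_white=36.0)
    view = select_view(library, "1B")
    assert 90 in run_cascade(band, view).final_codes
    no_wrap = Thresholds(wrap_hue=False)
    assert 90 not in run_cascade(band, view, no_wrap).final_codes


def test_band_requires_rf():
    with pytest.raises(CascadeError):
        BandObservation(rf=None)


def test_empty_view_rejected(library):
    view = dataclasses.replace(select_view(library, "1A"), entries=())
    with pytest.raises(CascadeError):
        run_cascade(validation.TEST_A_1A_BAND, view)


def test_trace_table_shape(library):
    trace = run_cascade(validation.TEST_A_1A_BAND,
                        validation.control_view(library, "1A"))
    frame = trace.to_frame()
    assert list(frame.columns) == ["stage", "threshold", "skipped", "count", "survivors"]
    assert len(frame) == 10
    assert frame["count"].tolist() == list(trace.counts)
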