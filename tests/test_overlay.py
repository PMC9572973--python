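"""Spectrum I/O, windowing, normalisation, overlay scores, and decisions."""

import io

import numpy as np
import pytest

from hptlcid import validation
from hptlcid.errors import SpectrumError, WindowError
from hptlcid.overlay import (
    ComparisonWindow,
    DecisionConfig,
    Spectrum,
    align,
    clip,
    decide,
    decide_scores,
    normalise,
    read_spectrum,
    score_overlay,
    write_spectrum,
)
from hptlcid.synth import SyntheticSpectrumSpec, make_entry_spectra, make_spectrum

from conftest import overlay_oracle


def gaussian(centre, width=20.0, grid=(250.0, 500.0, 1.0), noise=0.0, seed=0):
    return make_spectrum(SyntheticSpectrumSpec(
        peaks=((centre, 1.0, width),), grid=grid, noise_sd=noise, seed=seed))


# ------------------------------------------------------------------- I/O
def test_read_two_column_csv():
    s = read_spectrum(io.StringIO("250,0.1\n260,0.4\n"))
    assert len(s) == 2 and s.intensities[1] == pytest.approx(0.4)


def test_read_tolerates_header_and_tabs():
    s = read_spectrum(io.StringIO("wavelength\tabs\n250\t0.1\n260\t0.4\n"))
    assert len(s) == 2


@pytest.mark.parametrize("text, message", [
    ("250,0.1\nabc,0.4\n", "line 2"),
    ("250,0.1\n250,0.2\n", "duplicate wavelength"),
    ("250,0.1\n", "at least 2"),
])
def test_read_errors(text, message):
    with pytest.raises(SpectrumError, match=message):
        read_spectrum(io.StringIO(text))


def test_write_read_round_trip(tmp_path):
    s = gaussian(350.0, noise=0.01, seed=5)
    path = tmp_path / "s.csv"
    write_spectrum(s, path)
    again = read_spectrum(path)
    assert np.array_equal(again.wavelengths, s.wavelengths)
    assert np.array_equal(again.intensities, s.intensities)


def test_spectrum_invariants():
    with pytest.raises(SpectrumError):
        Spectrum(np.array([250.0, 250.0, 260.0]), np.array([1.0, 2.0, 3.0]))
    with pytest.raises(SpectrumError):
        Spectrum(np.array([250.0]), np.array([1.0]))


# ------------------------------------------------------- clip / normalise
def test_clip_restricts_inclusively():
    s = gaussian(350.0, grid=(190.0, 900.0, 1.0))
    c = clip(s, ComparisonWindow(250.0, 500.0))
    assert c.wavelengths[0] == 250.0 and c.wavelengths[-1] == 500.0


def test_clip_identity_when_window_covers_range():
    s = gaussian(350.0)
    c = clip(s, ComparisonWindow(250.0, 500.0))
    assert np.array_equal(c.intensities, s.intensities)


def test_clip_requires_overlap():
    s = gaussian(350.0, grid=(190.0, 500.0, 1.0))
    with pytest.raises(WindowError):
        clip(s, ComparisonWindow(600.0, 700.0))


def test_normalise_scales_to_unit_maximum():
    s = Spectrum(np.array([1.0, 2.0, 3.0]), np.array([0.5, 2.0, 1.0]))
    n = normalise(s)
    assert n.intensities == pytest.approx([0.25, 1.0, 0.5])
    assert np.array_equal(normalise(n).intensities, n.intensities)  # idempotent


def test_normalise_rejects_nonpositive_maximum():
    with pytest.raises(SpectrumError):
        normalise(Spectrum(np.array([1.0, 2.0]), np.array([0.0, 0.0])))


def test_align_interpolates_standard_onto_unknown_grid():
    unknown = Spectrum(np.array([0.0, 2.0, 4.0]), np.array([1.0, 2.0, 3.0]))
    standard = Spectrum(np.array([0.0, 1.0, 2.0, 3.0, 4.0]),
                        np.array([0.0, 1.0, 2.0, 3.0, 4.0]))
    grid, u, s = align(unknown, standard)
    assert np.array_equal(grid, [0.0, 2.0, 4.0])
    assert s == pytest.approx([0.0, 2.0, 4.0])
    disjoint = Spectrum(np.array([10.0, 11.0]), np.array([1.0, 2.0]))
    with pytest.raises(WindowError):
        align(unknown, disjoint)


# ----------------------------------------------------------------- scoring
def test_self_overlay_is_perfect():
    s = gaussian(350.0)
    result = score_overlay(s, s)
    assert result.pearson_r == pytest.approx(1.0)
    assert result.percent_within == 100.0
    assert result.n_points == 251


def test_everywhere_separated_curves_score_zero_percent():
    wl = np.linspace(250.0, 500.0, 26)
    unknown = Spectrum(wl, np.linspace(1.0, 0.5, wl.size))  # max at the left
    standard = Spectrum(wl, np.concatenate([np.full(wl.size - 1, 0.2), [1.0]]))
    result = score_overlay(unknown, standard, ComparisonWindow(250.0, 500.0))
    # both already normalised; gaps >= 0.3 everywhere, 0.5 at the last point
    assert result.percent_within == 0.0


def test_two_gaussians_match_direct_summation_oracle():
    u, s = gaussian(350.0), gaussian(360.0)
    result = score_overlay(u, s, ComparisonWindow(250.0, 500.0))
    r, within = overlay_oracle(u, s, 250.0, 500.0)
    assert result.pearson_r == pytest.approx(r, abs=1e-12)
    assert result.percent_within == pytest.approx(within, abs=1e-12)


def test_random_spectra_match_oracle_and_band_monotonicity():
    rng = np.random.default_rng(42)
    for _ in range(30):
        u = gaussian(rng.uniform(280, 460), rng.uniform(10, 40),
                     noise=0.02, seed=int(rng.integers(2**31)))
        s = gaussian(rng.uniform(280, 460), rng.uniform(10, 40),
                     noise=0.02, seed=int(rng.integers(2**31)))
        result = score_overlay(u, s)
        r, within = overlay_oracle(u, s, 250.0, 500.0)
        assert result.pearson_r == pytest.approx(r, abs=1e-9)
        assert result.percent_within == pytest.approx(within, abs=1e-9)
        narrower = score_overlay(u, s, band=0.0625)
        assert narrower.percent_within <= result.percent_within


def test_constant_spectrum_has_undefined_correlation():
    flat = Spectrum(np.linspace(250, 500, 10), np.full(10, 0.7))
    peaked = gaussian(350.0)
    with pytest.raises(SpectrumError):
        score_overlay(flat, peaked, ComparisonWindow(250.0, 500.0))


# ---------------------------------------------------------------- decisions
def test_recorded_scores_escalate_then_select_syringic_acid():
    """The two shortlisted candidates for test compound A cannot be told
    apart before derivatisation; the NP-PEG overlay separates them by
    percent-within, the VSA overlay by correlation."""
    pre_only = {"uv_pre": dict(validation.OVERLAY_SCORES_A["uv_pre"])}
    assert decide_scores(pre_only).status == "ambiguous"

    d = decide_scores(dict(validation.OVERLAY_SCORES_A))
    assert (d.status, d.candidate, d.state) == ("matched", 58, "uv_np")

    vs_only = {"uv_vs": dict(validation.OVERLAY_SCORES_A["uv_vs"])}
    d = decide_scores(vs_only)
    assert (d.status, d.candidate) == ("matched", 58)
    assert "correlation gap" in d.reason


def test_recorded_flavonol_scores_select_kaempferol():
    d = decide_scores(dict(validation.OVERLAY_SCORES_B_MPA))
    assert (d.status, d.candidate) == ("matched", 14)


def test_recorded_negative_control_scores_are_rejected():
    d = decide_scores(dict(validation.OVERLAY_SCORES_C_MPA))
    assert d.status == "no_match"


def test_decision_is_permutation_invariant():
    scores = {"uv_pre": {"a": (0.90, 80.0), "b": (0.85, 70.0), "c": (0.60, 30.0)}}
    flipped = {"uv_pre": dict(reversed(list(scores["uv_pre"].items())))}
    assert decide_scores(scores).candidate == decide_scores(flipped).candidate


def test_gaps_are_strict():
    cfg = DecisionConfig(floors=None)
    exactly_at = {"uv_pre": {"a": (0.900, 60.0), "b": (0.800, 50.0)}}
    assert decide_scores(exactly_at, cfg).status == "ambiguous"
    just_over = {"uv_pre": {"a": (0.901, 60.0), "b": (0.800, 50.0)}}
    assert decide_scores(just_over, cfg).candidate == "a"


def test_no_scores_at_all_is_an_error():
    with pytest.raises(SpectrumError):
        decide_scores({})


def test_decide_end_to_end_with_synthetic_spectra(library):
    """An unknown equal to one candidate's spectra is matched; two
    identical candidates are ambiguous."""
    ms, sya = library[48], library[58]
    cand = {48: make_entry_spectra(ms), 58: make_entry_spectra(sya)}
    unknown = make_entry_spectra(sya, seed=3, noise_sd=0.01)
    d = decide(unknown, cand)
    assert (d.status, d.candidate) == ("matched", 58)

    clone = {1: make_entry_spectra(sya), 2: make_entry_spectra(sya)}
    assert decide(unknown, clone).status == "ambiguous"
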