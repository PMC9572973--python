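"""Synthetic spectra and perturbed band observations for testing.

Real densitometer exports are not distributable, so every scoring and
matching path is exercised with synthetic data: sums of Gaussian peaks on
a regular wavelength grid (the simplest smooth unimodal stand-in for an
absorbance band — peak shape is irrelevant to the scoring contracts), and
band observations derived from a library standard by jittering each
attribute uniformly within a chosen fraction of its filter tolerance (the
synthetic analogue of spiking a known standard into artificial honey).
All randomness is explicitly seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cascade import BandObservation, Thresholds
from .library import StandardEntry, VIEW_LABELS
from .overlay import DEFAULT_WINDOWS, Spectrum

__all__ = ["SyntheticSpectrumSpec", "make_spectrum", "jitter_band", "make_entry_spectra"]


@dataclass(frozen=True)
class SyntheticSpectrumSpec:
    """Recipe for one synthetic spectrum: Gaussian peaks (centre nm,
    height AU, width-sigma nm) on a regular grid, plus optional seeded
    Gaussian noise."""

    peaks: tuple[tuple[float, float, float], ...]
    grid: tuple[float, float, float] = (250.0, 500.0, 1.0)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(tuple(p) for p in self.peaks))
        if not self.peaks:
            raise ValueError("need at least one peak")
        low, high, step = self.grid
        if step <= 0 or high <= low:
            raise ValueError(f"bad grid {self.grid}")
        for centre, height, width in self.peaks:
            if height <= 0 or width <= 0:
                raise ValueError("peak heights and widths must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_spectrum(spec: SyntheticSpectrumSpec, modality: str = "uv-vis",
                  state: str = "pre") -> Spectrum:
    """Evaluate the Gaussian mixture of ``spec`` on its grid.

    Deterministic for a fixed seed; with ``noise_sd = 0`` the seed is
    irrelevant and a solitary peak attains exactly its nominal height
    whenever its centre lies on the grid.
    """
    low, high, step = spec.grid
    wl = np.arange(low, high + step / 2, step)
    ab = np.zeros_like(wl)
    for centre, height, width in spec.peaks:
        ab += height * np.exp(-0.5 * ((wl - centre) / width) ** 2)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        ab = ab + rng.normal(0.0, spec.noise_sd, size=wl.size)
    return Spectrum(wl, ab, modality=modality, state=state)


def _wrap_hue(value: float) -> float:
    return value % 360.0


def jitter_band(entry: StandardEntry, fraction: float, view_label: str,
                seed: int = 0,
                thresholds: Thresholds | None = None) -> BandObservation:
    """A band observation for ``view_label`` whose every attribute is the
    entry's value perturbed uniformly within ±fraction x tolerance.

    With ``fraction < 1`` the source standard survives its own cascade by
    construction (all filters are boundary-inclusive); ``fraction < 0.5``
    leaves headroom for an equal measurement error on the library side.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    if view_label not in VIEW_LABELS:
        raise KeyError(f"unknown view label {view_label!r}")
    phase, reagent = VIEW_LABELS[view_label]
    thresholds = thresholds or Thresholds()
    rng = np.random.default_rng(seed)

    def jit(value: float, tol: float) -> float:
        return float(value + rng.uniform(-fraction * tol, fraction * tol))

    kwargs: dict = {
        "label": view_label,
        "rf": min(1.0, max(0.0, jit(entry.rf[phase], thresholds.rf_tol))),
        "hue_dev254": _wrap_hue(jit(entry.hue["dev254"], thresholds.hue_tol)),
        "hue_dev366": _wrap_hue(jit(entry.hue["dev366"], thresholds.hue_tol)),
        "fl_pre_max": jit(entry.fl_pre_max, thresholds.lambda_tol),
        "fl_pre_min": jit(entry.fl_pre_min, thresholds.lambda_tol),
        "uv_pre": tuple(sorted(jit(v, thresholds.lambda_tol) for v in entry.uv_pre)),
    }
    if reagent == "NP-PEG":
        kwargs["hue_np366"] = _wrap_hue(jit(entry.hue["np366"], thresholds.hue_tol))
        kwargs["fl_np_max"] = jit(entry.fl_np_max, thresholds.lambda_tol)
        kwargs["uv_np_max"] = jit(entry.uv_np[0], thresholds.uv_post_tol)
    else:
        kwargs["hue_vsa366"] = _wrap_hue(jit(entry.hue["vsa366"], thresholds.hue_tol))
        kwargs["hue_vsa_white"] = _wrap_hue(jit(entry.hue["vsa_white"], thresholds.hue_tol))
        if entry.fl_vs_max is not None:
            kwargs["fl_vs_max"] = jit(entry.fl_vs_max, thresholds.lambda_tol)
        if entry.uv_vs_max is not None:
            kwargs["uv_vs_max"] = jit(entry.uv_vs_max, thresholds.uv_post_tol)
    return BandObservation(**kwargs)


def make_entry_spectra(entry: StandardEntry, seed: int = 0, noise_sd: float = 0.0,
                       width: float = 20.0) -> dict[str, Spectrum]:
    """Plausible synthetic spectra for a standard, one per spectrum kind,
    with Gaussian peaks centred on the entry's recorded lambda maxima.

    Useful for end-to-end demonstrations when no densitometer exports are
    at hand; the curves are cartoons, not chromophore physics.
    """
    out: dict[str, Spectrum] = {}

    def build(key: str, centres, modality: str, state: str, index: int) -> None:
        window = DEFAULT_WINDOWS[key]
        peaks = tuple((c, 1.0 * (0.8 ** i), width) for i, c in enumerate(centres))
        spec = SyntheticSpectrumSpec(
            peaks=peaks, grid=(window.low - 20.0, window.high + 20.0, 1.0),
            noise_sd=noise_sd, seed=seed * 16 + index)
        out[key] = make_spectrum(spec, modality=modality, state=state)

    build("uv_pre", entry.uv_pre, "uv-vis", "pre", 0)
    build("uv_np", entry.uv_np, "uv-vis", "np-peg", 1)
    if entry.uv_vs_max is not None:
        build("uv_vs", (entry.uv_vs_max,), "uv-vis", "vsa", 2)
    build("fl_pre", (entry.fl_pre_max,), "fluorescence", "pre", 3)
    build("fl_np", (entry.fl_np_max,), "fluorescence", "np-peg", 4)
    if entry.fl_vs_max is not None:
        build("fl_vs", (entry.fl_vs_max,), "fluorescence", "vsa", 5)
    return out
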