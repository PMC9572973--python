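"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately re-derive results by direct computation (plain
loops, explicit formulas) so they share no code path with the package
implementations they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

from hptlcid import load_reference_library
from hptlcid.cascade import BandObservation, Thresholds
from hptlcid.library import DatabaseView

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def library():
    return load_reference_library()


# --------------------------------------------------------------- oracles
def _wrap_dist(a: float, b: float) -> float:
    d = abs(a - b)
    return min(d, 360.0 - d)


def _near(q: float, c: float, tol: float) -> bool:
    return abs(q - c) <= tol + 1e-9


def brute_force_matches(band: BandObservation, view: DatabaseView,
                        thresholds: Thresholds | None = None) -> set[int]:
    """Order-free conjunction oracle: evaluates every filter directly per
    candidate, independent of the staged cascade implementation."""
    th = thresholds or Thresholds()
    reagent = view.derivatisation
    hue_conditions = ["dev254", "dev366"] + (
        ["np366"] if reagent == "NP-PEG" else ["vsa366", "vsa_white"])
    out = set()
    for e in view.entries:
        keep = _near(band.rf, view.rf_of(e), th.rf_tol)
        for cond in hue_conditions:
            q = getattr(band, f"hue_{cond}")
            if q is None or not keep:
                continue
            d = (_wrap_dist(q, e.hue[cond]) if th.wrap_hue else abs(q - e.hue[cond]))
            keep = d <= th.hue_tol + 1e-9
        for attr in ("fl_pre_max", "fl_pre_min"):
            q = getattr(band, attr)
            if q is not None and keep:
                keep = _near(q, getattr(e, attr), th.lambda_tol)
        if band.uv_pre is not None and keep:
            keep = (len(band.uv_pre) == len(e.uv_pre)
                    and all(_near(q, c, th.lambda_tol)
                            for q, c in zip(band.uv_pre, e.uv_pre)))
        if reagent == "NP-PEG":
            post = [(band.fl_np_max, e.fl_np_max, th.lambda_tol),
                    (band.uv_np_max, e.uv_np[0], th.uv_post_tol)]
        else:
            post = [(band.fl_vs_max, e.fl_vs_max, th.lambda_tol),
                    (band.uv_vs_max, e.uv_vs_max, th.uv_post_tol)]
        for q, c, tol in post:
            if q is not None and keep:
                keep = c is not None and _near(q, c, tol)
        if keep:
            out.add(e.code)
    return out


def overlay_oracle(unknown, standard, low: float, high: float,
                   band: float = 0.125) -> tuple[float, float]:
    """Direct-summation re-computation of the overlay scores.

    Clips both spectra to [low, high], rescales each by its own windowed
    maximum, interpolates the standard by hand onto the unknown's grid and
    accumulates the Pearson sums and the within-band count in a plain loop.
    """
    uw = [(w, a) for w, a in zip(unknown.wavelengths, unknown.intensities)
          if low <= w <= high]
    sw = [(w, a) for w, a in zip(standard.wavelengths, standard.intensities)
          if low <= w <= high]
    u_max = max(a for _, a in uw)
    s_max = max(a for _, a in sw)
    uw = [(w, a / u_max) for w, a in uw]
    sw = [(w, a / s_max) for w, a in sw]

    def interp(x: float) -> float:
        if x <= sw[0][0]:
            return sw[0][1]
        if x >= sw[-1][0]:
            return sw[-1][1]
        for (w0, a0), (w1, a1) in zip(sw, sw[1:]):
            if w0 <= x <= w1:
                return a0 + (a1 - a0) * (x - w0) / (w1 - w0)
        raise AssertionError("unreachable")

    lo = max(uw[0][0], sw[0][0])
    hi = min(uw[-1][0], sw[-1][0])
    pairs = [(a, interp(w)) for w, a in uw if lo <= w <= hi]
    n = len(pairs)
    su = sum(u for u, _ in pairs)
    ss = sum(s for _, s in pairs)
    suu = sum(u * u for u, _ in pairs)
    sss = sum(s * s for _, s in pairs)
    sus = sum(u * s for u, s in pairs)
    r = (n * sus - su * ss) / math.sqrt((n * suu - su * su) * (n * sss - ss * ss))
    within = 100.0 * sum(1 for u, s in pairs if abs(u - s) <= band) / n
    return r, within


def random_band(rng: np.random.Generator, entry, view_label: str,
                scale: float = 2.0) -> BandObservation:
    """A query band derived from ``entry`` with uniform perturbations of up
    to ``scale`` x each tolerance and randomly omitted attributes, so both
    pass and fail branches of every filter are exercised."""
    from hptlcid.synth import jitter_band  # base shape, then stretch

    th = Thresholds()
    band = jitter_band(entry, fraction=0.0, view_label=view_label, seed=0)
    values = {k: v for k, v in vars(band).items() if v is not None}

    def stretch(value, tol):
        return value + rng.uniform(-scale * tol, scale * tol)

    tols = {"rf": th.rf_tol, "fl_pre_max": th.lambda_tol, "fl_pre_min": th.lambda_tol,
            "fl_np_max": th.lambda_tol, "fl_vs_max": th.lambda_tol,
            "uv_np_max": th.uv_post_tol, "uv_vs_max": th.uv_post_tol}
    out = {}
    for key, value in values.items():
        if key == "label":
            out[key] = value
            continue
        if key != "rf" and rng.random() < 0.2:
            continue  # drop the attribute; the stage will be skipped
        if key.startswith("hue_"):
            out[key] = stretch(value, th.hue_tol) % 360.0
        elif key == "uv_pre":
            peaks = [stretch(v, th.lambda_tol) for v in value]
            if rng.random() < 0.3:
                peaks = peaks[: rng.integers(1, len(peaks) + 1)]
            out[key] = tuple(sorted(peaks))
        else:
            out[key] = min(1.0, max(0.0, stretch(value, tols[key]))) \
                if key == "rf" else stretch(value, tols[key])
    return BandObservation(**out)
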