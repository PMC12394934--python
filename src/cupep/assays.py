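"""Arithmetic for the plate-based assays.

* Degree of hydrolysis: DH% = (h / h_tot) x 100, where h is the
  free-amine content of a sample in leucine equivalents per gram and
  h_tot the total molar equivalence per gram of protein.
* Copper chelation (zincon competition): the sample absorbance is the
  full well (sample + Cu + chelator) minus the sample-plus-copper
  background, and chelation% = (A_control - A_sample) / A_control x 100.
  Negative percents (a sample raising apparent free copper) are reported
  with a warning, not clipped.
* Luminescence AUC: trapezoidal integral of a kinetic trace over a fixed
  window (default 20 min), with the window edge linearly interpolated.
* ROS readout normalisation: with-metal signal over the matched
  without-metal baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "AssayMeasurement",
    "KineticTrace",
    "EndpointSet",
    "degree_of_hydrolysis",
    "chelation_percent",
    "luminescence_auc",
    "normalize_to_no_metal",
    "replicate_summary",
]


@dataclass(frozen=True)
class AssayMeasurement:
    """Free-amine equivalents of a sample and the total molar equivalence."""

    h: float
    h_tot: float

    def __post_init__(self) -> None:
        if self.h < 0:
            raise ValueError(f"h must be >= 0, got {self.h}")
        if self.h_tot <= 0:
            raise ValueError(f"h_tot must be > 0, got {self.h_tot}")


def degree_of_hydrolysis(m: AssayMeasurement) -> float:
    """DH% = (h / h_tot) x 100."""
    return m.h / m.h_tot * 100.0


@dataclass(frozen=True)
class EndpointSet:
    """Endpoint readings of a chelation-competition well set.

    ``a_control``: chelator + Cu, no sample. ``a_sample_background``:
    sample + Cu, no chelator. ``a_full``: sample + Cu + chelator.
    """

    a_control: float
    a_sample_background: float
    a_full: float

    def __post_init__(self) -> None:
        for name in ("a_control", "a_sample_background", "a_full"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def chelation_percent(e: EndpointSet) -> float:
    """Chelated-copper percent from a zincon-style competition endpoint.

    A_sample = A_full - A_sample_background, then
    ((A_control - A_sample) / A_control) x 100. Values below 0 are
    returned as-is with a warning.
    """
    if e.a_control <= 0:
        raise ValueError("a_control must be > 0")
    a_sample = e.a_full - e.a_sample_background
    pct = (e.a_control - a_sample) / e.a_control * 100.0
    if pct < 0:
        warnings.warn(
            f"chelation percent {pct:.3g} below 0: sample raises apparent free copper",
            stacklevel=2,
        )
    return pct


@dataclass(frozen=True)
class KineticTrace:
    """Time-ordered plate-reader readings of one replicate.

    Times are minutes, strictly increasing; signals are instrument units,
    nonnegative; at least two points are needed to integrate.
    """

    time_min: np.ndarray
    signal: np.ndarray
    replicate: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "signal", s)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("time and signal must be equal-length 1-D vectors")
        if t.size < 2:
            raise ValueError("a kinetic trace needs >= 2 points for integration")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time points must be strictly increasing")
        if np.any(s < 0):
            raise ValueError("signal values must be >= 0")


def luminescence_auc(trace: KineticTrace, window_minutes: float = 20.0) -> float:
    """Trapezoidal integral of the signal over [0, window] (signal·min).

    The trace must cover the window; a partial last interval is handled by
    linear interpolation of the signal at the window edge.
    """
    if window_minutes <= 0:
        raise ValueError("window must be > 0")
    t, s = trace.time_min, trace.signal
    if window_minutes > t[-1] + 1e-12:
        raise ValueError(
            f"window {window_minutes} min extends beyond trace end {t[-1]} min")
    lo, hi = max(0.0, t[0]), float(window_minutes)
    inside = (t > lo) & (t < hi)
    tt = np.concatenate([[lo], t[inside], [hi]])
    ss = np.interp(tt, t, s)
    return float(np.trapezoid(ss, tt))


def normalize_to_no_metal(signal_with_metal: float, signal_without_metal: float) -> float:
    """Ratio of a with-metal signal to its matched no-metal baseline."""
    if signal_without_metal <= 0:
        raise ValueError("no-metal baseline must be > 0")
    return signal_with_metal / signal_without_metal


def replicate_summary(values: Sequence[float]) -> dict[str, float]:
    """Mean ± SEM with n over replicate measurements."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no replicate values")
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else float("nan")
    return {"mean": float(arr.mean()), "sem": sem, "n": int(arr.size)}
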