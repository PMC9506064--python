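"""Synthetic pulse-trace generation and resistance estimation.

Low-voltage electroporators driven by capacitor banks do not deliver
perfectly rectangular pulses: the bank discharges during the pulse, so
the applied voltage droops.  This module emulates oscilloscope
recordings of such pulses (voltage and current, multiplicative gaussian
measurement noise) and provides the estimator used to validate the
device model: the system resistance as the voltage-to-current ratio
over the pulse window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import InvalidInputError

__all__ = [
    "PulseSpec",
    "PulseTrace",
    "generate_trace",
    "resistance_from_trace",
    "trace_to_csv",
    "trace_from_csv",
]


@dataclass(frozen=True)
class PulseSpec:
    """Applied pulse-train description.

    ``droop_tau`` models the generator's capacitor discharge as a single
    exponential; ``math.inf`` gives ideal rectangular pulses.
    """

    amplitude: float = 20.0  # V, peak (reported convention)
    duration: float = 10e-3  # s
    count: int = 1
    repetition_frequency: float = 1.0  # Hz
    droop_tau: float = 50e-3  # s
    polarity: int = +1

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise InvalidInputError("duration must be > 0")
        if self.count < 1:
            raise InvalidInputError("count must be >= 1")
        if self.repetition_frequency <= 0:
            raise InvalidInputError("repetition_frequency must be > 0")
        if self.droop_tau <= 0:
            raise InvalidInputError("droop_tau must be > 0")
        if self.polarity not in (-1, +1):
            raise InvalidInputError("polarity must be +1 or -1")
        if not 0.0 <= abs(self.amplitude) <= 40.0:
            warnings.warn(
                f"amplitude {self.amplitude} V outside the 0-40 V range the "
                "device is characterised for",
                UserWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class PulseTrace:
    """Sampled voltage/current recording of a pulse train."""

    time: np.ndarray
    voltage: np.ndarray
    current: np.ndarray
    seed: int
    spec: PulseSpec | None = None

    def __post_init__(self) -> None:
        if not (len(self.time) == len(self.voltage) == len(self.current)):
            raise InvalidInputError("trace arrays must have equal length")


def generate_trace(
    spec: PulseSpec,
    true_resistance: float,
    noise_level: float = 0.0,
    seed: int = 0,
    sample_rate: float = 1e5,
) -> PulseTrace:
    """Synthesize an oscilloscope recording of a pulse train across a
    resistive load.

    Voltage is ``amplitude * exp(-t'/tau)`` inside each pulse (t' from
    that pulse's start) and zero outside; current is voltage divided by
    ``true_resistance``; both channels get independent multiplicative
    gaussian noise of relative standard deviation ``noise_level``.
    Bitwise reproducible for a given ``(spec, resistance, noise, seed)``.
    """
    if true_resistance <= 0:
        raise InvalidInputError("true_resistance must be > 0")
    if noise_level < 0:
        raise InvalidInputError("noise_level must be >= 0")
    period = 1.0 / spec.repetition_frequency
    total = (spec.count - 1) * period + spec.duration * 1.5 + 2e-3
    t = np.arange(0.0, total, 1.0 / sample_rate)
    v = np.zeros_like(t)
    for k in range(spec.count):
        t0 = k * period
        inside = (t >= t0) & (t < t0 + spec.duration)
        v[inside] = (
            spec.polarity
            * spec.amplitude
            * np.exp(-(t[inside] - t0) / spec.droop_tau)
        )
    i = v / true_resistance
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        v = v * (1.0 + noise_level * rng.standard_normal(len(t)))
        i = i * (1.0 + noise_level * rng.standard_normal(len(t)))
    return PulseTrace(time=t, voltage=v, current=i, seed=seed, spec=spec)


def resistance_from_trace(trace: PulseTrace, method: str = "window") -> float:
    """Estimate the load resistance from a recorded trace (Ω).

    ``window`` (default) fits the least-squares slope of V against I
    over all in-pulse samples, which is unbiased on noiseless traces and
    robust to droop; ``peak`` divides the peak voltage by the
    corresponding current sample, matching the convention of reporting
    the peak applied voltage as the pulse amplitude.
    """
    v, i = trace.voltage, trace.current
    if not np.any(v != 0):
        raise InvalidInputError("no identifiable pulse window in the trace")
    mask = np.abs(v) > 0.05 * np.max(np.abs(v))
    if not np.any(np.abs(i[mask]) > 0):
        raise InvalidInputError("trace carries no current; resistance undefined")
    if method == "peak":
        k = int(np.argmax(np.abs(v)))
        if i[k] == 0:
            raise InvalidInputError("zero current at the voltage peak")
        return float(v[k] / i[k])
    if method != "window":
        raise InvalidInputError(f"unknown method {method!r}")
    vv, ii = v[mask], i[mask]
    denom = float(np.dot(ii, ii))
    if denom == 0.0:
        raise InvalidInputError("trace carries no current; resistance undefined")
    return float(np.dot(vv, ii) / denom)


def trace_to_csv(trace: PulseTrace, path) -> None:
    """Write a trace as three-column CSV (time_s, voltage_V, current_A)."""
    pd.DataFrame(
        {"time_s": trace.time, "voltage_V": trace.voltage, "current_A": trace.current}
    ).to_csv(path, index=False)


def trace_from_csv(path, seed: int = -1) -> PulseTrace:
    df = pd.read_csv(path)
    return PulseTrace(
        time=df["time_s"].to_numpy(),
        voltage=df["voltage_V"].to_numpy(),
        current=df["current_A"].to_numpy(),
        seed=seed,
    )
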