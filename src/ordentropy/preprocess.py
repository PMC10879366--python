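"""Causal band-limiting and resampling: 250 Hz -> 200 Hz via 1000 Hz.

Online monitoring forbids looking into the future, so the usual
zero-phase (forward-backward) filtering is off the table.  Instead the
chain is strictly causal but phase-coherent:

1. upsample 250 Hz -> 1000 Hz by zero-stuffing (insert 3 zeros between
   samples, gain-compensated by 4x inside the filter),
2. apply an order-1000 linear-phase FIR low-pass at 30 Hz
   (band-limiting and anti-aliasing in one step),
3. keep every fifth filtered sample -> 200 Hz.

A symmetric (type-I) FIR of order 1000 has a group delay of exactly 500
samples at 1000 Hz: every frequency is delayed by the same 500 ms, so
relative timing between channels is preserved (no phase distortion) at
the cost of a known, constant latency.  The first second of output
contains the filter's settling transient; downstream windows must not
start inside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import DataError, EegRecording

FS_IN = 250.0
FS_INTERNAL = 1000.0
FS_OUT = 200.0
UP = 4   # 250 -> 1000
DOWN = 5  # 1000 -> 200
SETTLE_S = 1.0  # output flagged as transient before this time


class FilterDesignError(ValueError):
    """Raised when a designed filter misses its pass/stopband contract."""


@dataclass
class FilterSpec:
    """A linear-phase FIR low-pass for the 1000 Hz internal rate."""

    order: int
    fs_internal: float
    cutoff_hz: float
    coefficients: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        h = np.asarray(self.coefficients, dtype=float)
        if h.size != self.order + 1:
            raise FilterDesignError(
                f"expected {self.order + 1} coefficients, got {h.size}"
            )
        if not np.allclose(h, h[::-1], rtol=0, atol=1e-12):
            raise FilterDesignError("coefficients not symmetric (not linear phase)")
        if abs(h.sum() - 1.0) > 1e-6:
            raise FilterDesignError(f"DC gain {h.sum():.8f} differs from 1")
        self.coefficients = h

    @property
    def group_delay_samples(self) -> float:
        """Group delay at the internal rate, in samples (order/2)."""
        return self.order / 2.0

    @property
    def group_delay_s(self) -> float:
        return self.group_delay_samples / self.fs_internal

    def gain_at(self, freqs_hz) -> np.ndarray:
        """Magnitude response at the given frequencies (linear gain)."""
        _, h = sps.freqz(self.coefficients, worN=np.atleast_1d(freqs_hz),
                         fs=self.fs_internal)
        return np.abs(h)


def design_lowpass_fir(
    order: int = 1000,
    fs_internal: float = FS_INTERNAL,
    cutoff_hz: float = 30.0,
) -> FilterSpec:
    """Design the symmetric windowed-sinc (Hamming) low-pass FIR.

    The contract checked here: passband ripple within -1 dB up to
    0.9 * cutoff, and at least 40 dB attenuation over [100, 500] Hz — the
    band that would alias into the 200 Hz output after decimation.
    """
    if order % 2 != 0 or order < 2:
        raise FilterDesignError(f"order must be even and >= 2, got {order}")
    if not 0 < cutoff_hz < fs_internal / 2:
        raise FilterDesignError(
            f"cutoff {cutoff_hz} Hz outside (0, {fs_internal / 2}) Hz"
        )
    h = sps.firwin(order + 1, cutoff_hz, window="hamming", fs=fs_internal)
    spec = FilterSpec(order=order, fs_internal=fs_internal,
                      cutoff_hz=cutoff_hz, coefficients=h)
    pass_freqs = np.linspace(0, cutoff_hz * 0.9, 64)
    pass_gain = spec.gain_at(pass_freqs)
    if pass_gain.min() < 10 ** (-1 / 20):
        raise FilterDesignError(
            f"passband droop {20 * np.log10(pass_gain.min()):.2f} dB "
            f"exceeds -1 dB below {cutoff_hz * 0.9:.1f} Hz"
        )
    stop_freqs = np.linspace(100.0, fs_internal / 2, 256)
    stop_gain = spec.gain_at(stop_freqs)
    atten_db = -20 * np.log10(stop_gain.max())
    if atten_db < 40.0:
        raise FilterDesignError(
            f"stopband attenuation only {atten_db:.1f} dB (< 40 dB) "
            f"over [100, {fs_internal / 2:.0f}] Hz"
        )
    return spec


def causal_resample(signal: np.ndarray, spec: FilterSpec | None = None) -> np.ndarray:
    """Resample one channel 250 Hz -> 200 Hz through the causal chain.

    Output sample k is the filtered value at internal index 5k; it depends
    only on input samples at times <= k / 200 s and represents the input
    500 ms earlier.  Output length is floor(4 N / 5) for N input samples.
    """
    if spec is None:
        spec = design_lowpass_fir()
    x = np.asarray(signal, dtype=float).ravel()
    if x.size < 1:
        raise DataError("empty input signal")
    bad = ~np.isfinite(x)
    if bad.any():
        raise DataError(f"non-finite sample at index {int(np.argmax(bad))}")
    # upfirdn = zero-stuff by 4, FIR filter, keep internal indices = 0 mod 5;
    # the 4x gain compensates the power lost to the stuffed zeros.
    y = sps.upfirdn(UP * spec.coefficients, x, up=UP, down=DOWN)
    out_len = (UP * x.size) // DOWN
    return y[:out_len]


def preprocess_recording(rec: EegRecording, spec: FilterSpec | None = None) -> EegRecording:
    """Band-limit and resample all channels of a 250 Hz recording to 200 Hz.

    Channels are processed independently with the identical filter.  Output
    timestamps follow the causal convention: output sample k carries the
    time of the newest input sample it can depend on
    (``start_time_s + k / 200``); its content lags that time by 500 ms.
    The returned recording is flagged settled from ``start_time_s + 1 s``.
    """
    if rec.fs != FS_IN:
        raise DataError(
            f"preprocessing expects {FS_IN:.0f} Hz input, got {rec.fs} Hz "
            "(no silent rate inference)"
        )
    if spec is None:
        spec = design_lowpass_fir()
    out = np.stack([causal_resample(ch, spec) for ch in rec.samples])
    return EegRecording(
        channel_labels=list(rec.channel_labels),
        fs=FS_OUT,
        samples=out,
        start_time_s=rec.start_time_s,
        settled_from_s=rec.start_time_s + SETTLE_S,
    )
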