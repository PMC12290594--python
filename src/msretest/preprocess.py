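"""Standard EEG cleaning steps applied before artifact-subspace removal.

The pipeline for scanner EEG is: Butterworth band edges (0.5 Hz high-pass,
125 Hz low-pass, 2nd order, applied forward-backward), average-artifact
subtraction of the gradient artifact using volume triggers, carbon-wire-loop
regression of motion artifacts, resampling, a 2-20 Hz zero-phase FIR
band-pass, rejection of segments with excessive 15-30 Hz power, common
average re-referencing and noisy-channel interpolation.  All operations
return a new :class:`~msretest.core.Recording` and append one provenance
entry.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .core import EventSelection, Recording


class ParameterError(ValueError):
    pass


@dataclass
class SegmentMask:
    """Half-open ``[start, stop)`` sample intervals flagged as rejected."""

    intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        prev_stop = -1
        for start, stop in self.intervals:
            if start >= stop:
                raise ParameterError(f"empty interval ({start}, {stop})")
            if start < prev_stop:
                raise ParameterError("intervals must be sorted and disjoint")
            prev_stop = stop

    def total_samples(self) -> int:
        return sum(stop - start for start, stop in self.intervals)


# ---------------------------------------------------------------------
# filters & resampling
# ---------------------------------------------------------------------

def butter_filter(rec: Recording, low: float | None, high: float | None,
                  order: int = 2, bidirectional: bool = True) -> Recording:
    """Butterworth IIR filter, zero-phase when ``bidirectional``.

    ``low``/``high`` are the band edges in Hz; pass one of them as None
    for a pure low-/high-pass.  Bidirectional application squares the
    magnitude response (and doubles the effective order), which is the
    convention assumed throughout the pipeline defaults.
    """
    nyq = rec.rate / 2
    for f in (low, high):
        if f is not None and not (0 < f < nyq):
            raise ParameterError(f"cutoff {f} Hz outside (0, {nyq}) Hz")
    if low is None and high is None:
        raise ParameterError("need at least one cutoff")
    if low is not None and high is not None:
        if low >= high:
            raise ParameterError("low cutoff must be below high cutoff")
        sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.rate, output="sos")
        desc = f"butter bandpass {low}-{high} Hz order {order}"
    elif low is not None:
        sos = signal.butter(order, low, btype="highpass", fs=rec.rate, output="sos")
        desc = f"butter highpass {low} Hz order {order}"
    else:
        sos = signal.butter(order, high, btype="lowpass", fs=rec.rate, output="sos")
        desc = f"butter lowpass {high} Hz order {order}"
    if bidirectional:
        out = signal.sosfiltfilt(sos, rec.data, axis=1)
        desc += " bidirectional"
    else:
        out = signal.sosfilt(sos, rec.data, axis=1)
    return rec.with_data(out, desc)


def fir_bandpass(rec: Recording, low: float = 2.0, high: float = 20.0,
                 order: int = 2000, window: str = "hamming") -> Recording:
    """Zero-phase windowed-sinc FIR band-pass (linear phase, delay
    compensated by symmetric convolution)."""
    nyq = rec.rate / 2
    if not (0 < low < high < nyq):
        raise ParameterError(f"band ({low}, {high}) outside (0, {nyq}) Hz")
    if rec.n_samples < order + 1:
        raise ParameterError(
            f"signal of {rec.n_samples} samples shorter than {order + 1} filter taps")
    ntaps = order + 1 if (order + 1) % 2 == 1 else order + 1  # firwin needs odd for bandpass
    if ntaps % 2 == 0:
        ntaps += 1
    taps = signal.firwin(ntaps, [low, high], pass_zero=False, window=window, fs=rec.rate)
    half = ntaps // 2
    padded = np.pad(rec.data, ((0, 0), (half, half)), mode="reflect")
    out = signal.fftconvolve(padded, taps[None, :], mode="valid", axes=1)
    return rec.with_data(out, f"fir bandpass {low}-{high} Hz order {order} {window}")


def resample(rec: Recording, target_rate: float) -> Recording:
    """Anti-aliased rational resampling; event indices rescaled."""
    if target_rate <= 0:
        raise ParameterError("target rate must be positive")
    if abs(target_rate - rec.rate) < 1e-12:
        return rec.with_data(rec.data, f"resample {target_rate} Hz (identity)")
    frac = Fraction(target_rate / rec.rate).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(rec.data, up, down, axis=1)
    n_target = int(round(rec.n_samples * target_rate / rec.rate))
    if out.shape[1] > n_target:
        out = out[:, :n_target]
    elif out.shape[1] < n_target:
        out = np.pad(out, ((0, 0), (0, n_target - out.shape[1])), mode="edge")
    ratio = target_rate / rec.rate
    events = [(min(int(round(s * ratio)), n_target - 1), lab) for s, lab in rec.events]
    return rec.with_data(out, f"resample {rec.rate} -> {target_rate} Hz",
                         events=events, rate=target_rate)


# ---------------------------------------------------------------------
# gradient artifact: average artifact subtraction
# ---------------------------------------------------------------------

def aas_correct(rec: Recording, volume_triggers: EventSelection,
                n_avg: int = 15, channels: np.ndarray | None = None) -> Recording:
    """Average-artifact subtraction of a periodic (gradient-like) artifact.

    For each trigger epoch the template is the mean of the ``n_avg``
    nearest epochs (centered sliding window, truncated at the edges of
    the record, current epoch included) and is subtracted in place.
    Trigger spacing must be periodic to within +/-1 sample.
    """
    trig = volume_triggers.indices
    if len(trig) == 0:
        raise ParameterError("zero volume triggers")
    if len(trig) < n_avg:
        raise ParameterError(f"{len(trig)} triggers < n_avg = {n_avg}")
    intervals = np.diff(trig)
    period = int(round(np.median(intervals)))
    bad = np.where(np.abs(intervals - period) > 1)[0]
    if len(bad):
        i = bad[0]
        raise ParameterError(
            f"irregular trigger spacing: interval {i} is {intervals[i]} samples, "
            f"expected {period} +/- 1")
    if channels is None:
        channels = np.arange(rec.n_channels)

    # epochs of one period each, anchored at the triggers
    usable = [t for t in trig if t + period <= rec.n_samples]
    E = len(usable)
    epochs = np.stack([rec.data[np.ix_(channels, np.arange(t, t + period))]
                       for t in usable], axis=0)   # E x ch x period
    csum = np.cumsum(epochs, axis=0)
    out = rec.data.copy()
    half = n_avg // 2
    for k, t in enumerate(usable):
        a = max(0, k - half)
        b = min(E, a + n_avg)
        a = max(0, b - n_avg)
        template = (csum[b - 1] - (csum[a - 1] if a > 0 else 0)) / (b - a)
        out[np.ix_(channels, np.arange(t, t + period))] -= template
    return rec.with_data(out, f"aas n_avg={n_avg} over {E} epochs")


# ---------------------------------------------------------------------
# carbon-wire-loop regression
# ---------------------------------------------------------------------

def cwl_regress(rec: Recording, max_lag_s: float = 0.1,
                window_s: float | None = None) -> Recording:
    """Remove the least-squares projection of each EEG channel onto
    time-lag-embedded carbon-wire-loop channels.

    Lags span ``-max_lag_s ... +max_lag_s``.  With ``window_s`` None the
    regression is a single global fit; otherwise it is refit in
    non-overlapping windows.  CWL channels are dropped from the output.
    """
    cwl_idx = rec.channel_indices("cwl")
    if len(cwl_idx) == 0:
        raise ParameterError("recording has no CWL channels")
    lag = int(round(max_lag_s * rec.rate))
    cwl = rec.data[cwl_idx]
    n = rec.n_samples
    # design matrix: lag-embedded CWL channels
    cols = []
    for ch in cwl:
        for d in range(-lag, lag + 1):
            cols.append(np.roll(ch, d))
    X = np.array(cols).T    # n x (n_cwl * (2 lag + 1))

    keep = [i for i in range(rec.n_channels) if i not in set(cwl_idx.tolist())]
    out = rec.data[keep].copy()
    eeg_rows = [r for r, i in enumerate(keep) if rec.ch_types[i] == "eeg"]

    def _clean(sl: slice) -> None:
        Xw = X[sl]
        Y = out[eeg_rows][:, sl].T
        beta, *_ = np.linalg.lstsq(Xw, Y, rcond=None)
        resid = Y - Xw @ beta
        for j, r in enumerate(eeg_rows):
            out[r, sl] = resid[:, j]

    if window_s is None:
        _clean(slice(0, n))
    else:
        w = int(round(window_s * rec.rate))
        for start in range(0, n, w):
            _clean(slice(start, min(start + w, n)))

    return rec.with_data(
        out, f"cwl regression max_lag={max_lag_s}s window={window_s}",
        ch_names=[rec.ch_names[i] for i in keep],
        ch_types=[rec.ch_types[i] for i in keep],
        positions=None if rec.positions is None else rec.positions[keep],
    )


# ---------------------------------------------------------------------
# spectral segment rejection
# ---------------------------------------------------------------------

def reject_spectral_segments(rec: Recording, band: tuple[float, float] = (15.0, 30.0),
                             window_s: float = 1.0, step_s: float = 0.25,
                             threshold_factor: float = 8.0,
                             ) -> tuple[Recording, SegmentMask]:
    """Excise stretches whose band power exceeds ``threshold_factor`` times
    the median windowed band power.

    Band power is computed in sliding windows over the mean across EEG
    channels' periodograms; flagged windows are merged into intervals,
    the intervals are cut out, the remainder concatenated.  Events inside
    excised spans are dropped; later events shift left.
    """
    nyq = rec.rate / 2
    if not (0 < band[0] < band[1] < nyq):
        raise ParameterError(f"band {band} outside (0, {nyq}) Hz")
    w = int(round(window_s * rec.rate))
    step = max(1, int(round(step_s * rec.rate)))
    n = rec.n_samples
    if w > n:
        raise ParameterError("window longer than recording")
    starts = np.arange(0, n - w + 1, step)
    eeg = rec.eeg_data()
    freqs = np.fft.rfftfreq(w, 1 / rec.rate)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    powers = np.empty(len(starts))
    for i, s in enumerate(starts):
        spec = np.abs(np.fft.rfft(eeg[:, s:s + w], axis=1)) ** 2
        powers[i] = spec[:, sel].mean()
    med = np.median(powers)
    flagged = powers > threshold_factor * med   # strict: all-zero stays clean

    intervals: list[tuple[int, int]] = []
    for i, f in enumerate(flagged):
        if not f:
            continue
        a, b = int(starts[i]), int(starts[i] + w)
        if intervals and a <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], b))
        else:
            intervals.append((a, b))
    mask = SegmentMask(intervals=intervals)

    if mask.total_samples() >= n:
        raise ParameterError("no data survives rejection")
    if not intervals:
        return rec.with_data(rec.data, "spectral rejection: nothing flagged"), mask

    keep = np.ones(n, dtype=bool)
    for a, b in intervals:
        keep[a:b] = False
    new_index = np.cumsum(keep) - 1
    events = []
    dropped = 0
    for s, lab in rec.events:
        if keep[s]:
            events.append((int(new_index[s]), lab))
        else:
            dropped += 1
    out = rec.data[:, keep]
    return rec.with_data(
        out,
        f"spectral rejection {band[0]}-{band[1]} Hz: removed "
        f"{mask.total_samples()} samples in {len(intervals)} intervals, "
        f"dropped {dropped} events",
        events=events,
    ), mask


# ---------------------------------------------------------------------
# referencing & bad channels
# ---------------------------------------------------------------------

def rereference_average(rec: Recording) -> Recording:
    """Common average reference over EEG channels (others untouched)."""
    eeg = rec.eeg_indices
    if len(eeg) < 2:
        raise ParameterError("need at least 2 EEG channels")
    out = rec.data.copy()
    out[eeg] -= out[eeg].mean(axis=0, keepdims=True)
    return rec.with_data(out, "common average reference")


def bad_channels(rec: Recording, correlation_threshold: float = 0.4,
                 flat_threshold_uv: float = 1e-3,
                 ) -> tuple[Recording, list[str]]:
    """Flag EEG channels that are flat or decorrelated from every other
    channel, and replace them by an inverse-distance-weighted average of
    the 4 nearest good channels (sensor positions required)."""
    if rec.positions is None:
        raise ParameterError("sensor positions required for interpolation")
    eeg = rec.eeg_indices
    X = rec.data[eeg]
    sd = X.std(axis=1)
    flat = sd < flat_threshold_uv
    with np.errstate(invalid="ignore"):
        C = np.corrcoef(X)
    np.fill_diagonal(C, np.nan)
    maxcorr = np.nanmax(np.abs(np.nan_to_num(C, nan=0.0)), axis=1)
    bad = flat | (maxcorr < correlation_threshold)
    if bad.sum() > 0.5 * len(eeg):
        raise ParameterError("recording unusable: more than half the EEG channels flagged")
    out = rec.data.copy()
    labels = []
    good = eeg[~bad]
    for row, ch in zip(np.where(bad)[0], eeg[bad]):
        d = np.linalg.norm(rec.positions[good] - rec.positions[ch], axis=1)
        nearest = good[np.argsort(d)[:4]]
        wts = 1.0 / np.maximum(np.sort(d)[:4], 1e-6)
        wts /= wts.sum()
        out[ch] = wts @ rec.data[nearest]
        labels.append(rec.ch_names[ch])
    return rec.with_data(out, f"bad channels interpolated: {labels}"), labels
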