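"""Induced time-frequency power and the regulation-associated theta summary.

Induced (non-phase-locked) activity is isolated by subtracting each
condition's trial-averaged evoked potential from its single trials.
Time-frequency power then uses a sliding 2-s Hanning window stepped
every 50 ms, for frequencies 1-30 Hz in 0.5-Hz steps; power is averaged
over trials within a condition, baseline-corrected by subtraction
(baseline 1.2-0.2 s before picture onset), and the reappraisal-minus-
maintenance contrast is summarised per channel over the theta band
(3.5-8.5 Hz) and regulation window (1-5 s).

Spectral convention: the Hanning taper is normalised to unit energy
(sum of squared taper = 1), so for a sinusoid of amplitude A at an
on-grid frequency the plateau power is A^2 * (sum w)^2 / 4 with w the
unit-energy taper -- equal to A^2 * N / 6 for a length-N periodic
Hanning window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .containers import (
    BASELINE_WINDOW,
    CONDITIONS,
    REGULATION_WINDOW,
    THETA_BAND,
    DataError,
    EpochedRecording,
)

__all__ = [
    "TFR",
    "ThetaSummary",
    "subtract_erp",
    "tfr_hanning",
    "baseline_subtract",
    "regulation_contrast",
    "theta_summary",
    "hanning_plateau_power",
]

DEFAULT_FREQS = np.arange(1.0, 30.0 + 1e-9, 0.5)


@dataclass
class TFR:
    """Time-frequency representation: ``power`` is (channels, freqs, times)."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channel_labels: list[str]
    baseline_state: str = "raw"     # "raw" | "subtracted"
    label: str = ""

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, float)
        self.freqs = np.asarray(self.freqs, float)
        self.times = np.asarray(self.times, float)
        if self.power.shape != (len(self.channel_labels), len(self.freqs),
                                len(self.times)):
            raise DataError("power shape does not match axes")

    def matches(self, other: "TFR") -> bool:
        return (np.array_equal(self.freqs, other.freqs)
                and np.array_equal(self.times, other.times)
                and self.channel_labels == other.channel_labels)


@dataclass
class ThetaSummary:
    """Per-channel mean baseline-subtracted power over the theta band and
    regulation window (µV²-scaled units)."""

    values: np.ndarray
    channel_labels: list[str]
    label: str = ""
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if not np.isfinite(self.values).all():
            raise DataError("non-finite theta summary")
        if len(self.values) != len(self.channel_labels):
            raise DataError("one value per channel required")


def subtract_erp(epochs: EpochedRecording) -> EpochedRecording:
    """Remove each condition's trial-averaged evoked potential."""
    out = epochs.data.copy()
    for cond in CONDITIONS:
        mask = epochs.condition == cond
        n = int(mask.sum())
        if n == 0:
            continue
        if n < 2:
            raise DataError(
                f"condition {cond!r} has {n} trial(s); need >= 2 to estimate "
                "the evoked potential")
        erp = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
        out[:, :, mask] -= erp
    prov = epochs.provenance.copy()
    prov.erp_subtracted = True
    return epochs.copy_with(data=out, provenance=prov)


def hanning_plateau_power(amplitude: float, n_window: int) -> float:
    """Analytic plateau power of an on-grid tone under the unit-energy
    Hanning convention."""
    w = sps.get_window("hann", n_window)
    w = w / np.sqrt(np.sum(w**2))
    return (amplitude * np.sum(w) / 2) ** 2


def tfr_hanning(
    epochs: EpochedRecording,
    window_s: float = 2.0,
    slide_s: float = 0.05,
    freqs: np.ndarray = DEFAULT_FREQS,
    by_condition: bool = True,
    time_windows: list | None = None,
) -> dict:
    """Sliding-Hanning-window power, averaged over trials per condition.

    Output time is the window centre (window [t-1, t+1] s for output
    time t); times where the window would exceed the epoch are NaN.
    ``time_windows`` optionally restricts computation to output times
    inside the given (lo, hi) intervals (others are NaN), which speeds
    up summary-only analyses.  Returns ``{condition: TFR}`` (or
    ``{"all": TFR}``).
    """
    sfreq = epochs.sfreq
    freqs = np.asarray(freqs, float)
    if freqs.max() > sfreq / 2:
        raise DataError(
            f"requested frequency {freqs.max()} Hz above Nyquist ({sfreq / 2} Hz)")
    n_win = int(round(window_s * sfreq))
    hop = max(1, int(round(slide_s * sfreq)))
    n_time = epochs.data.shape[1]
    if n_win > n_time:
        raise DataError("epoch shorter than one analysis window")

    w = sps.get_window("hann", n_win)
    w = w / np.sqrt(np.sum(w**2))
    fft_freqs = np.fft.rfftfreq(n_win, 1 / sfreq)
    bin_idx = np.array([int(np.argmin(np.abs(fft_freqs - f))) for f in freqs])
    if np.max(np.abs(fft_freqs[bin_idx] - freqs)) > 1e-6:
        raise DataError(
            "requested frequencies are off the FFT grid for a "
            f"{window_s}-s window at {sfreq} Hz")

    # all window centres on the hop grid, NaN where incomplete
    centres = np.arange(0, n_time, hop)
    starts = centres - n_win // 2
    valid = (starts >= 0) & (starts + n_win <= n_time)
    times = epochs.time_axis[centres]
    if time_windows is not None:
        wanted = np.zeros_like(valid)
        for lo_w, hi_w in time_windows:
            wanted |= (times >= lo_w - 1e-9) & (times <= hi_w + 1e-9)
        valid &= wanted

    groups = ({c: epochs.condition == c for c in CONDITIONS
               if (epochs.condition == c).any()}
              if by_condition else {"all": np.ones(epochs.n_trials, bool)})

    n_ch = epochs.n_channels
    sums = {c: np.zeros((n_ch, len(freqs), len(centres))) for c in groups}
    counts = {c: 0 for c in groups}
    vstarts = starts[valid]
    idx = vstarts[:, None] + np.arange(n_win)[None, :]
    for k in range(epochs.n_trials):
        x = epochs.data[:, :, k]
        seg = x[:, idx] * w  # (ch, n_valid_windows, n_win)
        spec = np.fft.rfft(seg, axis=2)[:, :, bin_idx]
        pw = np.abs(spec) ** 2  # (ch, n_win_valid, n_freqs)
        for c, mask in groups.items():
            if mask[k]:
                sums[c][:, :, valid] += pw.transpose(0, 2, 1)
                counts[c] += 1

    out = {}
    for c in groups:
        power = sums[c] / max(counts[c], 1)
        power[:, :, ~valid] = np.nan
        out[c] = TFR(power, freqs, times, list(epochs.channel_labels),
                     baseline_state="raw", label=c)
    return out


def baseline_subtract(tfr: TFR, window: tuple[float, float] = BASELINE_WINDOW) -> TFR:
    """Subtract the mean baseline-window power per channel and frequency."""
    lo, hi = window
    mask = (tfr.times >= lo - 1e-9) & (tfr.times <= hi + 1e-9)
    if not mask.any() or np.isnan(tfr.power[:, :, mask]).any():
        raise DataError(
            f"baseline window [{lo}, {hi}] s not covered by valid TFR times")
    base = tfr.power[:, :, mask].mean(axis=2, keepdims=True)
    return TFR(tfr.power - base, tfr.freqs, tfr.times, tfr.channel_labels,
               baseline_state="subtracted", label=tfr.label)


def regulation_contrast(tfr_reappraise: TFR, tfr_maintain: TFR) -> TFR:
    """Element-wise reappraisal-minus-maintenance difference."""
    if not tfr_reappraise.matches(tfr_maintain):
        raise DataError("TFR axes do not match")
    return TFR(
        tfr_reappraise.power - tfr_maintain.power,
        tfr_reappraise.freqs, tfr_reappraise.times,
        tfr_reappraise.channel_labels,
        baseline_state=tfr_reappraise.baseline_state,
        label="reappraisal-maintenance",
    )


def theta_summary(
    contrast_tfr: TFR,
    band: tuple[float, float] = THETA_BAND,
    window: tuple[float, float] = REGULATION_WINDOW,
    participant_id: str = "",
) -> ThetaSummary:
    """Mean power over the theta band × regulation window, per channel."""
    fmask = (contrast_tfr.freqs >= band[0] - 1e-9) & \
            (contrast_tfr.freqs <= band[1] + 1e-9)
    tmask = (contrast_tfr.times >= window[0] - 1e-9) & \
            (contrast_tfr.times <= window[1] + 1e-9)
    if not fmask.any() or not tmask.any():
        raise DataError("theta band / regulation window not covered")
    box = contrast_tfr.power[:, fmask][:, :, tmask]
    if np.isnan(box).any():
        raise DataError("NaN inside the theta summary box")
    return ThetaSummary(box.mean(axis=(1, 2)), contrast_tfr.channel_labels,
                        label=contrast_tfr.label, participant_id=participant_id)


def participant_theta_summary(epochs: EpochedRecording,
                              participant_id: str = "",
                              fast: bool = False) -> ThetaSummary:
    """Convenience chain: ERP subtraction → TFR → baseline → contrast → summary.

    ``fast=True`` computes TFR times only inside the baseline and
    regulation windows.
    """
    induced = subtract_erp(epochs)
    windows = [BASELINE_WINDOW, REGULATION_WINDOW] if fast else None
    tfrs = tfr_hanning(induced, time_windows=windows)
    for cond in ("reappraise", "maintain"):
        if cond not in tfrs:
            raise DataError(f"condition {cond!r} absent; cannot form contrast")
    contrast = regulation_contrast(
        baseline_subtract(tfrs["reappraise"]),
        baseline_subtract(tfrs["maintain"]),
    )
    return theta_summary(contrast, participant_id=participant_id)
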