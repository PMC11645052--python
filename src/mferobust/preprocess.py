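"""Filtering, epoching and the amplitude transformation (AT).

The preprocessing protocol: band-pass 0.5-45 Hz with a linear-phase FIR
filter whose order equals the number of samples in one 3 s window (600 at
200 Hz), applied causally; the first 3 s (the filter transient) are cut;
the remainder is split into non-overlapping 3 s epochs (16 per subject for
a 51 s recording).

The AT maps each subject's epochs into a common amplitude range [-5, 5]
with a single affine map per subject: per-epoch global extrema (pooled over
all channels) are reduced to one x_min / x_max by taking medians across
epochs, and every sample is mapped by

    x_AT = (x - x_min) / (x_max - x_min) * (A_max - A_min) + A_min.

Using one map for all channels preserves inter-channel amplitude ratios;
samples outside [x_min, x_max] (possible, since the bounds are medians of
epoch extrema) follow the same affine rule and are NOT clipped. The map is
exactly invariant to a positive rescaling of the whole recording once the
bounds are recomputed — the property that removes acquisition-gain
differences between subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import signal

from .cohort import Group, Recording

__all__ = [
    "FilterKernel",
    "AmplitudeState",
    "EpochedRecording",
    "ATBounds",
    "design_bandpass_fir",
    "bandpass_filter_and_trim",
    "epoch_signal",
    "compute_at_bounds",
    "amplitude_transform",
]


class AmplitudeState(str, Enum):
    RAW = "raw"
    TRANSFORMED = "transformed"


@dataclass(frozen=True)
class FilterKernel:
    """Linear-phase FIR band-pass kernel."""

    taps: np.ndarray
    fs: float
    band: tuple[float, float]

    def __post_init__(self) -> None:
        taps = np.asarray(self.taps, dtype=float)
        object.__setattr__(self, "taps", taps)
        if not np.allclose(taps, taps[::-1]):
            raise ValueError("taps must be symmetric (linear phase)")

    @property
    def order(self) -> int:
        return len(self.taps) - 1


def design_bandpass_fir(fs: float, band: tuple[float, float] = (0.5, 45.0),
                        window_seconds: float = 3.0,
                        window: str = "hamming") -> FilterKernel:
    """Windowed-sinc band-pass FIR, order = samples in one ``window_seconds`` window."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    low, high = band
    if not 0 < low < high < fs / 2:
        raise ValueError(f"band {band} invalid for fs={fs}")
    order = int(round(window_seconds * fs))  # 600 at 200 Hz
    numtaps = order + 1  # odd taps -> type-I linear phase
    taps = signal.firwin(numtaps, [low, high], pass_zero=False, fs=fs, window=window)
    return FilterKernel(taps=taps, fs=fs, band=(low, high))


def bandpass_filter_and_trim(rec: Recording, kernel: FilterKernel,
                             trim: float = 3.0) -> Recording:
    """Causal FIR filtering followed by removal of the first ``trim`` seconds.

    A single forward pass (``lfilter``) is used, not zero-phase filtering:
    the causal transient is what the trim removes.
    """
    if rec.fs != kernel.fs:
        raise ValueError(f"recording fs {rec.fs} != kernel fs {kernel.fs}")
    if rec.duration <= trim:
        raise ValueError(f"duration {rec.duration}s must exceed trim {trim}s")
    filtered = signal.lfilter(kernel.taps, 1.0, rec.data, axis=1)
    n_trim = int(round(trim * rec.fs))
    return Recording(subject_id=rec.subject_id, group=rec.group,
                     data=filtered[:, n_trim:], fs=rec.fs,
                     channel_names=rec.channel_names,
                     subject_gain=rec.subject_gain)


@dataclass
class EpochedRecording:
    """Per-subject epochs: channels x n_epochs x samples_per_epoch."""

    subject_id: str
    group: Group
    epochs: np.ndarray
    fs: float
    amplitude_state: AmplitudeState = AmplitudeState.RAW

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be channels x n_epochs x samples")

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[1]

    @property
    def samples_per_epoch(self) -> int:
        return self.epochs.shape[2]


def epoch_signal(rec: Recording, epoch_len: float = 3.0) -> EpochedRecording:
    """Cut into consecutive non-overlapping epochs; trailing remainder dropped."""
    if epoch_len <= 0:
        raise ValueError("epoch_len must be positive")
    spe = int(round(epoch_len * rec.fs))
    n_epochs = rec.n_samples // spe
    if n_epochs < 1:
        raise ValueError(
            f"recording of {rec.n_samples} samples shorter than one "
            f"{spe}-sample epoch")
    usable = rec.data[:, : n_epochs * spe]
    epochs = usable.reshape(rec.n_channels, n_epochs, spe)
    return EpochedRecording(subject_id=rec.subject_id, group=rec.group,
                            epochs=epochs, fs=rec.fs,
                            amplitude_state=AmplitudeState.RAW)


@dataclass(frozen=True)
class ATBounds:
    """Per-subject affine map parameters for the amplitude transformation."""

    x_min: float
    x_max: float
    a_min: float = -5.0
    a_max: float = 5.0

    def __post_init__(self) -> None:
        if not self.x_max > self.x_min:
            raise ValueError("x_max must exceed x_min")
        if not self.a_max > self.a_min:
            raise ValueError("A_max must exceed A_min")


def compute_at_bounds(ep: EpochedRecording, a_min: float = -5.0,
                      a_max: float = 5.0) -> ATBounds:
    """Medians across epochs of the per-epoch global (all-channel) extrema."""
    if ep.amplitude_state is not AmplitudeState.RAW:
        raise ValueError("AT bounds are computed on raw epochs")
    # pooled over channels within each epoch ("all channels simultaneously")
    epoch_max = ep.epochs.max(axis=(0, 2))
    epoch_min = ep.epochs.min(axis=(0, 2))
    x_max = float(np.median(epoch_max))
    x_min = float(np.median(epoch_min))
    if x_max == x_min:
        raise ValueError("degenerate amplitude: x_max equals x_min")
    return ATBounds(x_min=x_min, x_max=x_max, a_min=a_min, a_max=a_max)


def amplitude_transform(ep: EpochedRecording, bounds: ATBounds) -> EpochedRecording:
    """Apply the per-subject affine map to every channel, epoch and sample."""
    if ep.amplitude_state is not AmplitudeState.RAW:
        raise ValueError("recording already amplitude-transformed")
    span = bounds.x_max - bounds.x_min
    out_span = bounds.a_max - bounds.a_min
    data = (ep.epochs - bounds.x_min) / span * out_span + bounds.a_min
    return EpochedRecording(subject_id=ep.subject_id, group=ep.group,
                            epochs=data, fs=ep.fs,
                            amplitude_state=AmplitudeState.TRANSFORMED)
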