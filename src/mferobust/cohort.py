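"""Seeded synthetic two-group EEG-like cohorts.

The generator produces multichannel signals carrying the two statistical
features the downstream analysis depends on:

* a *group complexity difference* — each channel is a mixture
  ``a * oscillation + (1 - a) * noise`` where the mixing fraction ``a``
  ("regularity") differs between the healthy (HS) and Alzheimer's (AD)
  groups, so that entropy separates the groups;
* *amplitude heterogeneity* — log-normal multiplicative gains per subject
  (emulating different acquisition systems) and per channel (electrode
  gain spread), the bias source the amplitude transformation removes.

Everything is deterministic given the cohort seed: per-subject seeds are
derived with ``numpy.random.SeedSequence([seed, subject_index])``, a stable,
documented mixing, so regenerating any one subject does not depend on
generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np

__all__ = [
    "CHANNELS_1020",
    "Group",
    "CohortSpec",
    "Recording",
    "Cohort",
    "generate_subject",
    "generate_cohort",
    "write_cohort",
]

#: The 19 scalp electrodes of the international 10-20 placement system.
CHANNELS_1020 = (
    "FP1", "FP2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "FZ", "CZ", "PZ",
)


class Group(str, Enum):
    HS = "HS"
    AD = "AD"


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror the acquisition protocol of the clinical recordings the
    analysis emulates: 19 channels in the 10-20 layout, 200 Hz sampling,
    51 s of resting-state signal per subject, 30 subjects per group.
    """

    n_per_group: int = 30
    n_channels: int = 19
    fs: float = 200.0
    duration: float = 51.0
    regularity_hs: float = 0.2
    regularity_ad: float = 0.5
    osc_freq: float = 9.0
    subject_gain_sigma: float = 0.5
    channel_gain_sigma: float = 0.1
    noise_model: str = "pink"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        n_samples = self.fs * self.duration
        if abs(n_samples - round(n_samples)) > 1e-9:
            raise ValueError("fs * duration must be an integer sample count")
        for name in ("regularity_hs", "regularity_ad"):
            a = getattr(self, name)
            if not 0.0 <= a < 1.0:
                raise ValueError(f"{name} must lie in [0, 1), got {a}")
        if self.subject_gain_sigma < 0 or self.channel_gain_sigma < 0:
            raise ValueError("gain sigmas must be non-negative")
        if self.noise_model not in ("white", "pink"):
            raise ValueError("noise_model must be 'white' or 'pink'")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    @property
    def channel_names(self) -> tuple[str, ...]:
        if self.n_channels == len(CHANNELS_1020):
            return CHANNELS_1020
        if self.n_channels < len(CHANNELS_1020):
            return CHANNELS_1020[: self.n_channels]
        extra = tuple(f"EX{i}" for i in range(self.n_channels - len(CHANNELS_1020)))
        return CHANNELS_1020 + extra


@dataclass
class Recording:
    """One subject's multichannel signal (channels x samples, µV-like units)."""

    subject_id: str
    group: Group
    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    subject_gain: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Cohort:
    spec: CohortSpec
    recordings: list[Recording] = field(default_factory=list)

    def by_group(self, group: Group) -> list[Recording]:
        return [r for r in self.recordings if r.group == group]


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f-shaped noise via spectral filtering of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0  # no DC component
    x = np.fft.irfft(spec * scale, n)
    return x / x.std()


def subject_seed(cohort_seed: int, subject_index: int) -> int:
    """Stable per-subject seed: SeedSequence([cohort_seed, index])."""
    ss = np.random.SeedSequence([int(cohort_seed), int(subject_index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def generate_subject(spec: CohortSpec, group: Group, subj_seed: int,
                     subject_id: str | None = None) -> Recording:
    """Generate one subject.

    Each channel is ``g_subj * g_chan * mix(t)`` with ``mix`` the
    unit-variance normalization of ``a * o(t) + (1 - a) * n(t)``, where
    ``o`` is a unit-variance sinusoid at ``osc_freq`` with a per-channel
    random phase, ``n`` is unit-variance noise, and the gains are log-normal:
    ``g = exp(Normal(0, sigma^2))``, drawn once per subject resp. channel.
    The mixture is renormalized so that the regularity fraction controls
    only the signal's *structure*; amplitude differences between subjects
    and channels come exclusively from the gains.
    """
    group = Group(group)
    rng = np.random.default_rng(int(subj_seed))
    a = spec.regularity_hs if group is Group.HS else spec.regularity_ad
    n = spec.n_samples
    t = np.arange(n) / spec.fs

    g_subj = float(np.exp(rng.normal(0.0, spec.subject_gain_sigma))) \
        if spec.subject_gain_sigma > 0 else 1.0
    data = np.empty((spec.n_channels, n))
    for ch in range(spec.n_channels):
        g_chan = float(np.exp(rng.normal(0.0, spec.channel_gain_sigma))) \
            if spec.channel_gain_sigma > 0 else 1.0
        phase = rng.uniform(0.0, 2.0 * np.pi)
        osc = np.sqrt(2.0) * np.sin(2.0 * np.pi * spec.osc_freq * t + phase)
        if spec.noise_model == "white":
            noise = rng.standard_normal(n)
        else:
            noise = _pink_noise(rng, n)
        # normalize the mixture to unit variance so group membership does not
        # leak into amplitude: heterogeneity must come from the gains alone
        mix = (a * osc + (1.0 - a) * noise) / np.sqrt(a * a + (1.0 - a) ** 2)
        data[ch] = g_subj * g_chan * mix

    if subject_id is None:
        subject_id = f"{group.value}-{subj_seed:010d}"
    return Recording(subject_id=subject_id, group=group, data=data, fs=spec.fs,
                     channel_names=spec.channel_names, subject_gain=g_subj)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a balanced two-group cohort, fully determined by ``spec.seed``."""
    if spec.n_per_group < 2:
        raise ValueError("n_per_group must be >= 2 (group statistics undefined below)")
    recordings: list[Recording] = []
    idx = 0
    for group in (Group.HS, Group.AD):
        for k in range(spec.n_per_group):
            seed = subject_seed(spec.seed, idx)
            rec = generate_subject(spec, group, seed,
                                   subject_id=f"{group.value}{k + 1:03d}")
            recordings.append(rec)
            idx += 1
    return Cohort(spec=spec, recordings=recordings)


def write_cohort(cohort: Cohort, outdir: str | Path) -> list[Path]:
    """Write a cohort to disk: per-subject ``.npy`` arrays plus a CSV manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = ["subject_id,group,gain,path"]
    written: list[Path] = []
    for rec in cohort.recordings:
        path = outdir / f"{rec.subject_id}.npy"
        np.save(path, rec.data)
        written.append(path)
        rows.append(f"{rec.subject_id},{rec.group.value},{rec.subject_gain:.6g},{path.name}")
    manifest = outdir / "manifest.csv"
    manifest.write_text("\n".join(rows) + "\n")
    written.append(manifest)
    return written


def null_spec(spec: CohortSpec) -> CohortSpec:
    """Copy of ``spec`` with both groups set to the HS regularity (zero effect)."""
    return replace(spec, regularity_ad=spec.regularity_hs)
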