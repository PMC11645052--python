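"""Fuzzy entropy and its multiscale extension (MFE).

Fuzzy entropy (FuzzyEn) measures the regularity of a series by comparing
how often templates of ``m`` consecutive samples remain similar when
extended to ``m + 1`` samples. Templates are baseline-corrected (their own
mean is subtracted), compared with the Chebyshev distance ``d``, and graded
by a continuous exponential membership function

    D_ij = exp(-d_ij**n / r_abs)

instead of a hard threshold. With ``phi_m`` the mean membership over all
ordered template pairs (i != j),

    FE(m, n, r_abs) = -ln(phi_{m+1} / phi_m),

which is the (log-) conditional probability that patterns similar for ``m``
samples stay similar for ``m + 1``. Higher values mean a more irregular
signal. The multiscale profile evaluates FE on coarse-grained copies of the
series (non-overlapping means of ``s`` consecutive samples) for scale
factors ``s = 1..20``, with the *same* absolute tolerance ``r_abs`` at
every scale.

Because ``d`` carries the signal's amplitude while ``r_abs`` is only
proportional to a standard deviation, FE with ``n != 1`` is *not* invariant
to amplitude rescaling: larger-amplitude data are pushed toward lower
membership and higher entropy. This amplitude sensitivity is exactly what
the amplitude transformation in :mod:`mferobust.preprocess` removes. The
exact invariance that does hold is joint: ``FE(c*x, c**n * r_abs) ==
FE(x, r_abs)`` for any ``c > 0``.

The tolerance reference ``r_abs = r_coeff * SD`` supports two conventions
(``r_mode``): ``per_subject_global`` (default) uses one SD per subject,
computed over the full multichannel epoch array actually fed to the
entropy (raw or amplitude-transformed respectively); ``per_epoch_channel``
recomputes the SD on each epoch's scale-1 channel signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import cdist

from .cohort import Group
from .preprocess import AmplitudeState, EpochedRecording

__all__ = [
    "RMode",
    "EntropyParams",
    "EntropyGrid",
    "coarse_grain",
    "fuzzy_entropy",
    "mfe_profile",
    "scale_average",
    "subject_channel_profiles",
    "multi_combination_profiles",
    "DEFAULT_M_VALUES",
    "DEFAULT_R_COEFFS",
    "default_combinations",
]

#: The published parameter grid: 12 (m, r) combinations.
DEFAULT_M_VALUES = (2, 3, 4)
DEFAULT_R_COEFFS = (0.10, 0.15, 0.20, 0.25)


def default_combinations(m_values=DEFAULT_M_VALUES,
                         r_coeffs=DEFAULT_R_COEFFS) -> list[tuple[int, float]]:
    """(m, r_coeff) pairs in the standard combination order (1-12 by default)."""
    return [(m, r) for m in m_values for r in r_coeffs]


class RMode(str, Enum):
    PER_SUBJECT_GLOBAL = "per_subject_global"
    PER_EPOCH_CHANNEL = "per_epoch_channel"


@dataclass(frozen=True)
class EntropyParams:
    """One point of the MFE parameter grid."""

    m: int = 2
    r_coeff: float = 0.20
    n: float = 2.0
    scales: tuple[int, ...] = tuple(range(1, 21))
    r_mode: RMode = RMode.PER_SUBJECT_GLOBAL

    def __post_init__(self) -> None:
        if self.m < 1 or int(self.m) != self.m:
            raise ValueError("m must be a positive integer")
        if self.r_coeff <= 0:
            raise ValueError("r_coeff must be positive")
        if self.n <= 0:
            raise ValueError("n must be positive")
        if len(self.scales) == 0 or min(self.scales) < 1:
            raise ValueError("scales must be a nonempty set of integers >= 1")
        object.__setattr__(self, "r_mode", RMode(self.r_mode))


def coarse_grain(x: np.ndarray, s: int) -> np.ndarray:
    """Scale-``s`` series: non-overlapping means of ``s`` consecutive samples."""
    x = np.asarray(x, dtype=float)
    s = int(s)
    if s < 1:
        raise ValueError("scale factor must be >= 1")
    n = len(x)
    if s > n:
        raise ValueError(f"scale {s} exceeds series length {n}")
    if s == 1:
        return x.copy()
    m = n // s
    return x[: m * s].reshape(m, s).mean(axis=1)


def _templates(x: np.ndarray, k: int) -> np.ndarray:
    """All length-``k`` templates with their own mean subtracted."""
    e = sliding_window_view(x, k)
    return np.ascontiguousarray(e - e.mean(axis=1, keepdims=True))


def _phi_sums(x: np.ndarray, sizes: tuple[int, ...], n: float,
              r_list: np.ndarray) -> dict[int, tuple[np.ndarray, np.ndarray, int]]:
    """For each template size k, mean membership over pairs, per tolerance.

    Returns, per size k, ``(phi_full, phi_sub, T)`` where ``phi_full[j]``
    averages over all T = N-k+1 templates and ``phi_sub[j]`` over the first
    T-1 (the count used when k plays the role of m rather than m+1).
    """
    out: dict[int, tuple[np.ndarray, np.ndarray, int]] = {}
    for k in sizes:
        e = _templates(x, k)
        d = cdist(e, e, "chebyshev")
        p = d * d if n == 2 else d**n
        t = p.shape[0]
        phi_full = np.empty(len(r_list))
        phi_sub = np.empty(len(r_list))
        for j, r_abs in enumerate(r_list):
            mem = np.exp(p * (-1.0 / r_abs))
            s_full = mem.sum()
            last = mem[-1, :].sum()
            s_sub = s_full - 2.0 * last + mem[-1, -1]
            phi_full[j] = (s_full - t) / (t * (t - 1.0)) if t > 1 else np.nan
            ls = t - 1
            phi_sub[j] = (s_sub - ls) / (ls * (ls - 1.0)) if ls > 1 else np.nan
        out[k] = (phi_full, phi_sub, t)
    return out


def fuzzy_entropy(x: np.ndarray, m: int, n: float, r_abs: float) -> float:
    """FE of one series with an absolute tolerance ``r_abs``."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    if r_abs <= 0:
        raise ValueError("r_abs must be positive")
    big_n = len(x)
    if big_n < m + 2:
        raise ValueError(f"need at least m + 2 = {m + 2} samples, got {big_n}")
    table = _phi_sums(x, (m, m + 1), n, np.array([r_abs]))
    phi_m = table[m][1][0]      # N - m templates of length m
    phi_m1 = table[m + 1][0][0]  # all N - m templates of length m + 1
    return float(-np.log(phi_m1 / phi_m))


def mfe_profile(x: np.ndarray, p: EntropyParams, r_abs: float) -> np.ndarray:
    """Per-scale FE vector for one epoch series (same ``r_abs`` at all scales)."""
    x = np.asarray(x, dtype=float)
    out = np.empty(len(p.scales))
    for i, s in enumerate(p.scales):
        cg = coarse_grain(x, s)
        if len(cg) < p.m + 2:
            raise ValueError(
                f"scale {s}: coarse-grained length {len(cg)} below m + 2 = {p.m + 2}")
        out[i] = fuzzy_entropy(cg, p.m, p.n, r_abs)
    return out


def scale_average(profile: np.ndarray) -> float:
    """Arithmetic mean of a per-scale FE profile (the scalar MFE summary)."""
    profile = np.asarray(profile, dtype=float)
    if profile.size == 0:
        raise ValueError("empty profile")
    return float(profile.mean())


def _resolve_sd(ep: EpochedRecording) -> float:
    """One SD per subject over the full multichannel epoch array."""
    sd = float(ep.epochs.std())
    if sd == 0:
        raise ValueError("zero standard deviation in the r reference signal")
    return sd


def multi_combination_profiles(
    ep: EpochedRecording,
    combos: list[tuple[int, float]] | None = None,
    n: float = 2.0,
    scales: tuple[int, ...] = tuple(range(1, 21)),
    r_mode: RMode = RMode.PER_SUBJECT_GLOBAL,
) -> np.ndarray:
    """Epoch-averaged MFE for several (m, r_coeff) combinations at once.

    Shares the template distance matrices across the whole (m, r) grid —
    for the 12-combination default this costs barely more than a single
    combination. Returns an array of shape (n_combos, channels, scales).
    """
    if combos is None:
        combos = default_combinations()
    r_mode = RMode(r_mode)
    m_set = sorted({m for m, _ in combos})
    sizes = tuple(sorted({k for m in m_set for k in (m, m + 1)}))
    r_coeffs = [r for _, r in combos]

    if r_mode is RMode.PER_SUBJECT_GLOBAL:
        global_sd = _resolve_sd(ep)

    c_channels, n_epochs, spe = ep.epochs.shape
    min_len = spe // max(scales)
    if min_len < max(m_set) + 2:
        raise ValueError(
            f"scale {max(scales)}: coarse-grained length {min_len} below "
            f"m + 2 = {max(m_set) + 2}")

    acc = np.zeros((len(combos), c_channels, len(scales)))
    uniq_r = sorted(set(r_coeffs))
    for ch in range(c_channels):
        for e in range(n_epochs):
            x = ep.epochs[ch, e]
            if r_mode is RMode.PER_SUBJECT_GLOBAL:
                sd = global_sd
            else:
                sd = float(x.std())
                if sd == 0:
                    raise ValueError(
                        f"zero SD in channel {ch}, epoch {e} (r reference)")
            r_list = np.array([c * sd for c in uniq_r])
            r_index = {c: j for j, c in enumerate(uniq_r)}
            for si, s in enumerate(scales):
                cg = coarse_grain(x, s)
                table = _phi_sums(cg, sizes, n, r_list)
                for ci, (m, rc) in enumerate(combos):
                    j = r_index[rc]
                    phi_m = table[m][1][j]
                    phi_m1 = table[m + 1][0][j]
                    acc[ci, ch, si] += -np.log(phi_m1 / phi_m)
    return acc / n_epochs


def subject_channel_profiles(ep: EpochedRecording, p: EntropyParams) -> np.ndarray:
    """Epoch-averaged channels x scales MFE grid slice for one subject."""
    vals = multi_combination_profiles(
        ep, combos=[(p.m, p.r_coeff)], n=p.n, scales=p.scales, r_mode=p.r_mode)
    return vals[0]


@dataclass
class EntropyGrid:
    """Per-subject, per-channel, per-scale MFE values for one combination."""

    values: np.ndarray  # subjects x channels x scales
    params: EntropyParams
    amplitude_state: AmplitudeState
    subject_ids: list[str] = field(default_factory=list)
    groups: list[Group] = field(default_factory=list)
    combination_id: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be subjects x channels x scales")

    def group_values(self, group: Group) -> np.ndarray:
        mask = np.array([g == group for g in self.groups])
        return self.values[mask]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table of the grid."""
        n_subj, n_ch, n_sc = self.values.shape
        subj = self.subject_ids or [f"S{i}" for i in range(n_subj)]
        groups = [g.value for g in self.groups] if self.groups else [""] * n_subj
        rows = []
        for i in range(n_subj):
            for c in range(n_ch):
                for k, s in enumerate(self.params.scales):
                    rows.append((subj[i], groups[i], c, s, self.combination_id,
                                 self.amplitude_state.value, self.values[i, c, k]))
        return pd.DataFrame(rows, columns=[
            "subject_id", "group", "channel", "scale", "combination_id",
            "amplitude_state", "fe_value"])
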