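"""Ordinal pattern encoding and sliding-window segmentation.

Each channel is turned into a sequence of ordinal patterns: the pattern at
index i is the rank order of the m samples (x_i, x_{i+tau}, ...,
x_{i+(m-1)tau}).  With m = 5 there are 5! = 120 possible patterns; each is
assigned its 0-based lexicographic rank as an integer code.  Ordinal codes
depend only on the relative order of values, so they are invariant under
any strictly increasing transform of the signal — the property that makes
permutation entropy robust to amplitude scaling and electrode gain.

Pattern sequences are then cut into 30 s sliding windows advanced by 1 s.
A pattern belongs to a window iff all of its underlying EEG samples fall
inside the window, and each window (data block) is timestamped at its
rightmost underlying EEG sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np

from .core import DataError

N_CHANNELS_PER_BLOCK = 4


@dataclass
class OrdinalPatternSequence:
    """Per-channel sequence of ordinal pattern codes.

    ``t0_s`` is the time of the first pattern's rightmost underlying sample;
    ``fs`` is the pattern rate, equal to the sample rate for tau = 1.
    """

    channel_label: str
    m: int
    tau: int
    codes: np.ndarray
    t0_s: float
    fs: float

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def signal_start_s(self) -> float:
        """Time of the first underlying EEG sample."""
        return self.t0_s - (self.m - 1) * self.tau / self.fs


@dataclass
class DataBlock:
    """One sliding-window position: aligned code windows of all 4 channels.

    ``timestamp_s`` is the time of the rightmost underlying EEG sample
    (end-of-sample convention: a window covering samples 0..5999 of a
    recording starting at t=0 at 200 Hz is stamped 30.0 s).
    """

    channels: dict[str, np.ndarray]
    timestamp_s: float
    window_start_s: float
    m: int = 5

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise DataError(f"unequal channel window lengths: {lengths}")

    @property
    def window_len_patterns(self) -> int:
        return len(next(iter(self.channels.values())))


def encode_patterns(
    signal: np.ndarray, m: int = 5, tau: int = 1, *,
    channel_label: str = "", t_start_s: float = 0.0, fs: float = 200.0,
) -> OrdinalPatternSequence:
    """Encode a signal into ordinal pattern codes (lexicographic ranks).

    The code at index i is the 0-based lexicographic rank of the permutation
    of time offsets (0, tau, ..., (m-1)tau) that sorts the m values
    ascending.  Ties are broken by temporal order: the earlier sample ranks
    lower (stable sort), so e.g. the all-ascending window maps to code 0 and
    the all-descending window to code m!-1.

    Parameters
    ----------
    signal : 1-d array of samples.
    m : embedding dimension, 2..7.
    tau : time lag between embedded samples, in samples.
    channel_label, t_start_s, fs : metadata carried into the result;
        ``t_start_s`` is the time of ``signal[0]``.
    """
    if not 2 <= m <= 7:
        raise DataError(f"embedding dimension m must be in [2, 7], got {m}")
    if tau < 1:
        raise DataError(f"time lag tau must be >= 1, got {tau}")
    x = np.asarray(signal, dtype=float).ravel()
    min_len = (m - 1) * tau + 1
    if x.size < min_len:
        raise DataError(
            f"signal of length {x.size} too short for m={m}, tau={tau}; "
            f"minimum length is {min_len}"
        )
    n_pat = x.size - (m - 1) * tau
    # embedding matrix: row i holds (x_i, x_{i+tau}, ..., x_{i+(m-1)tau})
    idx = np.arange(n_pat)[:, None] + tau * np.arange(m)[None, :]
    emb = x[idx]
    # stable argsort -> permutation of time offsets in ascending value order
    perm = np.argsort(emb, axis=1, kind="stable")
    # Lehmer code: rank = sum_i #{j > i : perm_j < perm_i} * (m-1-i)!
    codes = np.zeros(n_pat, dtype=np.int64)
    for i in range(m - 1):
        inversions = (perm[:, i + 1:] < perm[:, i:i + 1]).sum(axis=1)
        codes += inversions * factorial(m - 1 - i)
    return OrdinalPatternSequence(
        channel_label=channel_label, m=m, tau=tau, codes=codes,
        t0_s=t_start_s + (m - 1) * tau / fs, fs=fs,
    )


def _check_aligned(sequences: list[OrdinalPatternSequence]) -> None:
    ref = sequences[0]
    for seq in sequences[1:]:
        if (seq.t0_s != ref.t0_s or seq.fs != ref.fs
                or len(seq) != len(ref) or seq.m != ref.m or seq.tau != ref.tau):
            raise DataError(
                f"misaligned pattern sequences: {seq.channel_label} vs "
                f"{ref.channel_label} (t0, fs, length or (m, tau) differ)"
            )


def segment_blocks(
    sequences: list[OrdinalPatternSequence],
    window_s: float = 30.0,
    shift_s: float = 1.0,
    min_window_start_s: float | None = None,
) -> list[DataBlock]:
    """Cut aligned pattern sequences into sliding-window data blocks.

    Windows are defined on EEG-sample time: block b covers the
    ``window_s * fs`` samples starting ``b * shift_s`` after the signal
    start, and contains exactly the patterns whose underlying samples all
    lie inside the window.  Blocks whose window starts before
    ``min_window_start_s`` (typically the end of the upstream filter's
    settling period) are dropped.
    """
    if not sequences:
        raise DataError("no pattern sequences given")
    _check_aligned(sequences)
    ref = sequences[0]
    fs = ref.fs
    m, tau = ref.m, ref.tau
    span = (m - 1) * tau  # samples covered by one pattern minus one
    window_len = int(round(window_s * fs))
    shift = int(round(shift_s * fs))
    if window_len <= span:
        raise DataError(f"window of {window_len} samples shorter than one pattern")
    n_samples = len(ref) + span
    t_start = ref.signal_start_s

    patterns_per_block = window_len - span
    blocks: list[DataBlock] = []
    b = 0
    while b * shift + window_len <= n_samples:
        left = b * shift  # sample index of the window's leftmost sample
        window_start_s = t_start + left / fs
        if min_window_start_s is None or window_start_s >= min_window_start_s - 1e-9:
            sl = slice(left, left + patterns_per_block)
            blocks.append(DataBlock(
                channels={s.channel_label: s.codes[sl] for s in sequences},
                timestamp_s=t_start + (left + window_len) / fs,
                window_start_s=window_start_s,
                m=m,
            ))
        b += 1
    return blocks
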