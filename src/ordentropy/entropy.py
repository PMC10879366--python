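"""Plug-in entropy estimation on ordinal-pattern data blocks.

Two scores are computed per data block, both in bits:

* **Permutation entropy (PE)** — the Shannon entropy of the empirical
  ordinal-pattern distribution within the window, averaged over the two
  frontal channels Fp1 and Fp2.  It is low for regular, slow-wave
  dominated signals and high for irregular ones; range [0, log2 m!].

* **Symbolic transfer entropy (STE)** — transfer entropy computed on the
  ordinal-pattern sequences of a source/target channel pair.  Using the
  reformulation

      T(X -> Y) = H(Y_t, Y_{t+d}) - H(Y_t) - H(X_t, Y_t, Y_{t+d}) + H(X_t, Y_t)

  all four entropies are plug-in estimates marginalized from the *single*
  empirical distribution of triples (X_t, Y_t, Y_{t+d}) over the common
  index range t = 0 .. len-1-d.  With consistent marginals the estimate is
  a conditional mutual information of one empirical distribution and is
  therefore non-negative by construction.

STE is evaluated for the four fronto-parietal pairs (Fp1->P3, Fp1->P4,
Fp2->P3, Fp2->P4), their four reverses, and six transfer delays
d = 7..12 pattern steps (35..60 ms at 200 Hz): 48 estimates per block.
STE_FP / STE_PF are the directional means (24 values each), STE_UND their
sum, and STE_MEAN the mean of all 48 (= STE_UND / 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np

from .core import DataError, EegRecording
from .ordinal import DataBlock, encode_patterns, segment_blocks

SCORE_NAMES = ("PE", "STE_FP", "STE_PF", "STE_UND", "STE_MEAN")

FP_PAIRS = (("Fp1", "P3"), ("Fp1", "P4"), ("Fp2", "P3"), ("Fp2", "P4"))


@dataclass
class EntropyConfig:
    """Which pairs, delays and channels enter the block scores.

    ``delays`` are transfer delays on the 200 Hz pattern grid; the default
    7..12 samples corresponds to 35..60 ms.  Scores are reported in bits
    (base-2 logarithm), unnormalized; set ``normalize_pe`` to divide PE by
    log2(m!) for display on a 0..1 scale.
    """

    delays: tuple[int, ...] = (7, 8, 9, 10, 11, 12)
    fp_pairs: tuple[tuple[str, str], ...] = FP_PAIRS
    pe_channels: tuple[str, ...] = ("Fp1", "Fp2")
    normalize_pe: bool = False

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.delays):
            raise DataError(f"transfer delays must be positive, got {self.delays}")

    @property
    def pf_pairs(self) -> tuple[tuple[str, str], ...]:
        return tuple((tgt, src) for src, tgt in self.fp_pairs)

    @property
    def n_ste_per_block(self) -> int:
        return 2 * len(self.fp_pairs) * len(self.delays)


@dataclass
class EntropyScoreSeries:
    """Per-recording time series of one score on the 1 s block grid."""

    patient_id: str
    score_name: str
    timestamps_s: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps_s.shape != self.values.shape:
            raise DataError("timestamps and values length mismatch")

    def __len__(self) -> int:
        return len(self.values)

    def value_at(self, t_s: float, tol_s: float = 0.5) -> float:
        """Series value whose timestamp is nearest t_s, required within tol_s."""
        i = int(np.argmin(np.abs(self.timestamps_s - t_s)))
        if abs(self.timestamps_s[i] - t_s) > tol_s:
            raise DataError(
                f"no {self.score_name} sample within {tol_s} s of t={t_s} s "
                f"(series covers [{self.timestamps_s[0]}, {self.timestamps_s[-1]}] s)"
            )
        return float(self.values[i])


def shannon_entropy(counts) -> float:
    """Shannon entropy (bits) of the distribution given by integer counts."""
    c = np.asarray(counts)
    if (c < 0).any():
        raise DataError("negative count")
    total = c.sum()
    if total < 1:
        raise DataError("all counts zero")
    p = c[c > 0] / total
    return float(-(p * np.log2(p)).sum())


def permutation_entropy(code_window, m: int = 5) -> float:
    """PE (bits) of one channel's code window: plug-in Shannon entropy of codes."""
    codes = np.asarray(code_window)
    if codes.size == 0:
        raise DataError("empty code window")
    n_sym = factorial(m)
    if codes.max() >= n_sym or codes.min() < 0:
        raise DataError(f"code outside [0, {n_sym - 1}] for m={m}")
    return shannon_entropy(np.bincount(codes, minlength=n_sym))


def _entropy_from_keys(keys: np.ndarray) -> float:
    """Shannon entropy (bits) of the empirical distribution of integer keys."""
    counts = np.unique(keys, return_counts=True)[1]
    p = counts / keys.size
    return float(-(p * np.log2(p)).sum())


def transfer_entropy(source_codes, target_codes, delta: int) -> float:
    """Plug-in transfer entropy T(X -> Y) in bits at transfer delay delta.

    All four entropy terms are marginals of the empirical distribution of
    (X_t, Y_t, Y_{t+delta}) over t = 0 .. len-1-delta, which makes the
    estimate non-negative (it is the conditional mutual information
    I(Y_{t+delta}; X_t | Y_t) of that one distribution).
    """
    x = np.asarray(source_codes, dtype=np.int64)
    y = np.asarray(target_codes, dtype=np.int64)
    if x.shape != y.shape:
        raise DataError("source and target sequences must be aligned (equal length)")
    n = x.size
    if delta < 1 or delta >= n:
        raise DataError(f"delta={delta} outside [1, {n - 1}] for length-{n} sequences")
    xt, yt, yf = x[: n - delta], y[: n - delta], y[delta:]
    base = int(max(xt.max(), yt.max(), yf.max())) + 1
    key_xy = xt * base + yt
    key_yf = yt * base + yf
    key_xyf = key_xy * base + yf
    te = (_entropy_from_keys(key_yf) - _entropy_from_keys(yt)
          - _entropy_from_keys(key_xyf) + _entropy_from_keys(key_xy))
    # mathematically >= 0; clamp float round-off only
    return 0.0 if -1e-9 < te < 0.0 else te


def block_scores(block: DataBlock, cfg: EntropyConfig | None = None) -> dict[str, float]:
    """All five scores for one data block.

    Exactly ``cfg.n_ste_per_block`` (48 by default) transfer-entropy
    estimates are computed: 4 fronto-parietal pairs x 6 delays in each
    direction.  PE is the mean permutation entropy of the frontal channels.
    """
    if cfg is None:
        cfg = EntropyConfig()
    needed = {c for pair in cfg.fp_pairs for c in pair} | set(cfg.pe_channels)
    for name in sorted(needed):
        if name not in block.channels:
            raise DataError(f"data block is missing channel {name!r}")
    n_pat = block.window_len_patterns
    if any(d >= n_pat for d in cfg.delays):
        raise DataError(f"delay >= window pattern count ({n_pat})")

    fp_values, pf_values = [], []
    for src, tgt in cfg.fp_pairs:
        for d in cfg.delays:
            fp_values.append(transfer_entropy(block.channels[src],
                                              block.channels[tgt], d))
            pf_values.append(transfer_entropy(block.channels[tgt],
                                              block.channels[src], d))
    assert len(fp_values) + len(pf_values) == cfg.n_ste_per_block

    pe_vals = [permutation_entropy(block.channels[c], block.m)
               for c in cfg.pe_channels]
    pe = float(np.mean(pe_vals))
    if cfg.normalize_pe:
        pe /= np.log2(factorial(block.m))

    ste_fp = float(np.mean(fp_values))
    ste_pf = float(np.mean(pf_values))
    return {
        "PE": pe,
        "STE_FP": ste_fp,
        "STE_PF": ste_pf,
        "STE_UND": ste_fp + ste_pf,
        "STE_MEAN": float(np.mean(fp_values + pf_values)),
    }


def score_recording(
    preprocessed: EegRecording,
    cfg: EntropyConfig | None = None,
    *,
    m: int = 5,
    tau: int = 1,
    window_s: float = 30.0,
    shift_s: float = 1.0,
    patient_id: str = "",
) -> dict[str, EntropyScoreSeries]:
    """Run ordinal encoding + block segmentation + scoring on one recording.

    Expects a 200 Hz recording with channels Fp1, Fp2, P3, P4 (typically
    the output of :func:`ordentropy.preprocess.preprocess_recording`).
    Returns one series per score name on the 1 s block grid.
    """
    if cfg is None:
        cfg = EntropyConfig()
    if preprocessed.fs != 200.0:
        raise DataError(f"expected a 200 Hz recording, got {preprocessed.fs} Hz")
    preprocessed.require_channels()
    sequences = [
        encode_patterns(preprocessed.channel(lab), m, tau, channel_label=lab,
                        t_start_s=preprocessed.start_time_s, fs=preprocessed.fs)
        for lab in ("Fp1", "Fp2", "P3", "P4")
    ]
    blocks = segment_blocks(sequences, window_s, shift_s,
                            min_window_start_s=preprocessed.settled_from_s)
    if not blocks:
        raise DataError("recording too short: no complete analysis window")
    timestamps = np.array([b.timestamp_s for b in blocks])
    per_block = [block_scores(b, cfg) for b in blocks]
    return {
        name: EntropyScoreSeries(
            patient_id=patient_id, score_name=name, timestamps_s=timestamps,
            values=np.array([s[name] for s in per_block]),
        )
        for name in SCORE_NAMES
    }
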