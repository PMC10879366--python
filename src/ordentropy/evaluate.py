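"""Responsiveness classification accuracy and bootstrap confidence intervals.

Scores are sampled at four time points per patient: T1 = LoR - 15 s and
T2 = LoR + 30 s around induction, T3 = RoR - 15 s and T4 = RoR + 30 s
around emergence.  With 30 s right-edge-stamped analysis windows, T1 is
the latest block containing no anesthetized-state EEG and T2 the earliest
containing no wakeful EEG; symmetrically for T3/T4.  T1 and T4 carry the
label *responsive*, T2 and T3 *unresponsive*.

A single dichotomization threshold is selected by maximizing accuracy on
the LoR contrast (T1 vs. T2) and reused for all contrasts; a score above
the threshold is read as "positive for wakefulness".  Accuracy is
(tp + tn) / (tp + fp + tn + fn) — the probability of correctly classifying
a patient's responsiveness state.  Confidence intervals come from
patient-level percentile bootstrap (default 10,000 replicates, 95% level);
pairwise accuracy differences between scores use paired resamples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DataError, EventAnnotations
from .entropy import EntropyScoreSeries

TIMEPOINTS = ("T1", "T2", "T3", "T4")
RESPONSIVE = {"T1": True, "T2": False, "T3": False, "T4": True}
CONTRAST_TIMEPOINTS = {
    "LoR": ("T1", "T2"),
    "RoR": ("T3", "T4"),
    "combined": TIMEPOINTS,
}
PRE_OFFSET_S = -15.0
POST_OFFSET_S = 30.0


@dataclass
class TimepointSample:
    """One patient's score at one analysis time point."""

    patient_id: str
    timepoint: str
    responsive: bool
    score: float


@dataclass
class AccuracyResult:
    contrast: str
    score_name: str
    threshold: float
    accuracy: float
    n_patients: int
    ci_low: float | None = None
    ci_high: float | None = None


def sample_timepoints(
    series: EntropyScoreSeries, events: EventAnnotations,
) -> list[TimepointSample]:
    """Extract the four T1..T4 samples from one patient's score series.

    Each target time is matched to the nearest series timestamp, required
    within 0.5 s; a target outside coverage raises an error naming the
    time point.
    """
    targets = {
        "T1": events.lor_s + PRE_OFFSET_S,
        "T2": events.lor_s + POST_OFFSET_S,
        "T3": events.ror_s + PRE_OFFSET_S,
        "T4": events.ror_s + POST_OFFSET_S,
    }
    out = []
    for tp in TIMEPOINTS:
        try:
            value = series.value_at(targets[tp])
        except DataError as exc:
            raise DataError(f"time point {tp}: {exc}") from exc
        out.append(TimepointSample(
            patient_id=events.patient_id, timepoint=tp,
            responsive=RESPONSIVE[tp], score=value,
        ))
    return out


def _scores_labels(samples: list[TimepointSample]) -> tuple[np.ndarray, np.ndarray]:
    scores = np.array([s.score for s in samples], dtype=float)
    labels = np.array([s.responsive for s in samples], dtype=bool)
    return scores, labels


def accuracy(samples: list[TimepointSample], threshold: float) -> float:
    """Fraction of samples whose responsiveness the threshold rule gets right.

    Classification rule: score strictly above threshold => positive for
    wakefulness; a score exactly at the threshold counts as negative.
    """
    if not samples:
        raise DataError("empty sample set")
    scores, labels = _scores_labels(samples)
    return float(np.mean((scores > threshold) == labels))


def threshold_candidates(scores: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct scores, plus one below the
    minimum and one above the maximum."""
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate([[distinct[0] - 1.0], mids, [distinct[-1] + 1.0]])


def select_threshold(samples: list[TimepointSample]) -> float:
    """The threshold maximizing LoR accuracy (T1 vs. T2), over midpoint
    candidates; ties resolved to the smallest maximizing candidate."""
    lor_samples = [s for s in samples if s.timepoint in ("T1", "T2")]
    if not lor_samples:
        raise DataError("no T1/T2 samples to select a threshold from")
    scores, labels = _scores_labels(lor_samples)
    cands = threshold_candidates(scores)
    # accuracy for every candidate at once; argmax returns the first
    # (= smallest) maximizer since candidates are sorted ascending
    correct = (scores[None, :] > cands[:, None]) == labels[None, :]
    acc = correct.mean(axis=1)
    return float(cands[int(np.argmax(acc))])


def _contrast_samples(samples: list[TimepointSample], contrast: str,
                      ) -> list[TimepointSample]:
    if contrast not in CONTRAST_TIMEPOINTS:
        raise DataError(f"unknown contrast {contrast!r}; "
                        f"expected one of {sorted(CONTRAST_TIMEPOINTS)}")
    keep = CONTRAST_TIMEPOINTS[contrast]
    sub = [s for s in samples if s.timepoint in keep]
    patients = {s.patient_id for s in sub}
    for pid in patients:
        have = {s.timepoint for s in sub if s.patient_id == pid}
        missing = set(keep) - have
        if missing:
            raise DataError(f"patient {pid} missing time point(s) {sorted(missing)}")
    return sub


def evaluate_contrast(
    samples: list[TimepointSample], threshold: float, contrast: str,
    score_name: str = "",
) -> AccuracyResult:
    """Point accuracy of one contrast (LoR: T1/T2; RoR: T3/T4; combined:
    all four) under the given fixed threshold."""
    sub = _contrast_samples(samples, contrast)
    return AccuracyResult(
        contrast=contrast, score_name=score_name, threshold=threshold,
        accuracy=accuracy(sub, threshold),
        n_patients=len({s.patient_id for s in sub}),
    )


def _per_patient_correct(samples: list[TimepointSample], threshold: float,
                         ) -> tuple[list[str], np.ndarray, int]:
    """Per-patient count of correctly classified time points."""
    patients = sorted({s.patient_id for s in samples})
    index = {pid: i for i, pid in enumerate(patients)}
    correct = np.zeros(len(patients))
    per_patient = len(samples) // len(patients)
    for s in samples:
        if ((s.score > threshold) == s.responsive):
            correct[index[s.patient_id]] += 1
    return patients, correct, per_patient


def bootstrap_ci(
    samples: list[TimepointSample], threshold: float, contrast: str,
    n_boot: int = 10_000, level: float = 0.95, seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for one contrast's accuracy.

    Patients are the exchangeable unit: each replicate resamples patients
    with replacement (keeping all their time points together) and
    recomputes accuracy with the threshold held fixed.
    """
    if n_boot < 1:
        raise DataError(f"n_boot must be >= 1, got {n_boot}")
    sub = _contrast_samples(samples, contrast)
    patients, correct, per_patient = _per_patient_correct(sub, threshold)
    if len(patients) < 2:
        raise DataError("bootstrap needs >= 2 patients")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(patients), size=(n_boot, len(patients)))
    acc = correct[idx].sum(axis=1) / (per_patient * len(patients))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(acc, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def accuracy_difference(
    samples_a: list[TimepointSample], samples_b: list[TimepointSample],
    threshold_a: float, threshold_b: float, contrast: str,
    n_boot: int = 10_000, level: float = 0.95, seed: int = 0,
) -> tuple[float, float, float]:
    """Paired bootstrap for the accuracy difference acc_A - acc_B.

    Both sample sets must cover the same patients (the same cohort scored
    by two different parameters).  Each bootstrap replicate draws one
    patient resample and recomputes both accuracies on it, preserving the
    within-patient pairing of the two scores.
    """
    sub_a = _contrast_samples(samples_a, contrast)
    sub_b = _contrast_samples(samples_b, contrast)
    pats_a, correct_a, per_pat = _per_patient_correct(sub_a, threshold_a)
    pats_b, correct_b, _ = _per_patient_correct(sub_b, threshold_b)
    if pats_a != pats_b:
        raise DataError(
            f"patient sets differ: {sorted(set(pats_a) ^ set(pats_b))}"
        )
    n = len(pats_a)
    point = float((correct_a.sum() - correct_b.sum()) / (per_pat * n))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    diff = (correct_a[idx].sum(axis=1) - correct_b[idx].sum(axis=1)) / (per_pat * n)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(diff, [alpha, 1.0 - alpha])
    return point, float(lo), float(hi)
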