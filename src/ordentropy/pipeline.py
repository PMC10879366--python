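"""End-to-end composition: recordings + events -> score tables -> accuracy tables."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .core import DataError
from .entropy import SCORE_NAMES
from .evaluate import (accuracy_difference, bootstrap_ci, evaluate_contrast,
                       sample_timepoints, select_threshold)
from .io import (read_events, read_recording, read_scores, write_events,
                 write_recording_csv, write_recording_edf, write_scores)
from .preprocess import design_lowpass_fir, preprocess_recording
from .synth import generate_cohort

log = logging.getLogger("ordentropy")

CONTRASTS = ("LoR", "RoR", "combined")


def simulate_cohort(config: PipelineConfig, out_dir, fmt: str = "csv") -> None:
    """Generate the synthetic cohort and write recordings + events files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config.simulation)
    events = []
    for rec, ev in cohort:
        log.info("simulate: patient %s (lor=%.1f s, ror=%.1f s)",
                 ev.patient_id, ev.lor_s, ev.ror_s)
        if fmt == "edf":
            write_recording_edf(rec, out_dir / f"{ev.patient_id}.edf")
        else:
            write_recording_csv(rec, out_dir / f"{ev.patient_id}.csv")
        events.append(ev)
    write_events(events, out_dir / "events.csv")


def compute_scores(config: PipelineConfig, recording_path, out_path,
                   patient_id: str | None = None) -> None:
    """Preprocess one recording and write its entropy score table."""
    from .entropy import score_recording

    recording_path = Path(recording_path)
    if patient_id is None:
        patient_id = recording_path.stem
    rec = read_recording(recording_path)
    spec = design_lowpass_fir(config.filter_order, cutoff_hz=config.filter_cutoff_hz)
    pre = preprocess_recording(rec, spec)
    series = score_recording(
        pre, config.entropy, m=config.m, tau=config.tau,
        window_s=config.window_s, shift_s=config.shift_s, patient_id=patient_id,
    )
    n_blocks = len(next(iter(series.values())))
    log.info("compute: %s -> %d blocks, %d STE values per block",
             patient_id, n_blocks, config.entropy.n_ste_per_block)
    write_scores(series, out_path)


def evaluate_cohort(config: PipelineConfig, scores_dir, events_path, out_dir,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Accuracy tables (per contrast/score + pairwise differences vs. PE)."""
    scores_dir, out_dir = Path(scores_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    events = {e.patient_id: e for e in read_events(events_path)}

    samples = {name: [] for name in SCORE_NAMES}
    for pid, ev in sorted(events.items()):
        path = scores_dir / f"{pid}.csv"
        if not path.exists():
            raise DataError(f"evaluate: no score table for patient {pid} ({path})")
        series = read_scores(path, patient_id=pid)
        for name in SCORE_NAMES:
            samples[name].extend(sample_timepoints(series[name], ev))

    thresholds = {name: select_threshold(samples[name]) for name in SCORE_NAMES}

    rows = []
    for name in SCORE_NAMES:
        for contrast in CONTRASTS:
            res = evaluate_contrast(samples[name], thresholds[name], contrast, name)
            lo, hi = bootstrap_ci(samples[name], thresholds[name], contrast,
                                  config.bootstrap_n, config.bootstrap_level,
                                  seed=config.seed)
            rows.append({
                "contrast": contrast, "score_name": name,
                "threshold": res.threshold, "accuracy": res.accuracy,
                "ci_low": lo, "ci_high": hi, "n_patients": res.n_patients,
            })
    results = pd.DataFrame(rows)
    results.to_csv(out_dir / "accuracy.csv", index=False)

    diff_rows = []
    for name in ("STE_FP", "STE_PF", "STE_UND", "STE_MEAN"):
        for contrast in CONTRASTS:
            d, lo, hi = accuracy_difference(
                samples[name], samples["PE"], thresholds[name],
                thresholds["PE"], contrast, config.bootstrap_n,
                config.bootstrap_level, seed=config.seed,
            )
            diff_rows.append({
                "contrast": contrast, "score_name": name, "reference": "PE",
                "difference": d, "ci_low": lo, "ci_high": hi,
            })
    differences = pd.DataFrame(diff_rows)
    differences.to_csv(out_dir / "accuracy_differences.csv", index=False)
    return results, differences


def run_pipeline(config: PipelineConfig, in_dir, out_dir,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full run on an input directory of recordings plus events.csv.

    Writes per-patient score tables, the two accuracy tables, and a run
    manifest under out_dir.  Any stage error aborts, naming the patient
    and stage.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    scores_dir = out_dir / "scores"
    scores_dir.mkdir(parents=True, exist_ok=True)
    events_path = in_dir / "events.csv"
    events = read_events(events_path)
    for ev in events:
        matches = [p for ext in ("csv", "edf")
                   for p in [in_dir / f"{ev.patient_id}.{ext}"] if p.exists()]
        if not matches:
            raise DataError(f"patient {ev.patient_id}: no recording in {in_dir}")
        try:
            compute_scores(config, matches[0], scores_dir / f"{ev.patient_id}.csv",
                           patient_id=ev.patient_id)
        except Exception as exc:
            raise DataError(
                f"patient {ev.patient_id}, stage compute: {exc}") from exc
    try:
        results, differences = evaluate_cohort(config, scores_dir, events_path,
                                               out_dir)
    except DataError as exc:
        raise DataError(f"stage evaluate: {exc}") from exc
    manifest = {
        "ordentropy_version": __version__,
        "config": config.to_dict(),
        "n_patients": len(events),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results, differences
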