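"""Shared fixtures: the frozen default synthetic cohort, scored once."""

from __future__ import annotations

import pytest

import ordentropy as oe


@pytest.fixture(scope="session")
def filter_spec():
    return oe.design_lowpass_fir()


@pytest.fixture(scope="session")
def default_cohort():
    """The frozen default cohort: n=20, master seed 0."""
    return oe.generate_cohort(oe.SimulationConfig())


@pytest.fixture(scope="session")
def scored_cohort(default_cohort):
    """(events, score-series dict) per patient of the default cohort,
    through the full preprocess -> ordinal -> entropy chain.

    Session-scoped: this is the expensive end-to-end computation
    (~1.5 min) that several Monte-Carlo recovery tests share.
    """
    out = []
    for rec, ev in default_cohort:
        pre = oe.preprocess_recording(rec)
        out.append((ev, oe.score_recording(pre, patient_id=ev.patient_id)))
    return out


@pytest.fixture(scope="session")
def cohort_timepoint_samples(scored_cohort):
    """T1..T4 samples per score name, pooled over the cohort."""
    samples = {name: [] for name in oe.SCORE_NAMES}
    for ev, series in scored_cohort:
        for name in oe.SCORE_NAMES:
            samples[name].extend(oe.sample_timepoints(series[name], ev))
    return samples


def mean_in_window(series: oe.EntropyScoreSeries, t0: float, t1: float) -> float:
    mask = (series.timestamps_s >= t0) & (series.timestamps_s <= t1)
    assert mask.any(), f"no samples in [{t0}, {t1}]"
    return float(series.values[mask].mean())
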