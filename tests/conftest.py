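"""Shared fixtures: calibrations, small cohorts, noiseless parameter sets."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import clockdraw as cd
from clockdraw.metrics import compute_metrics

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def unimp_cmd():
    return cd.default_calibration("unimpaired", "command")


@pytest.fixture(scope="session")
def imp_cmd():
    return cd.default_calibration("impaired", "command")


def noiseless(params):
    """A deterministic-geometry variant: perfect circle, no tremor/jitter,
    no unexpected strokes."""
    return params.replace(
        circularity_med=0.0, circularity_q1=0.0, circularity_q3=0.0,
        tremor_amp_mm=0.0, digit_jitter_rad=0.0, hand_jitter_rad=0.0,
        radial_jitter_frac=0.0, hand_len_jitter=0.0,
        noise_rate=0.0, omission_rate=0.0, overwrite_rate=0.0, crossout_rate=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_cmd(unimp_cmd):
    return noiseless(unimp_cmd)


@pytest.fixture(scope="session")
def noiseless_drawing(noiseless_cmd):
    return cd.generate_drawing(noiseless_cmd, seed=42)


@pytest.fixture(scope="session")
def small_cohort():
    """44 subjects, both conditions, with truth-classified metric records."""
    subs = cd.generate_cohort(44, 0.5, seed=123)
    rows, labels = [], []
    for s in subs:
        mc = compute_metrics(cd.classified_from_truth(s.record.command, s.truth_command))
        mp = compute_metrics(cd.classified_from_truth(s.record.copy, s.truth_copy))
        rows.append((s.record.subject_id, mc, mp))
        labels.append(s.record.label)
    return subs, rows, np.array(labels)
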