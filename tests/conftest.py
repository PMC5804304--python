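"""Shared fixtures: synthetic eyes and traced results reused across tests.

Tracing is the expensive step (~1 s/eye), so traced eyes, cohorts and
templates are session-scoped.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from fiberflux.compensation import RgcDensityModel, compensation_map
from fiberflux.synthetic import SyntheticEyeSpec, default_family, generate_eye
from fiberflux.template import average_trajectories
from fiberflux.tracing import trace_iterate


@pytest.fixture(scope="session")
def family():
    return default_family()


@pytest.fixture(scope="session")
def gamma_map():
    spec = SyntheticEyeSpec()
    return compensation_map(default_family(), RgcDensityModel(),
                            spec.radii, spec.n_theta)


@pytest.fixture(scope="session")
def conserved_eye():
    """Noise-free flux-conserving eye (no macular termination)."""
    return generate_eye(SyntheticEyeSpec(seed=11, macular_termination=False,
                                         noise_sd_um=0.0))


@pytest.fixture(scope="session")
def conserved_trace(conserved_eye):
    return trace_iterate(conserved_eye.polar_thickness)


@pytest.fixture(scope="session")
def terminating_eye():
    """Noise-free eye with macular ganglion-cell flux loss."""
    return generate_eye(SyntheticEyeSpec(seed=12, macular_termination=True,
                                         noise_sd_um=0.0))


@pytest.fixture(scope="session")
def matched_pair():
    """A healthy eye and its defect twin (same trajectory, same seed)."""
    healthy_spec = SyntheticEyeSpec(seed=500, jitter_sd_deg=0.0, noise_sd_um=0.0)
    healthy = generate_eye(healthy_spec)
    defect = generate_eye(replace(healthy_spec, defects=[(10, 15, 0.4)]))
    return healthy, defect


@pytest.fixture(scope="session")
def matched_template(matched_pair, gamma_map):
    """Template traced from the healthy twin of the matched pair."""
    healthy, _ = matched_pair
    res = trace_iterate(healthy.polar_thickness, gamma=gamma_map)
    return average_trajectories([res.trajectory, res.trajectory])


@pytest.fixture(scope="session")
def healthy_cohort():
    """24 healthy eyes with 5 deg inter-eye jitter and 2 um noise."""
    base = SyntheticEyeSpec(seed=0, jitter_sd_deg=5.0, noise_sd_um=2.0)
    return [generate_eye(replace(base, seed=100 + i)) for i in range(24)]


@pytest.fixture(scope="session")
def cohort_traces(healthy_cohort, gamma_map):
    return [trace_iterate(e.polar_thickness, gamma=gamma_map)
            for e in healthy_cohort]


@pytest.fixture(scope="session")
def cohort_template(cohort_traces):
    return average_trajectories([t.trajectory for t in cohort_traces])
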