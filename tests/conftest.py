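"""Shared fixtures: simulated experiments and the in-memory pipeline helper."""

from __future__ import annotations

from datetime import timedelta

import pandas as pd
import pytest
from hypothesis import settings

import pneumatron as pn
from pneumatron.synthetic_device import DEFAULT_START

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def device() -> pn.DeviceConfig:
    return pn.DeviceConfig(tube_volume=2.6)


@pytest.fixture(scope="session")
def sample() -> pn.SampleModel:
    return pn.SampleModel()


def psi_observations(sample: pn.SampleModel, hours) -> pd.DataFrame:
    """Sparse water-potential record sampled from the true schedule."""
    rows = [{"datetime": DEFAULT_START + timedelta(hours=h),
             "psy": sample.psi_at(h * 3600.0)} for h in hours]
    return pd.DataFrame(rows)


def write_psi_csv(sample: pn.SampleModel, hours, path) -> None:
    obs = psi_observations(sample, hours)
    pd.DataFrame({
        "date": obs["datetime"].dt.strftime("%d/%m/%Y"),
        "hour": obs["datetime"].dt.strftime("%H:%M"),
        "psy": obs["psy"],
    }).to_csv(path, index=False)


def run_end_to_end(seed: int,
                   device: pn.DeviceConfig,
                   sample: pn.SampleModel,
                   duration_hours: float = 10.0,
                   psi_hours=(0, 2, 4, 6, 8, 10)) -> pn.AnalysisReport:
    """Simulate a dehydration experiment and run the full analysis in memory."""
    traces, _ = pn.simulate_dehydration_experiment(
        device, sample, duration_hours, rng_seed=seed)
    cycles = [pn.extract_endpoints(tr, vacuum_target=device.vacuum_target_abs)
              for tr in traces]
    analysis = pn.AnalysisConfig()
    return pn.analyze_frames(cycles, psi_observations(sample, psi_hours),
                             device, analysis)


@pytest.fixture(scope="session")
def default_report(device, sample) -> pn.AnalysisReport:
    """One analysed default experiment, shared across read-only tests."""
    return run_end_to_end(seed=7, device=device, sample=sample)
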