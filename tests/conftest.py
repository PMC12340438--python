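"""Shared fixtures: small random instances plus the (expensive) trained
benchmark runs reused across the synthetic-experiment tests."""

from __future__ import annotations

import numpy as np
import pytest

from seiznet import band_recovery_ratio, make_dataset, run_cycle
from seiznet.experiments import benchmark_model_config, benchmark_synth_config


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def band_dataset():
    """Benchmark data whose seizure signature is the planted 3-8 Hz band
    alone (high snr, no spike transients)."""
    return make_dataset(benchmark_synth_config(seed=0, signature="band"))


@pytest.fixture(scope="session")
def mixed_dataset():
    """Benchmark data mixing slow in-band bursts with fast spike transients
    at calibrated moderate difficulty."""
    return make_dataset(benchmark_synth_config(seed=0, signature="mixed"))


@pytest.fixture(scope="session")
def band_runs(band_dataset):
    """Five full-model train/test cycles on the band dataset (seeds 0..4).

    Shared session-wide because each cycle costs tens of CPU seconds; the
    band-recovery and classification tests both read from these runs.
    """
    synth_cfg = benchmark_synth_config(seed=0, signature="band")
    runs = []
    for seed in range(5):
        res = run_cycle(benchmark_model_config(), band_dataset, seed,
                        return_model=True)
        res["band_ratio"] = band_recovery_ratio(
            res["model"], band_dataset.segments[res["test_indices"]], synth_cfg)
        del res["model"]  # free the graph-bearing parameters
        runs.append(res)
    return runs


@pytest.fixture(scope="session")
def ablation_runs(mixed_dataset):
    """Full model and the three ablations, five seeds each, on the mixed
    dataset — the scaled ablation-ordering experiment."""
    out = {}
    for variant in ("ORI", "AB1", "AB2", "AB3"):
        cfg = benchmark_model_config(variant=variant)
        out[variant] = [run_cycle(cfg, mixed_dataset, seed)["report"]
                        for seed in range(5)]
    return out
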