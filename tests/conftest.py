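import pandas as pd
import pytest

from crcsurgval.cohort import apply_inclusion
from crcsurgval.linkage import LinkageWindow, link_cohort
from crcsurgval.simulate import GeneratorConfig, default_code_list, generate_cohort


def identity_config(n_patients: int = 400, seed: int = 5) -> GeneratorConfig:
    """Perfect observation: every registry surgery appears, same date, in
    both sources; no false positives, no registry-only events."""
    zero = {s: 0.0 for s in ("I", "II", "III", "IV", "missing")}
    return GeneratorConfig(
        n_patients=n_patients,
        source_capture_prob={"billing": 1.0, "hospital": 1.0},
        false_positive_prob={"billing": dict(zero), "hospital": dict(zero)},
        registry_only_prob=dict(zero),
        date_jitter_prob=0.0,
        rng_seed=seed,
    )


def pipeline_linkage(config: GeneratorConfig) -> pd.DataFrame:
    """Generator -> cohort -> linkage table, with the synthetic code list."""
    ds = generate_cohort(config)
    registry = ds.registry.copy()
    registry["dx_date"] = pd.to_datetime(registry["dx_date"])
    registry["surgery_date"] = pd.to_datetime(registry["surgery_date"].replace("", pd.NA))
    billing, hospital = ds.billing.copy(), ds.hospital.copy()
    for df in (billing, hospital):
        df["service_date"] = pd.to_datetime(df["service_date"])
    cohort, _ = apply_inclusion(registry)
    return link_cohort(cohort, billing, hospital, LinkageWindow(), default_code_list())


@pytest.fixture(scope="session")
def default_datasets():
    """A mid-sized cohort under the default (study-structure) configuration."""
    return generate_cohort(GeneratorConfig(n_patients=2000, rng_seed=11))


@pytest.fixture(scope="session")
def default_linkage():
    return pipeline_linkage(GeneratorConfig(n_patients=2000, rng_seed=11))


@pytest.fixture(scope="session")
def recovery_datasets():
    """Large cohort for parameter-recovery checks: no registry-only events,
    so per-source sensitivity estimates the configured capture probability."""
    zero = {s: 0.0 for s in ("I", "II", "III", "IV", "missing")}
    config = GeneratorConfig(
        n_patients=20_000,
        registry_only_prob=dict(zero),
        rng_seed=42,
    )
    return config, generate_cohort(config)


@pytest.fixture(scope="session")
def recovery_linkage(recovery_datasets):
    config, _ = recovery_datasets
    return config, pipeline_linkage(config)
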