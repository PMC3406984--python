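"""Synthetic linked-cohort generator: determinism, invariants, recovery."""

import math

import numpy as np
import pandas as pd
import pytest

from crcsurgval.measures import compute_measures, cross_tabulate, date_agreement
from crcsurgval.simulate import GeneratorConfig, generate_cohort
from conftest import identity_config, pipeline_linkage


def test_zero_patients_gives_empty_datasets():
    ds = generate_cohort(GeneratorConfig(n_patients=0))
    assert len(ds.registry) == len(ds.billing) == len(ds.hospital) == 0
    assert len(ds.truth_log) == 0


def test_bitwise_determinism_given_seed(tmp_path):
    config = GeneratorConfig(n_patients=250, rng_seed=99)
    a, b = generate_cohort(config), generate_cohort(config)
    for name in ("registry", "billing", "hospital", "truth_log"):
        pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))
    a.write_csvs(tmp_path / "a")
    b.write_csvs(tmp_path / "b")
    for name in ("registry", "billing", "hospital", "truth_log"):
        assert (tmp_path / "a" / f"{name}.csv").read_bytes() == (
            tmp_path / "b" / f"{name}.csv"
        ).read_bytes()


def test_different_seed_changes_output():
    a = generate_cohort(GeneratorConfig(n_patients=250, rng_seed=1))
    b = generate_cohort(GeneratorConfig(n_patients=250, rng_seed=2))
    assert not a.registry.equals(b.registry)


def test_every_claim_links_to_a_registry_row():
    ds = generate_cohort(GeneratorConfig(n_patients=500, rng_seed=3))
    registry_ulis = set(ds.registry["uli"]) - {""}
    for claims in (ds.billing, ds.hospital):
        assert set(claims["uli"]) <= registry_ulis


def test_truth_log_covers_every_patient_once():
    config = GeneratorConfig(n_patients=500, rng_seed=3)
    ds = generate_cohort(config)
    assert len(ds.truth_log) == config.n_patients
    assert ds.truth_log["uli"].is_unique


def test_coding_system_consistent_with_service_date():
    ds = generate_cohort(GeneratorConfig(n_patients=800, rng_seed=4))
    assert (ds.billing["coding_system"] == "CCP").all()
    hosp = ds.hospital.copy()
    before = pd.to_datetime(hosp["service_date"]) < pd.Timestamp("2002-04-01")
    assert (hosp.loc[before, "coding_system"] == "ICD9CM").all()
    assert (hosp.loc[~before, "coding_system"] == "CCI").all()


def test_identity_configuration_yields_perfect_pipeline():
    """Capture 1, no false positives, no registry-only events, no jitter:
    every registry surgery has a same-date claim in both sources and every
    defined downstream measure is 100%."""
    rows = pipeline_linkage(identity_config(n_patients=300, seed=5))
    with_surgery = rows[rows["registry_flag"]]
    for source in ("billing", "hospital", "combined"):
        assert (
            with_surgery[f"{source}_date"] == with_surgery["registry_date"]
        ).all()
        vm = compute_measures(cross_tabulate(rows, source))
        for m, pct in vm.as_percent_dict().items():
            assert pct in (100, None)
        assert date_agreement(rows, source).exact_match_fraction == 1.0


def test_invalid_configurations_are_rejected():
    with pytest.raises(ValueError):
        GeneratorConfig(date_jitter_prob=1.5)
    with pytest.raises(ValueError):
        GeneratorConfig(year_range=(2005, 2000))
    with pytest.raises(ValueError):
        GeneratorConfig(stage_distribution={"I": 0.5, "II": 0.5})
    with pytest.raises(ValueError):
        GeneratorConfig(delay_min=-30)
    bad_sites = {"colon": 0.8, "rectum": 0.1}
    with pytest.raises(ValueError):
        GeneratorConfig(site_distribution=bad_sites)


def test_sensitivity_recovers_configured_capture_probability(recovery_linkage):
    """With registry-only events off, per-source pipeline sensitivity is a
    binomial estimate of the configured capture probability; at n = 20,000 it
    must sit within 3 binomial standard errors."""
    config, rows = recovery_linkage
    for source in ("billing", "hospital"):
        p = config.source_capture_prob[source]
        t = cross_tabulate(rows, source)
        n_pos = t.tp + t.fn
        est = t.tp / n_pos
        se = math.sqrt(p * (1 - p) / n_pos)
        assert abs(est - p) <= 3 * se, f"{source}: {est} vs {p} (3SE={3*se:.4f})"


def test_date_jitter_fraction_recovers_configured_probability(recovery_linkage):
    """The fraction of administrative dates differing from the registry date
    among captured surgeries converges to date_jitter_prob."""
    config, rows = recovery_linkage
    p = config.date_jitter_prob
    for source in ("billing", "hospital"):
        da = date_agreement(rows, source)
        se = math.sqrt(p * (1 - p) / da.n_pairs)
        assert abs((1 - da.exact_match_fraction) - p) <= 3 * se


def test_registry_only_mechanism_lowers_sensitivity_not_prevalence():
    """Suppressing the administrative counterpart (polypectomy mechanism)
    leaves registry prevalence alone but removes claims from both sources."""
    base = identity_config(n_patients=2000, seed=21)
    suppressed = identity_config(n_patients=2000, seed=21)
    suppressed.registry_only_prob = {s: (0.5 if s == "I" else 0.0)
                                     for s in ("I", "II", "III", "IV", "missing")}
    suppressed.__post_init__()
    rows_base = pipeline_linkage(base)
    rows_sup = pipeline_linkage(suppressed)
    stage1_base = rows_base[rows_base["stage"] == "I"]
    stage1_sup = rows_sup[rows_sup["stage"] == "I"]
    assert stage1_base["registry_flag"].mean() == stage1_sup["registry_flag"].mean()
    t_base = cross_tabulate(rows_base, "billing", stratum=("stage", "I"))
    t_sup = cross_tabulate(rows_sup, "billing", stratum=("stage", "I"))
    sens_base = t_base.tp / (t_base.tp + t_base.fn)
    sens_sup = t_sup.tp / (t_sup.tp + t_sup.fn)
    assert sens_sup < sens_base - 0.25


def test_false_positive_correlation_couples_sources():
    """With correlation 1 the palliative event is shared: among registry-
    negative stage-IV patients, hospital false positives are (almost) a
    subset of billing false positives, since the billing probability
    dominates; with correlation 0 the overlap is strictly smaller on the
    same seed."""
    def fp_overlap(rho, seed=31):
        cfg = GeneratorConfig(n_patients=4000, fp_correlation=rho, rng_seed=seed)
        ds = generate_cohort(cfg)
        log = ds.truth_log
        neg = log[~log["latent_surgery"] & (log["stage"] == "IV")]
        both = (neg["billing_fp"] & neg["hospital_fp"]).sum()
        return both, int(neg["hospital_fp"].sum())

    both_corr, hosp_corr = fp_overlap(1.0)
    both_ind, hosp_ind = fp_overlap(0.0)
    assert both_corr == hosp_corr  # comonotone: hospital FP implies billing FP
    assert both_ind < hosp_ind


def test_jittered_dates_stay_inside_the_window():
    cfg = GeneratorConfig(n_patients=3000, date_jitter_prob=1.0,
                          date_jitter_range=(-10, 10), rng_seed=8)
    ds = generate_cohort(cfg)
    registry = ds.registry.set_index("uli")
    for claims in (ds.billing, ds.hospital):
        merged = claims.join(registry[["dx_date"]], on="uli")
        offsets = (
            pd.to_datetime(merged["service_date"]) - pd.to_datetime(merged["dx_date"])
        ).dt.days
        assert offsets.between(-7, 548).all()


def test_yaml_config_round_trip(tmp_path):
    cfg = GeneratorConfig(n_patients=123, rng_seed=7, date_jitter_prob=0.2)
    path = tmp_path / "gen.yaml"
    cfg.to_yaml(path)
    loaded = GeneratorConfig.from_yaml(path)
    assert loaded == cfg
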