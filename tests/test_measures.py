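"""Validation measures, Wilson intervals, instability flags, date agreement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crcsurgval.measures import (
    ContingencyTable,
    compute_measures,
    cross_tabulate,
    date_agreement,
    flag_instability,
    proportion_ci,
)
from crcsurgval.simulate import GeneratorConfig
from conftest import pipeline_linkage


def test_cross_tabulate_single_true_positive():
    rows = pd.DataFrame(
        {
            "registry_flag": [True],
            "billing_date": [pd.Timestamp("2003-07-01")],
            "dx_year": [2003],
            "stage": ["II"],
            "tumor_site": ["colon"],
        }
    )
    t = cross_tabulate(rows, "billing")
    assert (t.tp, t.fp, t.fn, t.tn) == (1, 0, 0, 0)


def test_cross_tabulate_rejects_unknown_source():
    rows = pd.DataFrame({"registry_flag": [True], "billing_date": [None]})
    with pytest.raises(ValueError):
        cross_tabulate(rows, "registry")


def test_cross_tabulate_matches_row_by_row_oracle():
    """Counts equal an independent per-row classification on a 200-patient
    synthetic cohort, overall and per stratum."""
    rows = pipeline_linkage(GeneratorConfig(n_patients=200, rng_seed=17))
    for source in ("billing", "hospital", "combined"):
        for stratum in [None, ("stage", "IV"), ("site", "rectum"), ("year", 2003)]:
            sub = rows
            if stratum is not None:
                factor, level = stratum
                col = {"stage": "stage", "site": "tumor_site", "year": "dx_year"}[factor]
                sub = rows[rows[col] == level]
            tp = fp = fn = tn = 0
            for _, r in sub.iterrows():
                truth = bool(r["registry_flag"])
                test = r[f"{source}_date"] is not None and pd.notna(r[f"{source}_date"])
                if truth and test:
                    tp += 1
                elif test:
                    fp += 1
                elif truth:
                    fn += 1
                else:
                    tn += 1
            t = cross_tabulate(rows, source, stratum=stratum)
            assert (t.tp, t.fp, t.fn, t.tn) == (tp, fp, fn, tn)


def test_whole_percent_report_of_reconstructed_overall_table():
    vm = compute_measures(ContingencyTable(tp=6825, fp=348, fn=241, tn=894))
    assert vm.as_percent_dict() == {
        "sensitivity": 97,
        "specificity": 72,
        "ppv": 95,
        "npv": 79,
        "agreement": 93,
    }


def test_perfect_table_all_measures_100():
    vm = compute_measures(ContingencyTable(10, 0, 0, 5))
    assert all(vm[m].as_percent() == 100 for m in vm.as_percent_dict())


def test_zero_denominators_reported_as_undefined_not_zero():
    vm = compute_measures(ContingencyTable(0, 0, 0, 25))
    assert not vm.sensitivity.defined and not vm.ppv.defined
    assert vm.sensitivity.as_percent() is None
    assert vm.specificity.as_percent() == 100
    assert vm.npv.as_percent() == 100
    assert vm.agreement.as_percent() == 100


def test_empty_table_is_an_error():
    with pytest.raises(ValueError):
        compute_measures(ContingencyTable(0, 0, 0, 0))


def test_wilson_interval_boundaries_and_midpoint():
    lo, hi = proportion_ci(0, 50)
    assert lo == 0.0 and 0 < hi < 1
    lo, hi = proportion_ci(50, 100)
    assert lo == pytest.approx(0.404, abs=5e-4)
    assert hi == pytest.approx(0.596, abs=5e-4)
    lo, hi = proportion_ci(50, 50)
    assert hi == 1.0
    with pytest.raises(ValueError):
        proportion_ci(5, 0)
    with pytest.raises(ValueError):
        proportion_ci(6, 5)


def test_wald_option_differs_from_wilson_off_boundary():
    w = proportion_ci(45, 50, method="wilson")
    d = proportion_ci(45, 50, method="wald")
    assert w != d


def test_instability_flag_clauses():
    assert flag_instability(86, (78, 94))  # width 16 > 15 points
    assert flag_instability(30, (25, 37))  # width 12 >= 0.4 * 30, at equality
    assert not flag_instability(95, (93, 97))  # width 4, neither clause


def test_wilson_coverage_near_nominal():
    """Empirical coverage of the 95% Wilson interval at p=0.8, n=100 over
    1,000 replicates lies in [93%, 97%]."""
    rng = np.random.default_rng(2024)
    p, n, reps = 0.8, 100, 1000
    covered = 0
    for x in rng.binomial(n, p, size=reps):
        lo, hi = proportion_ci(int(x), n)
        covered += lo <= p <= hi
    assert 0.93 <= covered / reps <= 0.97


tables = st.tuples(
    st.integers(0, 400), st.integers(0, 400), st.integers(0, 400), st.integers(0, 400)
).filter(lambda t: sum(t) > 0)


@given(tables)
@settings(max_examples=150, deadline=None, derandomize=True)
def test_bayes_and_complement_identities(cells):
    """ppv = sens*pi / (sens*pi + (1-spec)(1-pi)) and
    agreement = sens*pi + spec*(1-pi), to 1e-12, whenever defined."""
    t = ContingencyTable(*cells)
    vm = compute_measures(t)
    pi = (t.tp + t.fn) / t.n
    if vm.sensitivity.defined and vm.specificity.defined and vm.ppv.defined:
        num = vm.sensitivity.value * pi
        den = num + (1 - vm.specificity.value) * (1 - pi)
        if den > 0:
            assert abs(vm.ppv.value - num / den) < 1e-12
    if vm.sensitivity.defined and vm.specificity.defined:
        assert abs(
            vm.agreement.value
            - (vm.sensitivity.value * pi + vm.specificity.value * (1 - pi))
        ) < 1e-12


@given(tables)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_adding_a_true_positive_never_decreases_key_measures(cells):
    t = ContingencyTable(*cells)
    t2 = ContingencyTable(t.tp + 1, t.fp, t.fn, t.tn)
    vm, vm2 = compute_measures(t), compute_measures(t2)
    for m in ("sensitivity", "ppv", "agreement"):
        if vm[m].defined:
            assert vm2[m].value >= vm[m].value - 1e-15


def test_date_agreement_all_exact():
    rows = pd.DataFrame(
        {
            "registry_flag": [True] * 3,
            "registry_date": pd.to_datetime(["2003-07-01"] * 3),
            "billing_date": pd.to_datetime(["2003-07-01"] * 3),
        }
    )
    da = date_agreement(rows, "billing")
    assert da.exact_match_fraction == 1.0
    assert da.difference_histogram == {0: 3}


def test_date_agreement_fraction_and_histogram():
    dates = ["2003-07-01"] * 9 + ["2003-07-04"]
    rows = pd.DataFrame(
        {
            "registry_flag": [True] * 10,
            "registry_date": pd.to_datetime(["2003-07-01"] * 10),
            "billing_date": pd.to_datetime(dates),
        }
    )
    da = date_agreement(rows, "billing")
    assert da.n_pairs == 10
    assert da.exact_match_fraction == pytest.approx(0.9)
    assert da.difference_histogram == {0: 9, 3: 1}
    assert sum(da.difference_histogram.values()) == da.n_pairs


def test_date_agreement_empty_is_undefined():
    rows = pd.DataFrame(
        {"registry_flag": [], "registry_date": [], "billing_date": []}
    )
    da = date_agreement(rows, "billing")
    assert da.n_pairs == 0 and da.exact_match_fraction is None
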