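"""End-to-end pipeline orchestration and stratified reports.

Two report tables are produced, mirroring how validation studies of
administrative surgery data present results:

- a *count* report: per stratum, the number (and whole percent) of patients
  with surgery according to the registry, each administrative source, and the
  combined administrative dataset;
- a *measures* report: sensitivity, specificity, PPV, NPV and observed
  agreement per stratum and source, with 95% CIs and instability flags.

Strata are overall, calendar year of diagnosis, stage at diagnosis (missing
stage is its own stratum, since those patients stay in the cohort), and tumor
site. Row order is fixed (all -> year -> stage -> site; levels ascending,
stages I, II, III, IV, missing) so identical inputs produce byte-identical
reports.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import List, Optional, Tuple

import pandas as pd

from crcsurgval import cohort as cohort_mod
from crcsurgval import linkage as linkage_mod
from crcsurgval.measures import (
    SOURCES,
    compute_measures,
    cross_tabulate,
    date_agreement,
    measures_to_tidy_row,
)
from crcsurgval.rounding import percent
from crcsurgval.simulate import GeneratorConfig, default_code_list, generate_cohort

logger = logging.getLogger(__name__)

STAGE_ORDER = ("I", "II", "III", "IV", "missing")


def render_percent(count: int, denom: int, convention: str = "half-up") -> int:
    """Whole-percent rendering of a count over a denominator (>= 1)."""
    return percent(count, denom, convention)


@dataclass
class RunConfig:
    """One pipeline run: either three CSV paths + a code list, or a generator.

    Exactly one of (``registry_path``..., ``generator``) must be given.
    """

    registry_path: Optional[str] = None
    billing_path: Optional[str] = None
    hospital_path: Optional[str] = None
    code_list_path: Optional[str] = None
    generator: Optional[GeneratorConfig] = None
    window_lower: int = -7
    window_upper: int = 548
    ci_method: str = "wilson"
    rounding: str = "half-up"
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        has_paths = self.registry_path is not None
        has_gen = self.generator is not None
        if has_paths == has_gen:
            raise ValueError("exactly one of input paths or a generator config is required")
        if has_paths and None in (self.billing_path, self.hospital_path):
            raise ValueError("billing_path and hospital_path are required with registry_path")


def _strata(linkage_rows: pd.DataFrame) -> List[Tuple[str, str]]:
    """Fixed-order stratum keys drawn from the cohort's own values."""
    strata: List[Tuple[str, str]] = [("all", "all")]
    strata += [("year", str(y)) for y in sorted(linkage_rows["dx_year"].unique())]
    present_stages = set(linkage_rows["stage"].unique())
    strata += [("stage", s) for s in STAGE_ORDER if s in present_stages]
    strata += [
        ("site", s) for s in ("colon", "rectum") if s in set(linkage_rows["tumor_site"])
    ]
    return strata


def _stratum_rows(linkage_rows: pd.DataFrame, factor: str, level: str) -> pd.DataFrame:
    if factor == "all":
        return linkage_rows
    if factor == "year":
        return linkage_rows[linkage_rows["dx_year"] == int(level)]
    if factor == "stage":
        return linkage_rows[linkage_rows["stage"] == level]
    return linkage_rows[linkage_rows["tumor_site"] == level]


def build_table1(linkage_rows: pd.DataFrame, convention: str = "half-up") -> pd.DataFrame:
    """Per-stratum surgery counts and whole percents per data source."""
    rows = []
    for factor, level in _strata(linkage_rows):
        sub = _stratum_rows(linkage_rows, factor, level)
        n = len(sub)
        row = {"stratum_factor": factor, "stratum_level": level, "n": n}
        row["registry_n"] = int(sub["registry_flag"].sum())
        row["registry_pct"] = render_percent(row["registry_n"], n, convention) if n else None
        for source in SOURCES:
            cnt = int(sub[f"{source}_date"].notna().sum())
            row[f"{source}_n"] = cnt
            row[f"{source}_pct"] = render_percent(cnt, n, convention) if n else None
        rows.append(row)
    return pd.DataFrame(rows)


def build_table2(
    linkage_rows: pd.DataFrame, ci_method: str = "wilson", level: float = 0.95
) -> pd.DataFrame:
    """Tidy per-stratum, per-source validation measures with CIs and flags."""
    rows = []
    for factor, lev in _strata(linkage_rows):
        for source in SOURCES:
            table = cross_tabulate(linkage_rows, source, stratum=(factor, lev))
            if table.n == 0:
                continue
            vm = compute_measures(table, level=level, ci_method=ci_method)
            rows.extend(measures_to_tidy_row(factor, lev, source, vm))
    return pd.DataFrame(rows)


def build_date_report(linkage_rows: pd.DataFrame) -> pd.DataFrame:
    """Exact-match fraction of administrative vs registry dates per source."""
    rows = []
    for source in SOURCES:
        da = date_agreement(linkage_rows, source)
        rows.append(
            {
                "source": source,
                "n_pairs": da.n_pairs,
                "exact_match_fraction": da.exact_match_fraction,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig):
    """Run cohort construction, linkage and reporting end to end.

    Returns ``(table1_report, table2_report, date_report, tally)``; also
    writes them (plus the linkage table) as CSV under ``out_dir`` when set.
    """
    if config.generator is not None:
        datasets = generate_cohort(config.generator)
        registry = datasets.registry.copy()
        registry["dx_date"] = pd.to_datetime(registry["dx_date"])
        registry["surgery_date"] = pd.to_datetime(
            registry["surgery_date"].replace("", pd.NA)
        )
        billing = datasets.billing.copy()
        hospital = datasets.hospital.copy()
        for df in (billing, hospital):
            df["service_date"] = pd.to_datetime(df["service_date"])
        codes = default_code_list()
    else:
        registry = cohort_mod.read_registry_csv(config.registry_path)
        billing = linkage_mod.read_claims_csv(config.billing_path, "billing")
        hospital = linkage_mod.read_claims_csv(config.hospital_path, "hospital")
        codes = (
            linkage_mod.CodeList.from_csv(config.code_list_path)
            if config.code_list_path
            else default_code_list()
        )

    cohort, tally = cohort_mod.apply_inclusion(registry)
    window = linkage_mod.LinkageWindow(config.window_lower, config.window_upper)
    linkage_rows = linkage_mod.link_cohort(cohort, billing, hospital, window, codes)

    table1 = build_table1(linkage_rows, convention=config.rounding)
    table2 = build_table2(linkage_rows, ci_method=config.ci_method)
    dates = build_date_report(linkage_rows)

    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        linkage_out = linkage_rows.copy()
        linkage_out.to_csv(os.path.join(config.out_dir, "linkage.csv"), index=False)
        table1.to_csv(os.path.join(config.out_dir, "table1_counts.csv"), index=False)
        table2.to_csv(os.path.join(config.out_dir, "table2_measures.csv"), index=False)
        dates.to_csv(os.path.join(config.out_dir, "date_agreement.csv"), index=False)
        cohort_mod.write_tally_csv(tally, os.path.join(config.out_dir, "exclusion_tally.csv"))
        with open(os.path.join(config.out_dir, "report.txt"), "w") as fh:
            fh.write(render_text_report(table1, table2, dates, tally))

    return table1, table2, dates, tally


def render_text_report(table1, table2, dates, tally) -> str:
    """Human-readable rendering of the three reports."""
    lines = []
    lines.append("Cohort construction")
    lines.append("-" * 70)
    lines.append(
        f"input records: {tally.n_input}; out-of-scope site: "
        f"{tally.n_nonqualifying_site}; missing ULI: {tally.n_missing_uli}; "
        f"unstageable: {tally.n_unstageable}; stage 0: {tally.n_stage0}; "
        f"included: {tally.n_included}"
    )
    lines.append("")
    lines.append("Surgery patients identified by data source (count report)")
    lines.append("-" * 70)
    lines.append(table1.to_string(index=False))
    lines.append("")
    lines.append("Validation measures vs registry (whole percent, 95% CI)")
    lines.append("-" * 70)
    t2 = table2.copy()
    for col in ("estimate_pct", "ci_low_pct", "ci_high_pct"):
        t2[col] = t2[col].map(lambda v: f"{v:.1f}" if pd.notna(v) else "--")
    lines.append(t2.to_string(index=False))
    lines.append("")
    lines.append("Surgery-date agreement on true positives")
    lines.append("-" * 70)
    lines.append(dates.to_string(index=False))
    lines.append("")
    return "\n".join(lines)
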