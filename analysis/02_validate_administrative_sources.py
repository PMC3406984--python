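"""Validate the synthetic administrative sources against registry truth.

Reads the CSVs written by 01_simulate_cohort.py, applies the inclusion rules,
links first qualifying surgeries within the [-7, +548]-day window, and writes
the stratified count report, measure report (with Wilson CIs and instability
flags) and surgery-date agreement under results/reports/.
"""

import pathlib

from crcsurgval.report import RunConfig, run_pipeline

ROOT = pathlib.Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "synthetic"
OUT = ROOT / "results" / "reports"


def main() -> None:
    config = RunConfig(
        registry_path=str(DATA / "registry.csv"),
        billing_path=str(DATA / "billing.csv"),
        hospital_path=str(DATA / "hospital.csv"),
        out_dir=str(OUT),
    )
    table1, table2, dates, tally = run_pipeline(config)

    print(
        f"cohort: {tally.n_included}/{tally.n_input} included "
        f"({tally.n_missing_uli} missing ULI, {tally.n_unstageable} unstageable, "
        f"{tally.n_stage0} stage 0 excluded)"
    )
    overall = table1[table1["stratum_factor"] == "all"].iloc[0]
    print(
        "surgery identified overall: "
        f"registry {overall['registry_n']} ({overall['registry_pct']}%), "
        f"billing {overall['billing_n']} ({overall['billing_pct']}%), "
        f"hospital {overall['hospital_n']} ({overall['hospital_pct']}%), "
        f"combined {overall['combined_n']} ({overall['combined_pct']}%)"
    )
    ov = table2[(table2["stratum_factor"] == "all") & table2["defined"]]
    for source in ("billing", "hospital", "combined"):
        row = {r["measure"]: r["estimate_pct"] for _, r in ov[ov["source"] == source].iterrows()}
        print(
            f"{source:>9}: sens {row['sensitivity']:.0f}%, spec {row['specificity']:.0f}%, "
            f"ppv {row['ppv']:.0f}%, npv {row['npv']:.0f}%, agreement {row['agreement']:.0f}%"
        )
    for _, r in dates.iterrows():
        print(
            f"date agreement {r['source']:>9}: {100 * r['exact_match_fraction']:.1f}% "
            f"exact of {r['n_pairs']} pairs"
        )
    print(f"reports written to {OUT}")


if __name__ == "__main__":
    main()
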