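"""Analysis-cohort construction: inclusion/exclusion of registry records.

The analysis cohort is every invasive colorectal cancer diagnosis (ICD-O
topography c18.0, c18.2–c18.9 for colon; c19.9, c20.9 for rectum) except
records that cannot be linked or validly staged:

1. missing the unique lifetime identifier (ULI) needed for linkage,
2. a histology outside the staging rules (flagged, not re-derived here),
3. stage 0 (in-situ) disease.

Records whose stage is missing for any *other* reason stay in the cohort and
form the "missing" stage stratum. Exclusion reasons are applied in the fixed
priority order above so each record is counted exactly once; records with
non-colorectal site codes are out-of-scope input and tallied in a separate
bucket.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Tuple

import pandas as pd

logger = logging.getLogger(__name__)

#: qualifying ICD-O topography codes (lower-case; matching is case-insensitive)
COLON_SITE_CODES = frozenset({"c18.0"} | {f"c18.{i}" for i in range(2, 10)})
RECTUM_SITE_CODES = frozenset({"c19.9", "c20.9"})
QUALIFYING_SITE_CODES = COLON_SITE_CODES | RECTUM_SITE_CODES

VALID_STAGES = ("0", "I", "II", "III", "IV")

REGISTRY_COLUMNS = [
    "uli",
    "dx_date",
    "site_code",
    "stage",
    "histology_stageable",
    "surgery_date",
]


@dataclass(frozen=True)
class ExclusionTally:
    """Counts of records removed from the input, by (prioritised) reason."""

    n_input: int
    n_nonqualifying_site: int
    n_missing_uli: int
    n_unstageable: int
    n_stage0: int
    n_included: int

    @property
    def n_excluded(self) -> int:
        """Exclusions among in-scope (colorectal-site) records."""
        return self.n_missing_uli + self.n_unstageable + self.n_stage0

    def __post_init__(self) -> None:
        expected = (
            self.n_input
            - self.n_nonqualifying_site
            - self.n_missing_uli
            - self.n_unstageable
            - self.n_stage0
        )
        if self.n_included != expected:
            raise ValueError("tally buckets do not partition the input")


def tumor_site(site_code: str) -> str:
    """Map an ICD-O topography code to 'colon' or 'rectum'; raise otherwise."""
    code = str(site_code).strip().lower()
    if code in COLON_SITE_CODES:
        return "colon"
    if code in RECTUM_SITE_CODES:
        return "rectum"
    raise ValueError(f"non-colorectal site code {site_code!r}")


def _normalise_stage(value, row_index) -> str:
    """Canonical stage level; '' denotes missing. Raises on garbage."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    s = str(value).strip()
    if s == "" or s.lower() in ("missing", "nan", "na"):
        return ""
    su = s.upper()
    if su in VALID_STAGES:
        return su
    raise ValueError(f"row {row_index}: unparseable stage value {value!r}")


def _missing_uli(value) -> bool:
    return pd.isna(value) or str(value).strip() == ""


def apply_inclusion(records: pd.DataFrame) -> Tuple[pd.DataFrame, ExclusionTally]:
    """Apply the inclusion/exclusion rules to raw registry records.

    Returns the analysis cohort (with a derived ``tumor_site`` column and
    canonicalised ``stage``, missing as '') and the exclusion tally.
    Exclusion priority: out-of-scope site -> missing ULI -> unstageable
    histology -> stage 0; each record lands in exactly one bucket or in the
    cohort.
    """
    records = records.reset_index(drop=True)
    n_input = len(records)
    if n_input == 0:
        tally = ExclusionTally(0, 0, 0, 0, 0, 0)
        return records.assign(tumor_site=pd.Series(dtype=object)), tally

    stages = pd.Series(
        [_normalise_stage(v, i) for i, v in enumerate(records["stage"])],
        index=records.index,
    )
    site_lc = records["site_code"].astype(str).str.strip().str.lower()
    qualifying = site_lc.isin(QUALIFYING_SITE_CODES)
    missing_uli = records["uli"].map(_missing_uli)
    stageable = records["histology_stageable"].map(_parse_bool)
    stage0 = stages == "0"

    in_scope = qualifying
    excl_uli = in_scope & missing_uli
    excl_unstageable = in_scope & ~excl_uli & ~stageable
    excl_stage0 = in_scope & ~excl_uli & ~excl_unstageable & stage0
    included = in_scope & ~excl_uli & ~excl_unstageable & ~excl_stage0

    cohort = records[included].copy()
    cohort["stage"] = stages[included]
    cohort["tumor_site"] = site_lc[included].map(
        lambda c: "colon" if c in COLON_SITE_CODES else "rectum"
    )

    tally = ExclusionTally(
        n_input=n_input,
        n_nonqualifying_site=int((~qualifying).sum()),
        n_missing_uli=int(excl_uli.sum()),
        n_unstageable=int(excl_unstageable.sum()),
        n_stage0=int(excl_stage0.sum()),
        n_included=int(included.sum()),
    )
    logger.info(
        "cohort: %d input, %d out-of-scope site, %d missing ULI, %d unstageable, "
        "%d stage 0, %d included",
        tally.n_input,
        tally.n_nonqualifying_site,
        tally.n_missing_uli,
        tally.n_unstageable,
        tally.n_stage0,
        tally.n_included,
    )
    return cohort.reset_index(drop=True), tally


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if pd.isna(value):
        return False
    s = str(value).strip().lower()
    if s in ("true", "1", "yes", "t"):
        return True
    if s in ("false", "0", "no", "f"):
        return False
    raise ValueError(f"unparseable boolean {value!r}")


def read_registry_csv(path) -> pd.DataFrame:
    """Read a registry CSV (ISO-8601 dates; missing surgery date allowed)."""
    df = pd.read_csv(path, dtype={"uli": str, "site_code": str, "stage": str})
    missing = set(REGISTRY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: registry CSV missing columns {sorted(missing)}")
    for col in ("dx_date", "surgery_date"):
        df[col] = pd.to_datetime(df[col], format="%Y-%m-%d", errors="raise")
    return df


def write_tally_csv(tally: ExclusionTally, path) -> None:
    pd.DataFrame([tally.__dict__]).to_csv(path, index=False)
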