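"""First-surgery selection in administrative claims and source combination.

For each cohort patient and each administrative source, the earliest claim
bearing a qualifying colorectal-surgery procedure code whose service date
falls within a diagnosis-anchored window — from 7 days before to 548 days
(1.5 years) after diagnosis, both ends inclusive — is taken as that source's
surgery event.  The first claim is expected to be the primary-tumor resection;
later claims are typically reconstruction or stoma procedures.

The combined administrative dataset is the union of the two sources: a date
present in only one source is kept as-is, and when both sources have events
the earlier date wins (tagged 'combined' when the dates coincide).

Registry truth is deliberately *not* windowed: the registry's surgery date is
the gold standard wherever it falls; the window governs only the
administrative extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Dict, FrozenSet, Iterable, Optional

import pandas as pd

logger = logging.getLogger(__name__)

CLAIM_COLUMNS = ["uli", "service_date", "proc_code", "coding_system"]

#: coding systems by source; hospital switched schemes in April 2002
CODING_SYSTEMS = ("CCP", "ICD9CM", "CCI")
HOSPITAL_CODING_SWITCH = date(2002, 4, 1)


@dataclass(frozen=True)
class LinkageWindow:
    """Diagnosis-anchored eligibility window for administrative claims, in days.

    The default lower bound (−7) absorbs small date inaccuracies in billing
    claims; the upper bound (+548, 1.5 years) is the maximum observed
    diagnosis-to-surgery delay. Both ends are inclusive.
    """

    lower_offset: int = -7
    upper_offset: int = 548

    def __post_init__(self) -> None:
        if self.lower_offset >= self.upper_offset:
            raise ValueError("lower_offset must be < upper_offset")

    def contains(self, dx_date: date, service_date: date) -> bool:
        offset = (service_date - dx_date).days
        return self.lower_offset <= offset <= self.upper_offset


@dataclass(frozen=True)
class SurgeryEvent:
    """The selected first qualifying surgery for one patient in one source."""

    uli: str
    date: date
    source: str  # billing | hospital | combined
    proc_code: str


@dataclass(frozen=True)
class CodeList:
    """Qualifying procedure codes per coding system.

    The real code lists are study configuration (they differ by coding scheme
    and jurisdiction); any non-empty mapping works, e.g.
    ``CodeList({'CCP': {'SURG01'}, 'ICD9CM': {'SURG01'}, 'CCI': {'SURG01'}})``.
    """

    codes: Dict[str, FrozenSet[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "codes",
            {k: frozenset(v) for k, v in self.codes.items()},
        )
        for system, values in self.codes.items():
            if not values:
                raise ValueError(f"empty code list for coding system {system!r}")

    def qualifies(self, coding_system: str, proc_code: str) -> bool:
        return proc_code in self.codes.get(coding_system, frozenset())

    @classmethod
    def from_csv(cls, path) -> "CodeList":
        df = pd.read_csv(path, dtype=str)
        if not {"coding_system", "code"} <= set(df.columns):
            raise ValueError(f"{path}: code list CSV needs columns (coding_system, code)")
        grouped = df.groupby("coding_system")["code"].apply(frozenset).to_dict()
        return cls(codes=grouped)

    def to_csv(self, path) -> None:
        rows = [
            {"coding_system": system, "code": code}
            for system in sorted(self.codes)
            for code in sorted(self.codes[system])
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def expected_coding_system(source: str, service_date: date) -> str:
    """Coding system a claim from this source/date should carry."""
    if source == "billing":
        return "CCP"
    if source == "hospital":
        return "ICD9CM" if service_date < HOSPITAL_CODING_SWITCH else "CCI"
    raise ValueError(f"unknown source {source!r}")


def identify_first_surgery(
    claims: Iterable,
    dx_date: date,
    window: LinkageWindow,
    codes: CodeList,
) -> Optional[SurgeryEvent]:
    """Earliest qualifying claim for one patient in one source, or None.

    ``claims`` is an iterable of objects/rows with attributes ``uli``,
    ``service_date``, ``proc_code``, ``source``, ``coding_system``. The result
    does not depend on input order: ties on the same date break by procedure
    code lexicographically, so linkage is reproducible under permutation.
    """
    best = None
    for claim in claims:
        service_date = _as_date(claim.service_date)
        if not codes.qualifies(claim.coding_system, claim.proc_code):
            continue
        if not window.contains(dx_date, service_date):
            continue
        key = (service_date, str(claim.proc_code))
        if best is None or key < best[0]:
            best = (key, claim)
    if best is None:
        return None
    _, claim = best
    return SurgeryEvent(
        uli=str(claim.uli),
        date=_as_date(claim.service_date),
        source=str(claim.source),
        proc_code=str(claim.proc_code),
    )


def combine_sources(
    billing_event: Optional[SurgeryEvent], hospital_event: Optional[SurgeryEvent]
) -> Optional[SurgeryEvent]:
    """Union rule for the combined administrative dataset.

    One source only -> that event; both with different dates -> the earlier;
    both with the same date -> that date, tagged source 'combined'; neither ->
    None.
    """
    if billing_event is None and hospital_event is None:
        return None
    if billing_event is None:
        return hospital_event
    if hospital_event is None:
        return billing_event
    if billing_event.uli != hospital_event.uli:
        raise ValueError(
            f"cannot combine events of different patients "
            f"({billing_event.uli!r} vs {hospital_event.uli!r})"
        )
    if billing_event.date < hospital_event.date:
        return billing_event
    if hospital_event.date < billing_event.date:
        return hospital_event
    return SurgeryEvent(
        uli=billing_event.uli,
        date=billing_event.date,
        source="combined",
        proc_code=billing_event.proc_code,
    )


def _as_date(value) -> date:
    if isinstance(value, date) and not isinstance(value, pd.Timestamp):
        return value
    return pd.Timestamp(value).date()


def _events_by_patient(
    claims: pd.DataFrame,
    source: str,
    dx_dates: Dict[str, date],
    window: LinkageWindow,
    codes: CodeList,
) -> Dict[str, SurgeryEvent]:
    """First qualifying event per cohort patient for one source."""
    events: Dict[str, SurgeryEvent] = {}
    if len(claims) == 0:
        return events
    claims = claims.copy()
    claims["uli"] = claims["uli"].astype(str)
    known = claims["uli"].isin(dx_dates)
    n_dropped = int((~known).sum())
    if n_dropped:
        logger.info("%s: dropped %d claims without a cohort match", source, n_dropped)
    claims = claims[known]
    claims["source"] = source
    for uli, group in claims.groupby("uli", sort=False):
        event = identify_first_surgery(
            group.itertuples(index=False), dx_dates[uli], window, codes
        )
        if event is not None:
            events[uli] = event
    return events


def link_cohort(
    cohort: pd.DataFrame,
    billing_claims: pd.DataFrame,
    hospital_claims: pd.DataFrame,
    window: LinkageWindow,
    codes: CodeList,
) -> pd.DataFrame:
    """Build the per-patient linkage table: registry truth vs. source events.

    Exactly one row per cohort patient, with columns: uli, dx_date, dx_year,
    stage (missing as 'missing'), tumor_site, registry_flag, registry_date,
    billing_date, hospital_date, combined_date, combined_source. Claims of
    patients outside the cohort are logged and dropped.
    """
    dx_dates = {
        str(row.uli): _as_date(row.dx_date) for row in cohort.itertuples(index=False)
    }
    billing_events = _events_by_patient(billing_claims, "billing", dx_dates, window, codes)
    hospital_events = _events_by_patient(hospital_claims, "hospital", dx_dates, window, codes)

    rows = []
    for rec in cohort.itertuples(index=False):
        uli = str(rec.uli)
        b = billing_events.get(uli)
        h = hospital_events.get(uli)
        c = combine_sources(b, h)
        registry_date = None if pd.isna(rec.surgery_date) else _as_date(rec.surgery_date)
        stage = str(rec.stage).strip() if str(rec.stage).strip() else "missing"
        rows.append(
            {
                "uli": uli,
                "dx_date": _as_date(rec.dx_date),
                "dx_year": _as_date(rec.dx_date).year,
                "stage": stage,
                "tumor_site": rec.tumor_site,
                "registry_flag": registry_date is not None,
                "registry_date": registry_date,
                "billing_date": b.date if b else None,
                "hospital_date": h.date if h else None,
                "combined_date": c.date if c else None,
                "combined_source": c.source if c else None,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "uli",
            "dx_date",
            "dx_year",
            "stage",
            "tumor_site",
            "registry_flag",
            "registry_date",
            "billing_date",
            "hospital_date",
            "combined_date",
            "combined_source",
        ],
    )


def read_claims_csv(path, source: str) -> pd.DataFrame:
    """Read a claims CSV (uli, service_date, proc_code, coding_system)."""
    df = pd.read_csv(path, dtype={"uli": str, "proc_code": str, "coding_system": str})
    missing = set(CLAIM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: claims CSV missing columns {sorted(missing)}")
    df["service_date"] = pd.to_datetime(df["service_date"], format="%Y-%m-%d", errors="raise")
    df["source"] = source
    return df
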