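"""Synthetic linked registry + claims cohort generator.

Real registry/claims linkages of this kind are confidential, so the pipeline
is exercised on synthetic cohorts generated from an explicit observation
model.  Per patient:

1. Diagnosis date uniform over the configured calendar years; stage and tumor
   site drawn from configured categorical distributions.
2. A small fraction of records are seeded as excludable (missing linkage
   identifier, unstageable histology, stage 0 in-situ disease) so cohort
   construction has real work to do.
3. A latent registry surgery indicator is drawn per stage (near 1 for stages
   I–III, ~0.6 for stage IV); if true, the registry surgery date is diagnosis
   plus a discretised-gamma delay.
4. The administrative counterpart of a registry surgery is suppressed with a
   per-stage probability (the stage-I polypectomy mechanism: an office
   excision the registry counts as surgery leaves no inpatient/billing
   surgery code); otherwise each source captures it independently with its
   capture probability, and the recorded date is jittered by a few days with
   a small probability (clamped inside the extraction window).
5. Patients without a registry surgery can still acquire qualifying claims
   (the stage-IV de-bulking/stoma mechanism: palliative operations the
   registry does not count). The underlying palliative event is shared
   between sources (correlation 1 by default) while its capture per source
   follows the configured per-source, per-stage probability.

Defaults are chosen so the generated cohort reproduces the broad structure of
a provincial colorectal cancer cohort: ~85% surgery prevalence overall,
near-100% for stages I–III, ~60% registry / ~66–74% administrative for stage
IV, and >90% exact date agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from crcsurgval.cohort import COLON_SITE_CODES, RECTUM_SITE_CODES, REGISTRY_COLUMNS
from crcsurgval.linkage import CLAIM_COLUMNS, CodeList, expected_coding_system

STAGES = ("I", "II", "III", "IV", "missing")
SITES = ("colon", "rectum")
ADMIN_SOURCES = ("billing", "hospital")

#: the synthetic qualifying procedure code, present in every coding system
SURGERY_CODE = "SURG01"
#: a non-qualifying code used for noise claims
NOISE_CODE = "OTHER99"


def default_code_list() -> CodeList:
    """Code list matching the synthetic vocabulary."""
    return CodeList(
        codes={sys: frozenset({SURGERY_CODE}) for sys in ("CCP", "ICD9CM", "CCI")}
    )


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {p}")


def _check_dist(name: str, dist: Dict[str, float], levels: Tuple[str, ...]) -> None:
    if set(dist) != set(levels):
        raise ValueError(f"{name} must have exactly levels {levels}, got {sorted(dist)}")
    for k, v in dist.items():
        _check_prob(f"{name}[{k}]", v)
    if abs(sum(dist.values()) - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {sum(dist.values())})")


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic cohort generator.

    All probabilities are in [0, 1]; categorical distributions must sum to 1.
    The delay distribution (diagnosis to surgery, days) is a discretised gamma
    clipped to ``[delay_min, delay_max]``, which must sit inside the claim
    extraction window [−7, 548].
    """

    n_patients: int = 8533
    year_range: Tuple[int, int] = (2000, 2005)
    stage_distribution: Dict[str, float] = field(
        default_factory=lambda: {
            "I": 0.167,
            "II": 0.266,
            "III": 0.229,
            "IV": 0.235,
            "missing": 0.103,
        }
    )
    site_distribution: Dict[str, float] = field(
        default_factory=lambda: {"colon": 0.638, "rectum": 0.362}
    )
    registry_surgery_prob: Dict[str, float] = field(
        default_factory=lambda: {
            "I": 0.99,
            "II": 0.98,
            "III": 0.99,
            "IV": 0.60,
            "missing": 0.56,
        }
    )
    source_capture_prob: Dict[str, float] = field(
        default_factory=lambda: {"billing": 0.97, "hospital": 0.945}
    )
    false_positive_prob: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            "billing": {"I": 0.12, "II": 0.50, "III": 0.30, "IV": 0.31, "missing": 0.18},
            "hospital": {"I": 0.12, "II": 0.37, "III": 0.22, "IV": 0.21, "missing": 0.14},
        }
    )
    fp_correlation: float = 1.0
    registry_only_prob: Dict[str, float] = field(
        default_factory=lambda: {
            "I": 0.07,
            "II": 0.0,
            "III": 0.0,
            "IV": 0.0,
            "missing": 0.05,
        }
    )
    date_jitter_prob: float = 0.05
    date_jitter_range: Tuple[int, int] = (-3, 3)
    missing_uli_rate: float = 2 / 8533
    unstageable_rate: float = 140 / 8533
    stage0_rate: float = 83 / 8533
    delay_gamma_shape: float = 2.0
    delay_gamma_scale: float = 15.0
    delay_min: int = 0
    delay_max: int = 548
    noise_claim_prob: float = 0.10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        y0, y1 = self.year_range
        if y0 > y1:
            raise ValueError("year_range must be (first, last) with first <= last")
        _check_dist("stage_distribution", self.stage_distribution, STAGES)
        _check_dist("site_distribution", self.site_distribution, SITES)
        for stage in STAGES:
            _check_prob(f"registry_surgery_prob[{stage}]", self.registry_surgery_prob[stage])
            _check_prob(f"registry_only_prob[{stage}]", self.registry_only_prob[stage])
        for src in ADMIN_SOURCES:
            _check_prob(f"source_capture_prob[{src}]", self.source_capture_prob[src])
            for stage in STAGES:
                _check_prob(
                    f"false_positive_prob[{src}][{stage}]",
                    self.false_positive_prob[src][stage],
                )
        for name in (
            "fp_correlation",
            "date_jitter_prob",
            "missing_uli_rate",
            "unstageable_rate",
            "stage0_rate",
            "noise_claim_prob",
        ):
            _check_prob(name, getattr(self, name))
        if self.missing_uli_rate + self.unstageable_rate + self.stage0_rate > 1.0:
            raise ValueError("exclusion-seeding rates sum to more than 1")
        lo, hi = self.date_jitter_range
        if lo > hi:
            raise ValueError("date_jitter_range must be (low, high) with low <= high")
        if self.delay_gamma_shape <= 0 or self.delay_gamma_scale <= 0:
            raise ValueError("delay gamma parameters must be positive")
        if not (-7 <= self.delay_min <= self.delay_max <= 548):
            raise ValueError("delay support must lie within the window [-7, 548]")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("year_range", "date_jitter_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["year_range"] = list(self.year_range)
        raw["date_jitter_range"] = list(self.date_jitter_range)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass
class LinkedDatasets:
    """The three linked datasets plus the latent truth log.

    ``truth_log`` records, per patient, every latent state the generator drew
    (exclusion seeding, latent surgery, suppression, per-source capture /
    false-positive / jitter outcomes) so tests can compare pipeline estimates
    against known truth.
    """

    registry: pd.DataFrame
    billing: pd.DataFrame
    hospital: pd.DataFrame
    truth_log: pd.DataFrame

    def write_csvs(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        for name in ("registry", "billing", "hospital", "truth_log"):
            getattr(self, name).to_csv(os.path.join(outdir, f"{name}.csv"), index=False)


_COLON_CODES = sorted(COLON_SITE_CODES)
_RECTUM_CODES = sorted(RECTUM_SITE_CODES)

TRUTH_LOG_COLUMNS = [
    "uli",
    "excluded_as",
    "stage",
    "tumor_site",
    "latent_surgery",
    "registry_date",
    "admin_suppressed",
    "billing_captured",
    "hospital_captured",
    "billing_fp",
    "hospital_fp",
    "billing_jittered",
    "hospital_jittered",
]


def _draw_delay(rng: np.random.Generator, config: GeneratorConfig) -> int:
    d = int(round(rng.gamma(config.delay_gamma_shape, config.delay_gamma_scale)))
    return int(np.clip(d, config.delay_min, config.delay_max))


def _jitter_offset(rng: np.random.Generator, config: GeneratorConfig) -> int:
    """A nonzero offset within the jitter range (0 would not be jitter)."""
    lo, hi = config.date_jitter_range
    choices = [d for d in range(lo, hi + 1) if d != 0]
    if not choices:
        return 0
    return int(choices[rng.integers(len(choices))])


def _clamp_to_window(d: date, dx: date) -> date:
    lo, hi = dx + timedelta(days=-7), dx + timedelta(days=548)
    return min(max(d, lo), hi)


def generate_cohort(config: GeneratorConfig) -> LinkedDatasets:
    """Generate the linked registry / billing / hospital datasets.

    Bit-for-bit reproducible for a given ``rng_seed`` (a single generator,
    fixed draw order). Every claim's identifier appears in the registry;
    records seeded as missing-ULI produce no claims, since nothing could link
    them.
    """
    rng = np.random.default_rng(config.rng_seed)
    y0, y1 = config.year_range
    start = date(y0, 1, 1)
    n_days = (date(y1, 12, 31) - start).days + 1

    registry_rows, billing_rows, hospital_rows, truth_rows = [], [], [], []

    for i in range(config.n_patients):
        uli = f"P{i:07d}"
        # A fixed block of draws per patient, consumed regardless of which
        # branches fire: changing one probability parameter then perturbs only
        # the outcomes that parameter governs (common random numbers), and
        # determinism is trivially structural.
        dx = start + timedelta(days=int(rng.integers(n_days)))
        site_u = rng.random()
        colon_idx = int(rng.integers(len(_COLON_CODES)))
        rectum_idx = int(rng.integers(len(_RECTUM_CODES)))
        excl_u = rng.random()
        stage_u = rng.random()
        latent_u = rng.random()
        surgery_delay = _draw_delay(rng, config)
        suppress_u = rng.random()
        shared_fp_u = rng.random()
        per_source = {
            src: {
                "capture_u": rng.random(),
                "jitter_u": rng.random(),
                "jitter_offset": _jitter_offset(rng, config),
                "own_fp_u": rng.random(),
                "mix_u": rng.random(),
                "fp_delay": _draw_delay(rng, config),
                "noise_u": rng.random(),
                "noise_day": int(rng.integers(-7, 549)),
            }
            for src in ADMIN_SOURCES
        }

        site = SITES[int(site_u >= config.site_distribution["colon"])]
        site_code = (
            _COLON_CODES[colon_idx] if site == "colon" else _RECTUM_CODES[rectum_idx]
        )

        if excl_u < config.missing_uli_rate:
            excluded_as = "missing_uli"
        elif excl_u < config.missing_uli_rate + config.unstageable_rate:
            excluded_as = "unstageable"
        elif excl_u < config.missing_uli_rate + config.unstageable_rate + config.stage0_rate:
            excluded_as = "stage0"
        else:
            excluded_as = ""

        if excluded_as == "unstageable":
            stage, stageable = "", False
        elif excluded_as == "stage0":
            stage, stageable = "0", True
        else:
            cum = 0.0
            stage = STAGES[-1]
            for s in STAGES:
                cum += config.stage_distribution[s]
                if stage_u < cum:
                    stage = s
                    break
            stage = "" if stage == "missing" else stage
            stageable = True

        # latent registry surgery; excluded records use the missing-stage rate
        stage_key = stage if stage in ("I", "II", "III", "IV") else "missing"
        latent = latent_u < config.registry_surgery_prob[stage_key]
        registry_date: Optional[date] = None
        if latent:
            registry_date = dx + timedelta(days=surgery_delay)

        suppressed = bool(latent and suppress_u < config.registry_only_prob[stage_key])

        captured = {src: False for src in ADMIN_SOURCES}
        fp = {src: False for src in ADMIN_SOURCES}
        jittered = {src: False for src in ADMIN_SOURCES}
        claim_dates: Dict[str, Optional[date]] = {src: None for src in ADMIN_SOURCES}

        if latent and not suppressed:
            for src in ADMIN_SOURCES:
                draws = per_source[src]
                captured[src] = draws["capture_u"] < config.source_capture_prob[src]
                if captured[src]:
                    d = registry_date
                    if (
                        draws["jitter_u"] < config.date_jitter_prob
                        and draws["jitter_offset"] != 0
                    ):
                        jittered[src] = True
                        d = _clamp_to_window(
                            d + timedelta(days=draws["jitter_offset"]), dx
                        )
                    claim_dates[src] = d
        elif not latent:
            # palliative event shared across sources; capture coupled by
            # fp_correlation (1 = comonotone, 0 = independent)
            for src in ADMIN_SOURCES:
                draws = per_source[src]
                u_src = (
                    shared_fp_u
                    if draws["mix_u"] < config.fp_correlation
                    else draws["own_fp_u"]
                )
                fp[src] = u_src < config.false_positive_prob[src][stage_key]
                if fp[src]:
                    claim_dates[src] = dx + timedelta(days=draws["fp_delay"])

        registry_rows.append(
            {
                "uli": "" if excluded_as == "missing_uli" else uli,
                "dx_date": dx.isoformat(),
                "site_code": site_code,
                "stage": stage,
                "histology_stageable": stageable,
                "surgery_date": registry_date.isoformat() if registry_date else "",
            }
        )

        if excluded_as != "missing_uli":
            for src, rows in (("billing", billing_rows), ("hospital", hospital_rows)):
                d = claim_dates[src]
                if d is not None:
                    rows.append(
                        {
                            "uli": uli,
                            "service_date": d.isoformat(),
                            "proc_code": SURGERY_CODE,
                            "coding_system": expected_coding_system(src, d),
                        }
                    )
                if per_source[src]["noise_u"] < config.noise_claim_prob:
                    nd = dx + timedelta(days=per_source[src]["noise_day"])
                    rows.append(
                        {
                            "uli": uli,
                            "service_date": nd.isoformat(),
                            "proc_code": NOISE_CODE,
                            "coding_system": expected_coding_system(src, nd),
                        }
                    )

        truth_rows.append(
            {
                "uli": uli,
                "excluded_as": excluded_as,
                "stage": stage if stage else "missing",
                "tumor_site": site,
                "latent_surgery": latent,
                "registry_date": registry_date.isoformat() if registry_date else "",
                "admin_suppressed": suppressed,
                "billing_captured": captured["billing"],
                "hospital_captured": captured["hospital"],
                "billing_fp": fp["billing"],
                "hospital_fp": fp["hospital"],
                "billing_jittered": jittered["billing"],
                "hospital_jittered": jittered["hospital"],
            }
        )

    registry = pd.DataFrame(registry_rows, columns=REGISTRY_COLUMNS)
    billing = pd.DataFrame(billing_rows, columns=CLAIM_COLUMNS)
    hospital = pd.DataFrame(hospital_rows, columns=CLAIM_COLUMNS)
    truth_log = pd.DataFrame(truth_rows, columns=TRUTH_LOG_COLUMNS)
    return LinkedDatasets(
        registry=registry, billing=billing, hospital=hospital, truth_log=truth_log
    )


def registry_with_exact_exclusions(
    n_total: int,
    n_missing_uli: int,
    n_unstageable: int,
    n_stage0: int,
    seed: int = 0,
) -> pd.DataFrame:
    """A registry table with *exactly* the requested exclusion counts.

    Unlike :func:`generate_cohort`, which seeds exclusions at random rates,
    this helper fixes the counts so exclusion arithmetic is deterministic:
    categories are assigned to a seeded random permutation of the rows.
    """
    n_excl = n_missing_uli + n_unstageable + n_stage0
    if n_excl > n_total:
        raise ValueError("exclusion counts exceed n_total")
    rng = np.random.default_rng(seed)
    config = GeneratorConfig(
        n_patients=n_total,
        missing_uli_rate=0.0,
        unstageable_rate=0.0,
        stage0_rate=0.0,
        rng_seed=int(rng.integers(2**31 - 1)),
    )
    registry = generate_cohort(config).registry
    order = rng.permutation(n_total)
    idx_uli = order[:n_missing_uli]
    idx_unstageable = order[n_missing_uli : n_missing_uli + n_unstageable]
    idx_stage0 = order[n_missing_uli + n_unstageable : n_excl]
    registry.loc[idx_uli, "uli"] = ""
    registry.loc[idx_unstageable, "histology_stageable"] = False
    registry.loc[idx_unstageable, "stage"] = ""
    registry.loc[idx_stage0, "stage"] = "0"
    registry.loc[idx_stage0, "histology_stageable"] = True
    return registry
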