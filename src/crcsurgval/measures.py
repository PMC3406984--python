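"""Diagnostic-accuracy measures of administrative surgery capture.

A patient-level linkage table (one row per cohort patient, with the registry
surgery indicator as truth and per-source administrative surgery events as the
test) is cross-tabulated into 2x2 contingency tables, from which the five
standard validation measures are computed:

- sensitivity  = TP / (TP + FN)
- specificity  = TN / (TN + FP)
- PPV          = TP / (TP + FP)
- NPV          = TN / (TN + FN)
- observed agreement = (TP + TN) / N

Observed agreement is used instead of Cohen's kappa because kappa is strongly
driven by trait prevalence, and surgery prevalence in early-stage strata of
this problem exceeds 98%.

Confidence intervals are Wilson score intervals by default (stable near 0 and
1, where several strata live); a Wald option exists for comparison.  Estimates
whose denominator is zero are *undefined* and reported as absent — never as 0
or 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Optional, Tuple

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from crcsurgval.rounding import percent

MEASURE_NAMES = ("sensitivity", "specificity", "ppv", "npv", "agreement")

#: administrative sources a linkage table carries
SOURCES = ("billing", "hospital", "combined")

#: stratification factors of the analysis
STRATUM_FACTORS = ("all", "year", "stage", "site")


@dataclass(frozen=True)
class ContingencyTable:
    """Integer 2x2 table of an administrative source against registry truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def truth_positives(self) -> int:
        return self.tp + self.fn

    @property
    def test_positives(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class MeasureEstimate:
    """One proportion estimate with its interval and stability flag.

    ``value`` and the CI bounds are proportions in [0, 1]; ``defined`` is
    False (and the numeric fields None) when the denominator is zero.
    """

    defined: bool
    value: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    unstable: Optional[bool] = None
    successes: Optional[int] = None
    trials: Optional[int] = None

    def as_percent(self, convention: str = "half-up") -> Optional[int]:
        """Whole-percent rendering by exact rational rounding; None if undefined."""
        if not self.defined:
            return None
        return percent(self.successes, self.trials, convention)


@dataclass(frozen=True)
class ValidationMeasures:
    """The five validation measures of one contingency table."""

    table: ContingencyTable
    sensitivity: MeasureEstimate
    specificity: MeasureEstimate
    ppv: MeasureEstimate
    npv: MeasureEstimate
    agreement: MeasureEstimate

    def __getitem__(self, name: str) -> MeasureEstimate:
        if name not in MEASURE_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def as_percent_dict(self, convention: str = "half-up") -> Dict[str, Optional[int]]:
        return {m: self[m].as_percent(convention) for m in MEASURE_NAMES}


@dataclass(frozen=True)
class DateAgreement:
    """Agreement of administrative vs. registry surgery dates on true positives."""

    n_pairs: int
    exact_match_fraction: Optional[float]
    difference_histogram: Dict[int, int] = field(default_factory=dict)


def proportion_ci(
    successes: int, n: int, level: float = 0.95, method: str = "wilson"
) -> Tuple[float, float]:
    """Confidence interval for a binomial proportion.

    Wilson score interval by default; ``method='wald'`` gives the normal
    approximation.  Bounds are clipped to [0, 1] and are exact at the
    degenerate counts (0 successes -> lower bound 0; n successes -> upper
    bound 1, which is the closed-form Wilson value there).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError(f"successes must be in [0, n], got {successes} of {n}")
    if method not in ("wilson", "wald"):
        raise ValueError(f"unknown CI method {method!r}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    sm_method = "normal" if method == "wald" else method
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method=sm_method)
    lo, hi = max(0.0, float(lo)), min(1.0, float(hi))
    # Wilson bounds are exactly 0/1 at the boundary counts; remove float fuzz.
    if successes == 0:
        lo = 0.0
    if successes == n:
        hi = 1.0
    return lo, hi


def flag_instability(estimate_percent: float, ci_percent: Tuple[float, float]) -> bool:
    """Flag an estimate whose interval is too wide to trust.

    True iff the 95% CI is wider than 15 percentage points (strict), or its
    width is 40% or more of the estimate itself (inclusive). Both estimate
    and CI are on the percentage scale.
    """
    width = ci_percent[1] - ci_percent[0]
    return width > 15.0 or width >= 0.40 * estimate_percent


def _estimate(successes: int, trials: int, level: float, method: str) -> MeasureEstimate:
    if trials == 0:
        return MeasureEstimate(defined=False)
    value = successes / trials
    lo, hi = proportion_ci(successes, trials, level=level, method=method)
    unstable = flag_instability(100.0 * value, (100.0 * lo, 100.0 * hi))
    return MeasureEstimate(
        defined=True,
        value=value,
        ci_low=lo,
        ci_high=hi,
        unstable=unstable,
        successes=successes,
        trials=trials,
    )


def compute_measures(
    t: ContingencyTable, level: float = 0.95, ci_method: str = "wilson"
) -> ValidationMeasures:
    """Compute the five validation measures of a 2x2 table.

    Zero-denominator measures come back undefined rather than raising; an
    entirely empty table (n = 0) is an error because no measure exists.
    """
    if t.n == 0:
        raise ValueError("contingency table is empty (n = 0)")
    return ValidationMeasures(
        table=t,
        sensitivity=_estimate(t.tp, t.tp + t.fn, level, ci_method),
        specificity=_estimate(t.tn, t.tn + t.fp, level, ci_method),
        ppv=_estimate(t.tp, t.tp + t.fp, level, ci_method),
        npv=_estimate(t.tn, t.tn + t.fn, level, ci_method),
        agreement=_estimate(t.tp + t.tn, t.n, level, ci_method),
    )


def _stratum_mask(linkage_rows: pd.DataFrame, factor: str, level) -> pd.Series:
    if factor == "all":
        return pd.Series(True, index=linkage_rows.index)
    if factor == "year":
        return linkage_rows["dx_year"] == int(level)
    if factor == "stage":
        return linkage_rows["stage"].fillna("missing") == str(level)
    if factor == "site":
        return linkage_rows["tumor_site"] == str(level)
    raise ValueError(f"unknown stratum factor {factor!r}; expected one of {STRATUM_FACTORS}")


def cross_tabulate(
    linkage_rows: pd.DataFrame,
    source: str,
    stratum: Optional[Tuple[str, object]] = None,
) -> ContingencyTable:
    """Cross-tabulate one administrative source against registry truth.

    ``linkage_rows`` is the per-patient table from
    :func:`crcsurgval.linkage.link_cohort`; ``stratum`` is an optional
    ``(factor, level)`` restriction with factor in {'all','year','stage','site'}.
    """
    if source not in SOURCES:
        raise ValueError(f"unknown source {source!r}; expected one of {SOURCES}")
    rows = linkage_rows
    if stratum is not None:
        rows = rows[_stratum_mask(rows, *stratum)]
    truth = rows["registry_flag"].astype(bool)
    test = rows[f"{source}_date"].notna()
    return ContingencyTable(
        tp=int((truth & test).sum()),
        fp=int((~truth & test).sum()),
        fn=int((truth & ~test).sum()),
        tn=int((~truth & ~test).sum()),
    )


def date_agreement(linkage_rows: pd.DataFrame, source: str) -> DateAgreement:
    """Histogram of (administrative − registry) surgery-date differences.

    Restricted to true positives: patients with both a registry surgery date
    and an event in ``source``. Empty input gives n_pairs 0 and an undefined
    fraction.
    """
    if source not in SOURCES:
        raise ValueError(f"unknown source {source!r}; expected one of {SOURCES}")
    rows = linkage_rows[linkage_rows["registry_flag"].astype(bool)]
    rows = rows[rows[f"{source}_date"].notna() & rows["registry_date"].notna()]
    if len(rows) == 0:
        return DateAgreement(n_pairs=0, exact_match_fraction=None)
    diffs = (
        pd.to_datetime(rows[f"{source}_date"]) - pd.to_datetime(rows["registry_date"])
    ).dt.days.astype(int)
    hist = diffs.value_counts().sort_index()
    histogram = {int(k): int(v) for k, v in hist.items()}
    n_pairs = int(len(diffs))
    return DateAgreement(
        n_pairs=n_pairs,
        exact_match_fraction=histogram.get(0, 0) / n_pairs,
        difference_histogram=histogram,
    )


def measures_to_tidy_row(
    factor: str,
    level: str,
    source: str,
    vm: ValidationMeasures,
) -> list:
    """Rows of the tidy measures CSV: one row per measure."""
    rows = []
    for m in MEASURE_NAMES:
        est = vm[m]
        rows.append(
            {
                "stratum_factor": factor,
                "stratum_level": level,
                "source": source,
                "measure": m,
                "estimate_pct": 100.0 * est.value if est.defined else None,
                "ci_low_pct": 100.0 * est.ci_low if est.defined else None,
                "ci_high_pct": 100.0 * est.ci_high if est.defined else None,
                "unstable": est.unstable if est.defined else None,
                "defined": est.defined,
            }
        )
    return rows
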