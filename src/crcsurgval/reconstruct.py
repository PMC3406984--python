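"""Recovering 2x2 tables from published marginals and rounded measures.

Published validation studies print the column marginals of each 2x2 table
(cohort size, registry-positive count, administrative-positive count) plus
whole-percent measures — but not the table cells themselves.  Because the
cells are integers, the marginals pin down the table up to a single free cell
(take TP: then FP, FN, TN follow by subtraction), so:

- :func:`reconstruct_from_seed` inverts *one* printed measure into that free
  cell deterministically, giving a concrete table to audit against the other
  printed measures; and
- :func:`feasible_tp_set` enumerates *every* TP consistent with a full set of
  printed rounded measures — an exhaustive consistency audit of a published
  row.  An empty set proves no integer table reproduces all printed values
  under the assumed rounding convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Set

from crcsurgval.measures import MEASURE_NAMES, ContingencyTable
from crcsurgval.rounding import percent, round_convention


@dataclass(frozen=True)
class MarginalSpec:
    """Printed marginals of one validation row.

    ``n``: analysis cohort size; ``truth_pos``: registry surgery count;
    ``test_pos``: administrative surgery count for the source at hand.
    """

    n: int
    truth_pos: int
    test_pos: int

    def __post_init__(self) -> None:
        if not 0 <= self.truth_pos <= self.n:
            raise ValueError("truth_pos must be in [0, n]")
        if not 0 <= self.test_pos <= self.n:
            raise ValueError("test_pos must be in [0, n]")


@dataclass(frozen=True)
class RoundedMeasureSet:
    """Whole-percent published measures; any subset may be present."""

    sensitivity: Optional[int] = None
    specificity: Optional[int] = None
    ppv: Optional[int] = None
    npv: Optional[int] = None
    agreement: Optional[int] = None

    def __post_init__(self) -> None:
        present = self.present()
        if not present:
            raise ValueError("at least one measure must be present")
        for name, value in present.items():
            if not (isinstance(value, int) and 0 <= value <= 100):
                raise ValueError(f"{name} must be an integer percent in [0, 100], got {value!r}")

    def present(self) -> dict:
        return {
            m: getattr(self, m) for m in MEASURE_NAMES if getattr(self, m) is not None
        }


class InfeasibleSeedError(ValueError):
    """The seed measure implies a negative table cell at these marginals."""


def _table_from_tp(m: MarginalSpec, tp: int) -> Optional[ContingencyTable]:
    """Expand a TP count to the full table; None if any cell is negative."""
    fp = m.test_pos - tp
    fn = m.truth_pos - tp
    tn = m.n - tp - fp - fn
    if min(tp, fp, fn, tn) < 0:
        return None
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)


def reconstruct_from_seed(
    m: MarginalSpec,
    seed_measure: str,
    seed_percent: int,
    convention: str = "half-up",
) -> ContingencyTable:
    """Deterministically invert one whole-percent measure into a 2x2 table.

    The seed percent is converted back to an integer count against its own
    denominator (derived from the marginals) using the stated rounding
    convention, and the remaining cells follow from the marginals:

    - sensitivity seed -> tp = round(seed/100 * truth_pos)
    - specificity seed -> tn = round(seed/100 * (n - truth_pos))
    - ppv seed         -> tp = round(seed/100 * test_pos)
    - npv seed         -> tn = round(seed/100 * (n - test_pos))
    - agreement seed   -> tp + tn = round(seed/100 * n), split using
      tp - tn = test_pos - (n - truth_pos); an odd split floors tp's half.

    Raises :class:`InfeasibleSeedError` when the implied table has a negative
    cell, so callers can report infeasibility rather than crash.
    """
    if seed_measure not in MEASURE_NAMES:
        raise ValueError(f"unknown seed measure {seed_measure!r}")
    if not 0 <= seed_percent <= 100:
        raise ValueError("seed_percent must be in [0, 100]")
    frac = Fraction(seed_percent, 100)

    if seed_measure == "sensitivity":
        tp = round_convention(frac * m.truth_pos, convention)
    elif seed_measure == "specificity":
        tn = round_convention(frac * (m.n - m.truth_pos), convention)
        tp = m.test_pos - ((m.n - m.truth_pos) - tn)
    elif seed_measure == "ppv":
        tp = round_convention(frac * m.test_pos, convention)
    elif seed_measure == "npv":
        tn = round_convention(frac * (m.n - m.test_pos), convention)
        tp = m.test_pos - ((m.n - m.truth_pos) - tn)
    else:  # agreement
        s = round_convention(frac * m.n, convention)  # tp + tn
        d = m.test_pos - (m.n - m.truth_pos)  # tp - tn
        tp = (s + d) // 2  # floors tp's half when s + d is odd

    table = _table_from_tp(m, tp)
    if table is None:
        raise InfeasibleSeedError(
            f"seed {seed_measure}={seed_percent}% is infeasible at marginals {m}"
        )
    return table


def feasible_tp_set(
    m: MarginalSpec, r: RoundedMeasureSet, convention: str = "half-up"
) -> Set[int]:
    """All TP counts whose implied table reproduces every present measure.

    Exhaustive enumeration of tp over the marginal-feasible range; a member is
    kept iff each present measure, computed at full (rational) precision and
    rounded to whole percent under ``convention``, equals its stated value.
    """
    targets = r.present()
    feasible: Set[int] = set()
    for tp in range(0, min(m.truth_pos, m.test_pos) + 1):
        table = _table_from_tp(m, tp)
        if table is None:
            continue
        if _matches(table, targets, convention):
            feasible.add(tp)
    return feasible


def _matches(t: ContingencyTable, targets: dict, convention: str) -> bool:
    denoms = {
        "sensitivity": (t.tp, t.tp + t.fn),
        "specificity": (t.tn, t.tn + t.fp),
        "ppv": (t.tp, t.tp + t.fp),
        "npv": (t.tn, t.tn + t.fn),
        "agreement": (t.tp + t.tn, t.n),
    }
    for name, target in targets.items():
        num, den = denoms[name]
        if den == 0:  # undefined measure can never match a printed value
            return False
        if percent(num, den, convention) != target:
            return False
    return True
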