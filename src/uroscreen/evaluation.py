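"""Screening-rule evaluation against adjudicated culture labels.

The gold standard is always the adjudicated label, never the raw growth
status (a culture can grow organisms and still be adjudicated negative).
"Positive screen" means the rule reflexes the sample to culture, so the
false-negative cell counts adjudicated-positive cultures the rule would have
missed, and the screen-negative margin (tn + fn) counts cultures avoided.

Percentages are rounded half-away-from-zero (:func:`round_half_up`), the
convention evident throughout clinical-laboratory reporting.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal, InvalidOperation
from typing import Iterable, Sequence, Union

import pandas as pd

from .cohort_model import GrowthStatus, Sample
from .exceptions import AdjudicationError, InputError
from .screening import ScreeningRule, parse_rule

__all__ = [
    "ConfusionMatrix",
    "MissedReport",
    "confusion_matrix",
    "sens_spec",
    "sweep",
    "missed_report",
    "round_half_up",
]


def round_half_up(x, decimals: int = 0):
    """Decimal round-half-away-from-zero at the given precision.

    Accepts floats or :class:`decimal.Decimal`; the return type follows the
    input (Decimal in, Decimal out).  Ties round away from zero, so 95.5 -> 96
    and -0.5 -> -1.
    """
    if isinstance(x, Decimal):
        d, as_decimal = x, True
    else:
        xf = float(x)
        if not math.isfinite(xf):
            raise InputError(f"cannot round non-finite value {x!r}")
        d, as_decimal = Decimal(repr(xf)), False
    try:
        q = d.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP)
    except InvalidOperation as exc:  # pragma: no cover - absurd precision
        raise InputError(f"cannot round {x!r} to {decimals} decimals") from exc
    return q if as_decimal else float(q)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Screen result (rows) vs adjudicated culture label (columns).

    tp: screen-positive & culture-positive; fn: screen-negative &
    culture-positive (missed cultures); fp: screen-positive &
    culture-negative (unnecessary cultures the rule still performs);
    tn: screen-negative & culture-negative (cultures correctly avoided).
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise InputError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def cultures_saved(self) -> int:
        """Screen-negative margin: cultures not performed under the rule."""
        return self.tn + self.fn

    def to_frame(self) -> pd.DataFrame:
        """2x2 table with margins, screen rows x culture columns."""
        df = pd.DataFrame(
            {
                "culture_negative": [self.tn, self.fp],
                "culture_positive": [self.fn, self.tp],
            },
            index=["sediment_negative", "sediment_positive"],
        )
        df["total"] = df.sum(axis=1)
        df.loc["total"] = df.sum(axis=0)
        return df


@dataclass(frozen=True)
class MissedReport:
    """Breakdown of the adjudicated-positive cultures a rule screens out."""

    total_missed: int
    species_counts: dict[str, int]
    no_treatment_count: int
    clinically_relevant_count: int
    #: True when multi-isolate cultures were tabulated under each species,
    #: in which case the species column may sum to more than total_missed.
    species_multicounted: bool = False

    def __post_init__(self):
        if not self.species_multicounted and sum(self.species_counts.values()) != self.total_missed:
            raise InputError("species counts must sum to total_missed")
        if self.no_treatment_count + self.clinically_relevant_count != self.total_missed:
            raise InputError("treatment split must sum to total_missed")

    def to_frame(self, decimals: int = 1) -> pd.DataFrame:
        rows = [
            {
                "species": sp,
                "count": c,
                "percent": round_half_up(100.0 * c / self.total_missed, decimals)
                if self.total_missed
                else 0.0,
            }
            for sp, c in self.species_counts.items()
        ]
        return pd.DataFrame(rows, columns=["species", "count", "percent"])


def _as_rule(rule: Union[ScreeningRule, str]) -> ScreeningRule:
    return parse_rule(rule) if isinstance(rule, str) else rule


def confusion_matrix(
    samples: Sequence[Sample], rule: Union[ScreeningRule, str]
) -> ConfusionMatrix:
    """Cross-tabulate a screening rule against adjudicated labels.

    Every sample must be adjudicated; the four cells conserve the cohort size.
    """
    rule = _as_rule(rule)
    tp = fp = tn = fn = 0
    for s in samples:
        if s.adjudicated is None:
            raise AdjudicationError(f"sample {s.sample_id} not adjudicated")
        screened_in = rule.applies(s.sediment)
        if screened_in:
            if s.is_positive:
                tp += 1
            else:
                fp += 1
        else:
            if s.is_positive:
                fn += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def sens_spec(cm: ConfusionMatrix, decimals: int = 0) -> dict[str, float]:
    """Sensitivity and specificity of the screen, in percent.

    Sensitivity = tp/(tp+fn)·100 (fraction of positive cultures reflexed in);
    specificity = tn/(tn+fp)·100 (fraction of negative cultures avoided).
    A degenerate margin yields NaN with a warning rather than an exception.
    """
    out: dict[str, float] = {}
    pos = cm.tp + cm.fn
    neg = cm.tn + cm.fp
    if pos > 0:
        out["sensitivity_pct"] = round_half_up(100.0 * cm.tp / pos, decimals)
    else:
        warnings.warn("no adjudicated positives: sensitivity undefined", stacklevel=2)
        out["sensitivity_pct"] = math.nan
    if neg > 0:
        out["specificity_pct"] = round_half_up(100.0 * cm.tn / neg, decimals)
    else:
        warnings.warn("no adjudicated negatives: specificity undefined", stacklevel=2)
        out["specificity_pct"] = math.nan
    return out


def sweep(
    samples: Sequence[Sample],
    rules: Iterable[Union[ScreeningRule, str]],
    decimals: int = 0,
) -> pd.DataFrame:
    """Evaluate a list of candidate rules; one row per rule.

    Columns: rule text, sensitivity and specificity (percent), and
    cultures_saved (the screen-negative margin tn + fn).
    """
    rows = []
    for rule in rules:
        rule = _as_rule(rule)
        cm = confusion_matrix(samples, rule)
        metrics = sens_spec(cm, decimals)
        rows.append(
            {
                "rule": rule.text,
                "sensitivity_pct": metrics["sensitivity_pct"],
                "specificity_pct": metrics["specificity_pct"],
                "cultures_saved": cm.cultures_saved,
            }
        )
    return pd.DataFrame(
        rows, columns=["rule", "sensitivity_pct", "specificity_pct", "cultures_saved"]
    )


def missed_report(
    samples: Sequence[Sample],
    rule: Union[ScreeningRule, str],
    species_mode: str = "first",
) -> MissedReport:
    """Summarise the positive cultures a rule would miss (the fn cell).

    Species are tabulated by the first-listed isolate by default
    (``species_mode="all"`` counts a multi-isolate culture under each of its
    species while still counting once in the total).  The treatment split
    uses the ``clinically_relevant`` flag: relevant means antibiotic
    treatment was given (symptomatic UTI or pre-procedure prophylaxis).
    """
    if species_mode not in ("first", "all"):
        raise InputError(f"species_mode must be 'first' or 'all', got {species_mode!r}")
    rule = _as_rule(rule)
    species: Counter[str] = Counter()
    total = 0
    relevant = 0
    for s in samples:
        if s.adjudicated is None:
            raise AdjudicationError(f"sample {s.sample_id} not adjudicated")
        if rule.applies(s.sediment) or not s.is_positive:
            continue
        total += 1
        if s.culture.clinically_relevant:
            relevant += 1
        if s.culture.growth_status is GrowthStatus.GROWTH:
            if species_mode == "first":
                species[s.culture.isolates[0].organism] += 1
            else:
                for name in dict.fromkeys(i.organism for i in s.culture.isolates):
                    species[name] += 1
        else:
            # a positive label without recorded growth cannot arise from the
            # adjudication clauses, but external labels may carry it
            species["(no growth recorded)"] += 1
    return MissedReport(
        total_missed=total,
        species_counts=dict(species.most_common()),
        no_treatment_count=total - relevant,
        clinically_relevant_count=relevant,
        species_multicounted=(species_mode == "all"),
    )
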