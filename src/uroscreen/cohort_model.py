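"""Sample data model and rule-based adjudication of urine cultures.

A urology-outpatient urine sample pairs an automated sediment analysis
(leukocytes/µL and bacteria/µL from an automated microscopy analyzer) with a
culture outcome (growth status, isolated organisms with cfu/ml, and treatment
flags).  A culture is adjudicated *negative* when any of five clauses holds:

1. no bacterial growth at all;
2. growth of "mixed contaminants" (polymicrobial contamination);
3. growth of a non-classic uropathogen below 10^5 cfu/ml;
4. growth of a non-classic uropathogen at >= 10^5 cfu/ml but with
   < 20 leukocytes/µL in the sediment and no need for antibiotics;
5. growth of a classic uropathogen at <= 10^4 cfu/ml with < 20 leukocytes/µL
   and no need for antibiotics.

All other cultures are positive.  Clauses 3-5 are evaluated per isolate; a
multi-isolate culture is negative only when every isolate individually
satisfies a negative clause.

The classic/non-classic split follows conventional urinary microbiology
(classic uropathogens cause UTI at low inoculum; skin and mucosal flora such
as *S. epidermidis* or *Candida* require stronger evidence).  The catalog is
configurable because laboratories disagree at the margins.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .exceptions import AdjudicationError, InputError, UnknownOrganismWarning

__all__ = [
    "GrowthStatus",
    "UropathogenClass",
    "GramClass",
    "SedimentResult",
    "Isolate",
    "CultureObservation",
    "OrganismEntry",
    "OrganismCatalog",
    "AdjudicationPolicy",
    "Adjudication",
    "Sample",
    "classify_organism",
    "adjudicate_sample",
    "adjudicate_cohort",
    "validate_record",
    "default_catalog",
]


class GrowthStatus(str, enum.Enum):
    NO_GROWTH = "no_growth"
    MIXED_CONTAMINANTS = "mixed_contaminants"
    GROWTH = "growth"


class UropathogenClass(str, enum.Enum):
    CLASSIC = "classic"
    NON_CLASSIC = "non_classic"
    UNKNOWN = "unknown"


class GramClass(str, enum.Enum):
    GRAM_POSITIVE = "gram_positive"
    GRAM_NEGATIVE = "gram_negative"
    YEAST = "yeast"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class SedimentResult:
    """Automated sediment counts, both in particles per microliter."""

    leukocytes: float
    bacteria: float

    def __post_init__(self):
        for name in ("leukocytes", "bacteria"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise InputError(f"{name} must be a number, got {v!r}")
            if not math.isfinite(v) or v < 0:
                raise InputError(f"{name} must be finite and >= 0, got {v!r}")


@dataclass(frozen=True)
class Isolate:
    """One cultured organism with its quantitative growth in cfu/ml."""

    organism: str
    cfu_per_ml: float

    def __post_init__(self):
        if not self.organism:
            raise InputError("isolate organism name must be non-empty")
        if not math.isfinite(self.cfu_per_ml) or self.cfu_per_ml < 0:
            raise InputError(
                f"cfu_per_ml must be finite and >= 0, got {self.cfu_per_ml!r}"
            )


@dataclass(frozen=True)
class CultureObservation:
    """Culture outcome: growth status, isolates, and treatment flags.

    ``antibiotics_needed`` records whether the clinician needed antibiotics for
    this episode; ``clinically_relevant`` whether treatment was actually given
    (for symptomatic UTI or as pre-procedure prophylaxis).  Missing flags
    default to False, which is conservative toward the negative clauses.
    """

    growth_status: GrowthStatus
    isolates: tuple[Isolate, ...] = ()
    antibiotics_needed: bool = False
    clinically_relevant: bool | None = None

    def __post_init__(self):
        status = GrowthStatus(self.growth_status)
        object.__setattr__(self, "growth_status", status)
        object.__setattr__(self, "isolates", tuple(self.isolates))
        if status is GrowthStatus.GROWTH and not self.isolates:
            raise InputError("growth_status=growth requires at least one isolate")
        if status is not GrowthStatus.GROWTH and self.isolates:
            raise InputError(f"growth_status={status.value} forbids isolates")


@dataclass(frozen=True)
class OrganismEntry:
    uropathogen_class: UropathogenClass
    gram_class: GramClass


#: Default catalog.  Classic uropathogens per conventional urinary
#: microbiology; every species of the default cohort resolves here.
_DEFAULT_ENTRIES: dict[str, OrganismEntry] = {
    # classic uropathogens
    "Escherichia coli": OrganismEntry(UropathogenClass.CLASSIC, GramClass.GRAM_NEGATIVE),
    "Klebsiella pneumoniae": OrganismEntry(UropathogenClass.CLASSIC, GramClass.GRAM_NEGATIVE),
    "Klebsiella oxytoca": OrganismEntry(UropathogenClass.CLASSIC, GramClass.GRAM_NEGATIVE),
    "Proteus mirabilis": OrganismEntry(UropathogenClass.CLASSIC, GramClass.GRAM_NEGATIVE),
    "Enterobacter cloacae": OrganismEntry(UropathogenClass.CLASSIC, GramClass.GRAM_NEGATIVE),
    "Pseudomonas aeruginosa": OrganismEntry(UropathogenClass.CLASSIC, GramClass.GRAM_NEGATIVE),
    "Enterococcus faecalis": OrganismEntry(UropathogenClass.CLASSIC, GramClass.GRAM_POSITIVE),
    "Staphylococcus saprophyticus": OrganismEntry(UropathogenClass.CLASSIC, GramClass.GRAM_POSITIVE),
    "Staphylococcus aureus": OrganismEntry(UropathogenClass.CLASSIC, GramClass.GRAM_POSITIVE),
    "Aerococcus urinae": OrganismEntry(UropathogenClass.CLASSIC, GramClass.GRAM_POSITIVE),
    "Actinobaculum schaalii": OrganismEntry(UropathogenClass.CLASSIC, GramClass.GRAM_POSITIVE),
    "Beta hemolytic streptococcus B": OrganismEntry(UropathogenClass.CLASSIC, GramClass.GRAM_POSITIVE),
    # non-classic organisms (skin/mucosal flora, environmental species, yeast)
    "Staphylococcus epidermidis": OrganismEntry(UropathogenClass.NON_CLASSIC, GramClass.GRAM_POSITIVE),
    "Candida species": OrganismEntry(UropathogenClass.NON_CLASSIC, GramClass.YEAST),
    "Corynebacterium species": OrganismEntry(UropathogenClass.NON_CLASSIC, GramClass.GRAM_POSITIVE),
    "Lactobacillus species": OrganismEntry(UropathogenClass.NON_CLASSIC, GramClass.GRAM_POSITIVE),
    "Viridans streptococci": OrganismEntry(UropathogenClass.NON_CLASSIC, GramClass.GRAM_POSITIVE),
    "Acinetobacter species": OrganismEntry(UropathogenClass.NON_CLASSIC, GramClass.GRAM_NEGATIVE),
    "Stenotrophomonas maltophilia": OrganismEntry(UropathogenClass.NON_CLASSIC, GramClass.GRAM_NEGATIVE),
}

_UNKNOWN_ENTRY = OrganismEntry(UropathogenClass.UNKNOWN, GramClass.UNKNOWN)


@dataclass(frozen=True)
class OrganismCatalog:
    """Species name -> (uropathogen class, Gram class) lookup table."""

    entries: Mapping[str, OrganismEntry]

    def __post_init__(self):
        object.__setattr__(self, "entries", dict(self.entries))
        if not self.entries:
            raise InputError("organism catalog must be non-empty")

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def get(self, name: str) -> OrganismEntry | None:
        return self.entries.get(name)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "OrganismCatalog":
        """Load a catalog from a YAML mapping
        ``{species: {uropathogen_class: ..., gram_class: ...}}``."""
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if not isinstance(raw, dict):
            raise InputError(f"catalog file {path} must contain a mapping")
        entries = {}
        for name, spec in raw.items():
            entries[str(name)] = OrganismEntry(
                UropathogenClass(spec["uropathogen_class"]),
                GramClass(spec["gram_class"]),
            )
        return cls(entries)

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            name: {
                "uropathogen_class": e.uropathogen_class.value,
                "gram_class": e.gram_class.value,
            }
            for name, e in sorted(self.entries.items())
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False), encoding="utf-8")


def default_catalog() -> OrganismCatalog:
    """The catalog shipped with the package (all default-cohort species resolve)."""
    return OrganismCatalog(dict(_DEFAULT_ENTRIES))


@dataclass(frozen=True)
class AdjudicationPolicy:
    """Thresholds of the five negative clauses.

    ``cfu_high`` (10^5 cfu/ml) bounds the non-classic low-count clause,
    ``cfu_low`` (10^4 cfu/ml) the classic low-count clause, and
    ``pyuria_threshold`` (20 leukocytes/µL) the "no pyuria" condition.
    ``unknown_fallback`` optionally maps unresolvable species to a class
    instead of raising.
    """

    cfu_high: float = 1e5
    cfu_low: float = 1e4
    pyuria_threshold: float = 20.0
    unknown_fallback: UropathogenClass | None = None

    def __post_init__(self):
        if not self.cfu_low < self.cfu_high:
            raise InputError("cfu_low must be < cfu_high")
        if not self.pyuria_threshold > 0:
            raise InputError("pyuria_threshold must be > 0")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "AdjudicationPolicy":
        kwargs = dict(raw)
        if kwargs.get("unknown_fallback") is not None:
            kwargs["unknown_fallback"] = UropathogenClass(kwargs["unknown_fallback"])
        return cls(**kwargs)


@dataclass(frozen=True)
class Adjudication:
    label: str  # "positive" | "negative"
    reason: str  # clause code, or "default_positive"


@dataclass
class Sample:
    """One urine sample: sediment counts plus culture outcome.

    ``adjudicated`` is set only by :func:`adjudicate_sample` /
    :func:`adjudicate_cohort`.
    """

    sample_id: str
    sediment: SedimentResult
    culture: CultureObservation
    adjudicated: Adjudication | None = field(default=None, compare=True)

    @property
    def is_positive(self) -> bool:
        if self.adjudicated is None:
            raise AdjudicationError(f"sample {self.sample_id} not adjudicated")
        return self.adjudicated.label == "positive"


def classify_organism(name: str, catalog: OrganismCatalog) -> OrganismEntry:
    """Look up a species in the catalog.

    Unknown names return the sentinel ``(unknown, unknown)`` entry and emit an
    :class:`UnknownOrganismWarning`; an empty name is an input error.
    """
    if not name:
        raise InputError("organism name must be non-empty")
    entry = catalog.get(name)
    if entry is None:
        warnings.warn(
            f"organism {name!r} not in catalog; classified as unknown",
            UnknownOrganismWarning,
            stacklevel=2,
        )
        return _UNKNOWN_ENTRY
    return entry


# Clause codes, in the order the clauses are checked.
CLAUSE_NO_GROWTH = "no_growth"
CLAUSE_MIXED = "mixed_contaminants"
CLAUSE_NONCLASSIC_LOW = "nonclassic_low_count"
CLAUSE_NONCLASSIC_NO_PYURIA = "nonclassic_no_pyuria_no_abx"
CLAUSE_CLASSIC_LOW = "classic_low_count_no_pyuria"
DEFAULT_POSITIVE = "default_positive"


def _isolate_negative_clause(
    isolate: Isolate,
    sediment: SedimentResult,
    antibiotics_needed: bool,
    catalog: OrganismCatalog,
    policy: AdjudicationPolicy,
) -> str | None:
    """Return the code of the first negative clause this isolate satisfies, else None."""
    entry = classify_organism(isolate.organism, catalog)
    klass = entry.uropathogen_class
    if klass is UropathogenClass.UNKNOWN:
        if policy.unknown_fallback is None:
            raise AdjudicationError(
                f"cannot adjudicate growth of unknown organism {isolate.organism!r} "
                "(no unknown_fallback configured)"
            )
        klass = policy.unknown_fallback
    no_pyuria = sediment.leukocytes < policy.pyuria_threshold
    if klass is UropathogenClass.NON_CLASSIC:
        if isolate.cfu_per_ml < policy.cfu_high:
            return CLAUSE_NONCLASSIC_LOW
        if no_pyuria and not antibiotics_needed:
            return CLAUSE_NONCLASSIC_NO_PYURIA
    else:  # classic
        if isolate.cfu_per_ml <= policy.cfu_low and no_pyuria and not antibiotics_needed:
            return CLAUSE_CLASSIC_LOW
    return None


def adjudicate_sample(
    sample: Sample,
    catalog: OrganismCatalog | None = None,
    policy: AdjudicationPolicy | None = None,
) -> Adjudication:
    """Adjudicate one culture as positive or negative under the five clauses.

    Pure function of ``(sample, catalog, policy)``; the returned reason is the
    first matching clause in clause order (for multi-isolate cultures, the
    first isolate's clause — the culture is negative only if *every* isolate
    satisfies some negative clause).
    """
    catalog = catalog or default_catalog()
    policy = policy or AdjudicationPolicy()
    culture = sample.culture
    if culture.growth_status is GrowthStatus.NO_GROWTH:
        return Adjudication("negative", CLAUSE_NO_GROWTH)
    if culture.growth_status is GrowthStatus.MIXED_CONTAMINANTS:
        return Adjudication("negative", CLAUSE_MIXED)
    clauses = [
        _isolate_negative_clause(
            iso, sample.sediment, culture.antibiotics_needed, catalog, policy
        )
        for iso in culture.isolates
    ]
    if all(c is not None for c in clauses):
        return Adjudication("negative", clauses[0])
    return Adjudication("positive", DEFAULT_POSITIVE)


def adjudicate_cohort(
    samples: Iterable[Sample],
    catalog: OrganismCatalog | None = None,
    policy: AdjudicationPolicy | None = None,
) -> list[Sample]:
    """Adjudicate every sample, setting ``sample.adjudicated`` in place."""
    samples = list(samples)
    for s in samples:
        s.adjudicated = adjudicate_sample(s, catalog, policy)
    return samples


_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no", ""}


def _parse_bool(raw: str, fieldname: str, errors: list[str], *, optional=False):
    raw = raw.strip().lower()
    if raw in _TRUE:
        return True
    if raw in _FALSE:
        if optional and raw == "":
            return None
        return False
    errors.append(f"{fieldname}: cannot parse boolean from {raw!r}")
    return None


def _parse_number(raw: str, fieldname: str, errors: list[str]) -> float | None:
    raw = raw.strip()
    if "," in raw:
        errors.append(f"{fieldname}: decimal comma in {raw!r}; use a decimal point")
        return None
    try:
        v = float(raw)
    except ValueError:
        errors.append(f"{fieldname}: cannot parse number from {raw!r}")
        return None
    if not math.isfinite(v):
        errors.append(f"{fieldname}: non-finite value {raw!r}")
        return None
    if v < 0:
        errors.append(f"{fieldname}: negative count {v}")
        return None
    return v


def validate_record(raw: Mapping[str, str]) -> Sample | list[str]:
    """Build a Sample from a raw field map, or return the full list of violations.

    Never raises on bad data; every field-level problem (negative counts,
    growth/isolate inconsistency, unparseable cfu, decimal commas) is
    accumulated and reported together.
    """
    errors: list[str] = []
    sample_id = str(raw.get("sample_id", "") or "").strip()
    if not sample_id:
        errors.append("sample_id: missing")

    leuk = _parse_number(str(raw.get("leukocytes_per_ul", "")), "leukocytes_per_ul", errors)
    bact = _parse_number(str(raw.get("bacteria_per_ul", "")), "bacteria_per_ul", errors)

    status_raw = str(raw.get("growth_status", "")).strip()
    status: GrowthStatus | None = None
    try:
        status = GrowthStatus(status_raw)
    except ValueError:
        errors.append(f"growth_status: unknown value {status_raw!r}")

    organisms = [o.strip() for o in str(raw.get("organisms", "") or "").split(";") if o.strip()]
    cfu_raw = [c.strip() for c in str(raw.get("cfu_per_ml", "") or "").split(";") if c.strip()]
    isolates: list[Isolate] = []
    if organisms or cfu_raw:
        if len(organisms) != len(cfu_raw):
            errors.append(
                f"cfu_per_ml: {len(cfu_raw)} values for {len(organisms)} organisms"
            )
        else:
            for org, cfu in zip(organisms, cfu_raw):
                v = _parse_number(cfu, f"cfu_per_ml[{org}]", errors)
                if v is not None:
                    isolates.append(Isolate(org, v))

    if status is GrowthStatus.GROWTH and not organisms:
        errors.append("organisms: growth_status=growth but no organisms listed")
    if status in (GrowthStatus.NO_GROWTH, GrowthStatus.MIXED_CONTAMINANTS) and organisms:
        errors.append(f"organisms: isolate/status mismatch ({status.value} with isolates)")

    abx = _parse_bool(str(raw.get("antibiotics_needed", "") or ""), "antibiotics_needed", errors)
    clin = _parse_bool(
        str(raw.get("clinically_relevant", "") or ""),
        "clinically_relevant",
        errors,
        optional=True,
    )

    if errors:
        return errors
    return Sample(
        sample_id=sample_id,
        sediment=SedimentResult(leukocytes=leuk, bacteria=bact),
        culture=CultureObservation(
            growth_status=status,
            isolates=tuple(isolates),
            antibiotics_needed=bool(abx),
            clinically_relevant=clin,
        ),
    )
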