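"""Calibrated synthetic cohorts for the reflex-screening analysis.

No raw per-sample data were deposited by the underlying study, but its
printed marginals fully determine a stratified cohort: growth-status mix,
species mix among growth cultures, the screen-by-adjudication 2x2 under the
adopted cut-off, the cost-category counts among avoided cultures, and the
species/treatment breakdown of the missed positives.  This module generates
cohorts whose raw attributes (leukocytes/µL, bacteria/µL, cfu/ml, flags) are
drawn inside each stratum's admissible region, so that re-deriving the strata
*through the analysis code* (adjudication clauses + screening rules, not
construction labels) reproduces the spec's counts exactly.

Generation is count-exact by default (the printed tables are exact counts);
an optional multinomial mode draws stratum membership stochastically for
robustness experiments.  All randomness flows through per-sample keyed
streams (``SeedSequence([seed, stratum, index])``), so a (spec, seed) pair
reproduces the identical cohort on any platform.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_model import (
    AdjudicationPolicy,
    CultureObservation,
    GrowthStatus,
    Isolate,
    OrganismCatalog,
    Sample,
    SedimentResult,
    adjudicate_sample,
    default_catalog,
)
from .evaluation import round_half_up
from .exceptions import InfeasibleSpecError, InputError
from .screening import ADOPTED_RULE_TEXT, ScreeningRule, legacy_trigger, parse_rule

__all__ = [
    "Stratum",
    "CohortSpec",
    "default_spec",
    "generate_cohort",
    "summarize_cohort",
    "DEFAULT_NAMED_SPECIES",
]


#: Species listed individually in the cohort species table; everything else
#: aggregates under "Other", multi-isolate cultures under "Polymicrobial".
DEFAULT_NAMED_SPECIES = (
    "Escherichia coli",
    "Klebsiella pneumoniae",
    "Enterococcus faecalis",
    "Proteus mirabilis",
    "Beta hemolytic streptococcus B",
    "Staphylococcus epidermidis",
    "Pseudomonas aeruginosa",
    "Aerococcus urinae",
    "Staphylococcus aureus",
    "Klebsiella oxytoca",
    "Enterobacter cloacae",
    "Actinobaculum schaalii",
    "Candida species",
)

OTHER_LABEL = "Other"
POLYMICROBIAL_LABEL = "Polymicrobial"


@dataclass(frozen=True)
class Stratum:
    """One homogeneous cell of the cohort design.

    ``leukocytes``/``bacteria`` are inclusive admissible intervals (per µL);
    ``cfu_log10`` holds one log10-cfu interval per organism.  ``screen_positive``
    and ``label`` state the side of the adopted rule and the adjudication the
    whole region must land on — the generator *verifies* this through the
    analysis code rather than trusting it.
    """

    name: str
    count: int
    growth_status: GrowthStatus
    screen_positive: bool
    label: str  # expected adjudication: "positive" | "negative"
    leukocytes: tuple[float, float]
    bacteria: tuple[float, float]
    organisms: tuple[str, ...] = ()
    cfu_log10: tuple[tuple[float, float], ...] = ()
    antibiotics_needed: bool = False
    treatment: str = "none"  # none | symptomatic | prophylaxis
    leuk_lognorm: tuple[float, float] | None = None  # (mu, sigma) overrides
    bact_lognorm: tuple[float, float] | None = None

    @property
    def clinically_relevant(self) -> bool:
        return self.treatment != "none"


def _interval_ok(lo: float, hi: float) -> bool:
    return np.isfinite(lo) and np.isfinite(hi) and 0 <= lo <= hi


def _corner_samples(st: Stratum) -> list[Sample]:
    """Extreme-corner samples of a stratum's admissible region.

    The adjudication clauses are monotone in leukocytes and cfu (negative
    clauses require low values of both), so checking the 2^(1+k) corners of
    the (leukocytes, cfu_1..cfu_k) box certifies the label over the region.
    """
    leuk_corners = {st.leukocytes[0], st.leukocytes[1]}
    bact_mid = 0.5 * (st.bacteria[0] + st.bacteria[1])
    if st.growth_status is not GrowthStatus.GROWTH:
        cfu_sets: list[tuple[float, ...]] = [()]
    else:
        cfu_sets = [()]
        for lo, hi in st.cfu_log10:
            cfu_sets = [c + (v,) for c in cfu_sets for v in {10.0**lo, 10.0**hi}]
    out = []
    for leuk in leuk_corners:
        for cfus in cfu_sets:
            isolates = tuple(
                Isolate(org, cfu) for org, cfu in zip(st.organisms, cfus)
            )
            out.append(
                Sample(
                    sample_id=f"corner:{st.name}",
                    sediment=SedimentResult(leukocytes=leuk, bacteria=bact_mid),
                    culture=CultureObservation(
                        growth_status=st.growth_status,
                        isolates=isolates,
                        antibiotics_needed=st.antibiotics_needed,
                        clinically_relevant=st.clinically_relevant,
                    ),
                )
            )
    return out


@dataclass(frozen=True)
class CohortSpec:
    """Stratum counts plus distribution parameters for a calibrated cohort."""

    strata: tuple[Stratum, ...]
    rule_text: str = ADOPTED_RULE_TEXT
    description: str = ""

    def __post_init__(self):
        object.__setattr__(self, "strata", tuple(self.strata))
        if not self.strata:
            raise InputError("a cohort spec needs at least one stratum")

    # -- derived marginals ---------------------------------------------------

    @property
    def n_total(self) -> int:
        return sum(s.count for s in self.strata)

    @property
    def rule(self) -> ScreeningRule:
        return parse_rule(self.rule_text)

    @property
    def growth_status_counts(self) -> dict[str, int]:
        c: Counter[str] = Counter()
        for s in self.strata:
            c[s.growth_status.value] += s.count
        return dict(c)

    @property
    def stratum_counts(self) -> dict[tuple[bool, str], int]:
        """Joint (screen_positive, label) counts — the 2x2 of the adopted rule."""
        c: Counter[tuple[bool, str]] = Counter()
        for s in self.strata:
            c[(s.screen_positive, s.label)] += s.count
        return dict(c)

    @property
    def species_mix(self) -> dict[str, int]:
        """Monomicrobial growth cultures by species (polymicrobial excluded)."""
        c: Counter[str] = Counter()
        for s in self.strata:
            if s.growth_status is GrowthStatus.GROWTH and len(s.organisms) == 1:
                c[s.organisms[0]] += s.count
        return dict(c)

    @property
    def missed_species_counts(self) -> dict[str, int]:
        c: Counter[str] = Counter()
        for s in self.strata:
            if s.label == "positive" and not s.screen_positive:
                c[s.organisms[0]] += s.count
        return dict(c)

    @property
    def missed_clinical(self) -> dict[str, int]:
        c = {"no_treatment": 0, "symptomatic_treated": 0, "prophylaxis": 0}
        key = {"none": "no_treatment", "symptomatic": "symptomatic_treated", "prophylaxis": "prophylaxis"}
        for s in self.strata:
            if s.label == "positive" and not s.screen_positive:
                c[key[s.treatment]] += s.count
        return c

    # -- feasibility ---------------------------------------------------------

    def validate(
        self,
        catalog: OrganismCatalog | None = None,
        policy: AdjudicationPolicy | None = None,
    ) -> None:
        """Check every populated stratum has a non-empty admissible region.

        Raises :class:`InfeasibleSpecError` naming the first offending
        stratum.  The screen-side check evaluates the adopted rule at the
        region's extreme corners, which certifies the whole region for
        rules monotone in both counts (all threshold rules are).
        """
        catalog = catalog or default_catalog()
        policy = policy or AdjudicationPolicy()
        rule = self.rule
        for st in self.strata:
            if st.count < 0:
                raise InfeasibleSpecError(f"stratum {st.name!r}: negative count")
            if st.count == 0:
                continue
            if not _interval_ok(*st.leukocytes):
                raise InfeasibleSpecError(
                    f"stratum {st.name!r}: empty leukocyte interval {st.leukocytes}"
                )
            if not _interval_ok(*st.bacteria):
                raise InfeasibleSpecError(
                    f"stratum {st.name!r}: empty bacteria interval {st.bacteria}"
                )
            if st.growth_status is GrowthStatus.GROWTH:
                if not st.organisms or len(st.organisms) != len(st.cfu_log10):
                    raise InfeasibleSpecError(
                        f"stratum {st.name!r}: organisms and cfu_log10 must align"
                    )
                for (lo, hi), org in zip(st.cfu_log10, st.organisms):
                    if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                        raise InfeasibleSpecError(
                            f"stratum {st.name!r}: empty cfu interval for {org}"
                        )
            elif st.organisms:
                raise InfeasibleSpecError(
                    f"stratum {st.name!r}: isolates without growth status"
                )
            # every sample must satisfy the legacy trigger
            if not (st.bacteria[0] >= 130 or st.leukocytes[0] > 50):
                raise InfeasibleSpecError(
                    f"stratum {st.name!r}: region not contained in the legacy "
                    "trigger (needs bacteria >= 130 or leukocytes > 50 throughout)"
                )
            # the whole region must land on the declared side of the rule
            lo_sed = SedimentResult(st.leukocytes[0], st.bacteria[0])
            hi_sed = SedimentResult(st.leukocytes[1], st.bacteria[1])
            if st.screen_positive and not rule.applies(lo_sed):
                raise InfeasibleSpecError(
                    f"stratum {st.name!r}: declared screen-positive but the rule "
                    f"{rule.text!r} fails at the region's lower corner"
                )
            if not st.screen_positive and rule.applies(hi_sed):
                raise InfeasibleSpecError(
                    f"stratum {st.name!r}: declared screen-negative but the rule "
                    f"{rule.text!r} holds inside the region"
                )
            # the whole region must adjudicate to the declared label
            for corner in _corner_samples(st):
                adj = adjudicate_sample(corner, catalog, policy)
                if adj.label != st.label:
                    raise InfeasibleSpecError(
                        f"stratum {st.name!r}: declared {st.label} but a corner of "
                        f"its region adjudicates {adj.label} ({adj.reason})"
                    )


# ---------------------------------------------------------------------------
# The default calibrated spec
# ---------------------------------------------------------------------------

# Attribute regions (inclusive bounds).  Screen-negative samples need
# leukocytes <= 20 and bacteria band <= + ; with the legacy trigger this
# forces bacteria into [130, 330].  Strata whose *negative* adjudication
# depends on "< 20 leukocytes" use 19.5 as the upper bound so the strict
# comparison holds throughout the region.
_SNEG = {"leukocytes": (0.0, 20.0), "bacteria": (130.0, 330.0)}
_SNEG_NOPYURIA = {"leukocytes": (0.0, 19.5), "bacteria": (130.0, 330.0)}
_SPOS_LEUK = {"leukocytes": (20.5, 1500.0), "bacteria": (130.0, 4000.0)}
# leukocyte-driven samples entering through the trigger's leukocyte arm only
# (band-negative bacteriuria), as both trigger arms occur in practice
_SPOS_LEUK_LOWBACT = {"leukocytes": (50.5, 1500.0), "bacteria": (0.0, 129.0)}
_SPOS_BACT = {"leukocytes": (0.0, 19.5), "bacteria": (335.0, 20000.0)}

# log10 cfu/ml intervals per adjudication role
_CFU_CLASSIC_POS = ((5.0, 8.0),)       # classic uropathogen, unambiguously positive
_CFU_CLASSIC_MISSED = ((4.05, 6.0),)   # classic, > 10^4: positive even without pyuria
_CFU_CLASSIC_NEG = ((2.0, 4.0),)       # classic, <= 10^4, no pyuria, no antibiotics
_CFU_NONCLASSIC_NEG = ((2.0, 4.95),)   # non-classic, < 10^5

# true-positive cultures by species (screen-positive, classic, high count)
_TP_SPECIES = (
    ("Escherichia coli", 381),
    ("Klebsiella pneumoniae", 81),
    ("Enterococcus faecalis", 64),
    ("Proteus mirabilis", 45),
    ("Beta hemolytic streptococcus B", 42),
    ("Pseudomonas aeruginosa", 21),
    ("Aerococcus urinae", 16),
    ("Staphylococcus aureus", 13),
    ("Klebsiella oxytoca", 11),
    ("Enterobacter cloacae", 9),
    ("Actinobaculum schaalii", 8),
)

# missed positives: (species, treatment, count); 21 untreated, 6 treated for
# symptomatic UTI, 5 given pre-procedure prophylaxis
_MISSED = (
    ("Escherichia coli", "none", 12),
    ("Escherichia coli", "symptomatic", 4),
    ("Escherichia coli", "prophylaxis", 3),
    ("Enterococcus faecalis", "none", 3),
    ("Enterococcus faecalis", "symptomatic", 1),
    ("Enterococcus faecalis", "prophylaxis", 1),
    ("Proteus mirabilis", "none", 2),
    ("Proteus mirabilis", "prophylaxis", 1),
    ("Klebsiella pneumoniae", "none", 2),
    ("Beta hemolytic streptococcus B", "none", 1),
    ("Staphylococcus aureus", "none", 1),
    ("Pseudomonas aeruginosa", "symptomatic", 1),
)

# screen-negative growth cultures adjudicated negative (low-count flora and
# low-count classic organisms without pyuria); Gram classes calibrated so the
# avoided-culture workup categories come out at 38 / 53 / 3
_SNEG_NEG_GROWTH = (
    ("Staphylococcus epidermidis", _CFU_NONCLASSIC_NEG, 10),
    ("Candida species", _CFU_NONCLASSIC_NEG, 2),
    ("Corynebacterium species", _CFU_NONCLASSIC_NEG, 10),
    ("Viridans streptococci", _CFU_NONCLASSIC_NEG, 5),
    ("Lactobacillus species", _CFU_NONCLASSIC_NEG, 4),
    ("Acinetobacter species", _CFU_NONCLASSIC_NEG, 15),
    ("Stenotrophomonas maltophilia", _CFU_NONCLASSIC_NEG, 10),
    ("Escherichia coli", _CFU_CLASSIC_NEG, 3),
)

# screen-positive growth cultures adjudicated negative (unnecessary cultures
# the adopted rule still performs)
_SPOS_NEG_GROWTH_LEUK = (
    ("Staphylococcus epidermidis", _CFU_NONCLASSIC_NEG, 18),
    ("Candida species", _CFU_NONCLASSIC_NEG, 2),
    ("Corynebacterium species", _CFU_NONCLASSIC_NEG, 20),
    ("Viridans streptococci", _CFU_NONCLASSIC_NEG, 15),
    ("Lactobacillus species", _CFU_NONCLASSIC_NEG, 11),
)
_SPOS_NEG_GROWTH_BACT = (
    ("Escherichia coli", _CFU_CLASSIC_NEG, 5),
    ("Klebsiella pneumoniae", _CFU_CLASSIC_NEG, 2),
    ("Proteus mirabilis", _CFU_CLASSIC_NEG, 1),
    ("Enterococcus faecalis", _CFU_CLASSIC_NEG, 1),
    ("Beta hemolytic streptococcus B", _CFU_CLASSIC_NEG, 1),
)

# polymicrobial mixed-Gram cultures (priced as "both"); all isolates are
# low-count flora so the culture adjudicates negative
_BOTH_PAIR = ("Staphylococcus epidermidis", "Acinetobacter species")
_CFU_BOTH = (_CFU_NONCLASSIC_NEG[0], _CFU_NONCLASSIC_NEG[0])


def default_spec() -> CohortSpec:
    """The calibrated default cohort: 2,821 urology-outpatient samples.

    Marginals: growth status 1356 / 600 / 865; adjudication 2098 negative,
    723 positive; adopted-rule 2x2 cells tn=1019, fn=32, fp=1079, tp=691;
    avoided-culture workup categories 957 / 38 / 53 / 3; species mix with
    E. coli 408 of 865; missed cultures 19 E. coli, 5 E. faecalis,
    3 P. mirabilis, 5 various, of which 21 untreated and 11 clinically
    relevant (6 symptomatic + 5 prophylaxis).
    """
    strata: list[Stratum] = []

    def add(name, count, status, screen_pos, label, region, organisms=(), cfu=(),
            abx=False, treatment="none"):
        strata.append(
            Stratum(
                name=name,
                count=count,
                growth_status=status,
                screen_positive=screen_pos,
                label=label,
                leukocytes=region["leukocytes"],
                bacteria=region["bacteria"],
                organisms=tuple(organisms),
                cfu_log10=tuple(cfu),
                antibiotics_needed=abx,
                treatment=treatment,
            )
        )

    # cultures without significant growth; part of the screen-positives enter
    # through the trigger's leukocyte arm with band-negative bacteriuria
    add("no_growth/screen_neg", 663, GrowthStatus.NO_GROWTH, False, "negative", _SNEG)
    add("no_growth/screen_pos", 473, GrowthStatus.NO_GROWTH, True, "negative", _SPOS_LEUK)
    add("no_growth/screen_pos_lowbact", 220, GrowthStatus.NO_GROWTH, True, "negative",
        _SPOS_LEUK_LOWBACT)
    add("mixed/screen_neg", 294, GrowthStatus.MIXED_CONTAMINANTS, False, "negative", _SNEG)
    add("mixed/screen_pos", 216, GrowthStatus.MIXED_CONTAMINANTS, True, "negative", _SPOS_LEUK)
    add("mixed/screen_pos_lowbact", 90, GrowthStatus.MIXED_CONTAMINANTS, True, "negative",
        _SPOS_LEUK_LOWBACT)

    # true positives: classic uropathogens at high count, screened in
    for species, n in _TP_SPECIES:
        n_lowbact = n // 5  # a fifth present without significant bacteriuria
        add(
            f"tp/{species}", n - n_lowbact, GrowthStatus.GROWTH, True, "positive",
            _SPOS_LEUK, (species,), _CFU_CLASSIC_POS, abx=True, treatment="symptomatic",
        )
        if n_lowbact:
            add(
                f"tp/{species}/lowbact", n_lowbact, GrowthStatus.GROWTH, True, "positive",
                _SPOS_LEUK_LOWBACT, (species,), _CFU_CLASSIC_POS,
                abx=True, treatment="symptomatic",
            )

    # missed positives: classic uropathogens above 10^4 cfu/ml without pyuria
    for species, treatment, n in _MISSED:
        add(
            f"missed/{species}/{treatment}", n, GrowthStatus.GROWTH, False, "positive",
            _SNEG, (species,), _CFU_CLASSIC_MISSED,
            abx=(treatment != "none"), treatment=treatment,
        )

    # screen-negative growth adjudicated negative
    for species, cfu, n in _SNEG_NEG_GROWTH:
        add(
            f"avoided_growth/{species}", n, GrowthStatus.GROWTH, False, "negative",
            _SNEG_NOPYURIA, (species,), cfu,
        )
    add(
        "avoided_growth/mixed_gram", 3, GrowthStatus.GROWTH, False, "negative",
        _SNEG_NOPYURIA, _BOTH_PAIR, _CFU_BOTH,
    )

    # screen-positive growth adjudicated negative
    for species, cfu, n in _SPOS_NEG_GROWTH_LEUK:
        add(
            f"cultured_negative/{species}", n, GrowthStatus.GROWTH, True, "negative",
            _SPOS_LEUK, (species,), cfu,
        )
    for species, cfu, n in _SPOS_NEG_GROWTH_BACT:
        add(
            f"cultured_negative_bacteriuria/{species}", n, GrowthStatus.GROWTH, True,
            "negative", _SPOS_BACT, (species,), cfu,
        )
    add(
        "cultured_negative/mixed_gram", 4, GrowthStatus.GROWTH, True, "negative",
        _SPOS_LEUK, _BOTH_PAIR, _CFU_BOTH,
    )

    return CohortSpec(
        strata=tuple(strata),
        rule_text=ADOPTED_RULE_TEXT,
        description="calibrated urology-outpatient cohort, n=2821",
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _trunc_lognormal(rng: np.random.Generator, lo: float, hi: float,
                     params: tuple[float, float] | None) -> float:
    """Log-normal draw truncated to [lo, hi] by rejection.

    Without explicit (mu, sigma), mu sits at the log-midpoint of the interval
    (acceptance well above 10%); after 200 rejections the draw falls back to
    uniform on the interval, keeping generation total.
    """
    if hi <= lo:
        return lo
    lo_eff = max(lo, 0.5)
    if params is None:
        mu = 0.5 * (np.log(lo_eff) + np.log(hi))
        sigma = 0.6
    else:
        mu, sigma = params
    for _ in range(200):
        x = rng.lognormal(mu, sigma)
        if lo <= x <= hi:
            return float(x)
    return float(rng.uniform(lo, hi))


def generate_cohort(
    spec: CohortSpec,
    seed: int,
    mode: str = "exact",
    scale: float = 1.0,
    catalog: OrganismCatalog | None = None,
    policy: AdjudicationPolicy | None = None,
    check: bool = True,
) -> list[Sample]:
    """Generate a cohort realising the spec's strata.

    ``mode="exact"`` emits exactly ``count * scale`` samples per stratum;
    ``mode="multinomial"`` draws stratum membership multinomially with the
    spec's proportions (for robustness experiments).  With ``check=True``
    every sample is re-derived through the trigger, the adopted rule, and the
    adjudication clauses, and any mismatch raises — generation is validated
    by the analysis code, not by construction labels.
    """
    if mode not in ("exact", "multinomial"):
        raise InputError(f"mode must be 'exact' or 'multinomial', got {mode!r}")
    if scale <= 0:
        raise InputError("scale must be > 0")
    catalog = catalog or default_catalog()
    policy = policy or AdjudicationPolicy()
    spec.validate(catalog, policy)
    rule = spec.rule

    master = np.random.default_rng([int(seed), 0x5EED])
    if mode == "exact":
        counts = [int(round(st.count * scale)) for st in spec.strata]
    else:
        n = int(round(spec.n_total * scale))
        probs = np.array([st.count for st in spec.strata], dtype=float)
        probs /= probs.sum()
        counts = master.multinomial(n, probs).tolist()

    samples: list[Sample] = []
    for si, (st, n_st) in enumerate(zip(spec.strata, counts)):
        for i in range(n_st):
            rng = np.random.default_rng([int(seed), si, i])
            leuk = _trunc_lognormal(rng, *st.leukocytes, st.leuk_lognorm)
            bact = _trunc_lognormal(rng, *st.bacteria, st.bact_lognorm)
            isolates = tuple(
                Isolate(org, float(10.0 ** rng.uniform(lo, hi)))
                for org, (lo, hi) in zip(st.organisms, st.cfu_log10)
            )
            sample = Sample(
                sample_id="",  # assigned after shuffling
                sediment=SedimentResult(leukocytes=leuk, bacteria=bact),
                culture=CultureObservation(
                    growth_status=st.growth_status,
                    isolates=isolates,
                    antibiotics_needed=st.antibiotics_needed,
                    clinically_relevant=st.clinically_relevant,
                ),
            )
            if check:
                if not legacy_trigger(sample.sediment):
                    raise InfeasibleSpecError(
                        f"stratum {st.name!r}: generated sample misses the legacy trigger"
                    )
                if rule.applies(sample.sediment) != st.screen_positive:
                    raise InfeasibleSpecError(
                        f"stratum {st.name!r}: generated sample lands on the wrong "
                        f"side of {rule.text!r}"
                    )
                adj = adjudicate_sample(sample, catalog, policy)
                if adj.label != st.label:
                    raise InfeasibleSpecError(
                        f"stratum {st.name!r}: generated sample adjudicates "
                        f"{adj.label} ({adj.reason}), expected {st.label}"
                    )
            samples.append(sample)

    order = master.permutation(len(samples))
    shuffled = [samples[i] for i in order]
    width = max(5, len(str(len(shuffled))))
    for k, s in enumerate(shuffled, start=1):
        s.sample_id = f"S{k:0{width}d}"
    return shuffled


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def summarize_cohort(
    samples: Sequence[Sample],
    named_species: Sequence[str] = DEFAULT_NAMED_SPECIES,
    decimals: int = 1,
) -> dict[str, pd.DataFrame]:
    """Marginal tables of a cohort: growth status, species, adjudication.

    Species are tabulated over growth cultures: monomicrobial cultures by
    organism (those outside ``named_species`` pooled as "Other"),
    polymicrobial cultures as one "Polymicrobial" row; percentages use the
    growth-culture denominator.  The adjudication table is present only when
    every sample is adjudicated.
    """
    n = len(samples)
    out: dict[str, pd.DataFrame] = {}

    def pct(c: int, denom: int) -> float:
        return round_half_up(100.0 * c / denom, decimals) if denom else 0.0

    status_counts = Counter(s.culture.growth_status for s in samples)
    status_rows = [
        {
            "result": label,
            "count": status_counts.get(status, 0),
            "percent": pct(status_counts.get(status, 0), n),
        }
        for status, label in (
            (GrowthStatus.NO_GROWTH, "No bacterial growth"),
            (GrowthStatus.MIXED_CONTAMINANTS, "Mixed contaminants"),
            (GrowthStatus.GROWTH, "Bacterial growth"),
        )
    ]
    out["growth_status"] = pd.DataFrame(
        status_rows if n else [], columns=["result", "count", "percent"]
    )

    growth = [s for s in samples if s.culture.growth_status is GrowthStatus.GROWTH]
    species: Counter[str] = Counter()
    for s in growth:
        if len(s.culture.isolates) == 1:
            name = s.culture.isolates[0].organism
            species[name if name in named_species else OTHER_LABEL] += 1
        else:
            species[POLYMICROBIAL_LABEL] += 1
    species_rows = [
        {"species": sp, "count": c, "percent": pct(c, len(growth))}
        for sp, c in species.most_common()
    ]
    out["species"] = pd.DataFrame(
        species_rows if growth else [], columns=["species", "count", "percent"]
    )

    if n and all(s.adjudicated is not None for s in samples):
        npos = sum(1 for s in samples if s.is_positive)
        out["adjudication"] = pd.DataFrame(
            [
                {"label": "negative", "count": n - npos, "percent": pct(n - npos, n)},
                {"label": "positive", "count": npos, "percent": pct(npos, n)},
            ],
            columns=["label", "count", "percent"],
        )
    else:
        out["adjudication"] = pd.DataFrame([], columns=["label", "count", "percent"])
    return out
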