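"""Calibrated cohort spec and count-exact stratified generation."""

import numpy as np
import pytest

from uroscreen import (
    GrowthStatus,
    adjudicate_cohort,
    adjudicate_sample,
    default_spec,
    generate_cohort,
    legacy_trigger,
    parse_rule,
    summarize_cohort,
)
from uroscreen.exceptions import InfeasibleSpecError
from uroscreen.synthetic_cohort import CohortSpec, Stratum


class TestDefaultSpec:
    def test_cohort_size_and_growth_mix(self):
        spec = default_spec()
        assert spec.n_total == 2821
        assert spec.growth_status_counts == {
            "no_growth": 1356,
            "mixed_contaminants": 600,
            "growth": 865,
        }

    def test_screen_by_label_cells(self):
        counts = default_spec().stratum_counts
        assert counts[(False, "negative")] == 1019  # correctly avoided
        assert counts[(False, "positive")] == 32  # missed
        assert counts[(True, "negative")] == 1079  # unnecessarily cultured
        assert counts[(True, "positive")] == 691

    def test_species_mix(self):
        mix = default_spec().species_mix
        assert mix["Escherichia coli"] == 408
        assert mix["Klebsiella pneumoniae"] == 85
        assert mix["Candida species"] == 4
        # monomicrobial cultures; the 7 mixed-Gram cultures sit outside the mix
        assert sum(mix.values()) == 858

    def test_missed_breakdown(self):
        spec = default_spec()
        assert spec.missed_species_counts["Escherichia coli"] == 19
        assert spec.missed_species_counts["Enterococcus faecalis"] == 5
        assert spec.missed_species_counts["Proteus mirabilis"] == 3
        assert sum(spec.missed_species_counts.values()) == 32
        assert spec.missed_clinical == {
            "no_treatment": 21,
            "symptomatic_treated": 6,
            "prophylaxis": 5,
        }

    def test_spec_validates(self):
        default_spec().validate()


class TestGeneration:
    def test_self_consistency_through_the_analysis_code(self):
        """Strata re-derived via adjudication + the rule reproduce the spec exactly.

        The generated labels are not trusted: each sample is pushed through
        adjudicate_sample and the adopted rule, and the resulting joint counts
        must equal the spec's stratum counts.
        """
        spec = default_spec()
        rule = parse_rule(spec.rule_text)
        samples = generate_cohort(spec, seed=20260921, check=False)
        derived = {(True, "positive"): 0, (True, "negative"): 0,
                   (False, "positive"): 0, (False, "negative"): 0}
        for s in samples:
            label = adjudicate_sample(s).label
            derived[(rule.applies(s.sediment), label)] += 1
        assert derived == spec.stratum_counts

    def test_every_sample_satisfies_the_legacy_trigger(self, default_cohort):
        assert all(legacy_trigger(s.sediment) for s in default_cohort)

    def test_reproducibility_same_seed_identical_cohort(self):
        spec = default_spec()
        a = generate_cohort(spec, seed=5, check=False)
        b = generate_cohort(spec, seed=5, check=False)
        assert a == b

    def test_different_seed_same_counts_different_values(self):
        spec = default_spec()
        a = generate_cohort(spec, seed=1, check=False)
        b = generate_cohort(spec, seed=2, check=False)
        assert len(a) == len(b) == spec.n_total
        leuk_a = sorted(s.sediment.leukocytes for s in a)
        leuk_b = sorted(s.sediment.leukocytes for s in b)
        assert leuk_a != leuk_b
        # the count structure is identical by construction
        sa = summarize_cohort(adjudicate_cohort(a))
        sb = summarize_cohort(adjudicate_cohort(b))
        assert sa["growth_status"].equals(sb["growth_status"])
        assert sa["adjudication"].equals(sb["adjudication"])

    def test_contradictory_screen_negative_stratum_is_infeasible(self):
        bad = CohortSpec(
            strata=(
                Stratum(
                    name="impossible",
                    count=5,
                    growth_status=GrowthStatus.NO_GROWTH,
                    screen_positive=False,
                    label="negative",
                    leukocytes=(25.0, 40.0),  # leuk > 20 can never screen negative
                    bacteria=(130.0, 330.0),
                ),
            )
        )
        with pytest.raises(InfeasibleSpecError, match="impossible"):
            generate_cohort(bad, seed=1)

    def test_empty_interval_is_infeasible(self):
        bad = CohortSpec(
            strata=(
                Stratum(
                    name="empty_region",
                    count=1,
                    growth_status=GrowthStatus.NO_GROWTH,
                    screen_positive=False,
                    label="negative",
                    leukocytes=(10.0, 5.0),
                    bacteria=(130.0, 330.0),
                ),
            )
        )
        with pytest.raises(InfeasibleSpecError, match="empty_region"):
            generate_cohort(bad, seed=1)

    def test_region_outside_legacy_trigger_is_infeasible(self):
        bad = CohortSpec(
            strata=(
                Stratum(
                    name="untriggered",
                    count=1,
                    growth_status=GrowthStatus.NO_GROWTH,
                    screen_positive=False,
                    label="negative",
                    leukocytes=(0.0, 20.0),
                    bacteria=(0.0, 100.0),  # below 130 with low leukocytes
                ),
            )
        )
        with pytest.raises(InfeasibleSpecError, match="trigger"):
            generate_cohort(bad, seed=1)

    def test_stochastic_mode_recovers_stratum_proportions(self):
        """Multinomial membership at 10x n stays within 3 SE of spec proportions."""
        spec = default_spec()
        rule = parse_rule(spec.rule_text)
        n = spec.n_total * 10
        samples = generate_cohort(spec, seed=11, mode="multinomial", scale=10, check=False)
        assert len(samples) == n
        derived = {k: 0 for k in spec.stratum_counts}
        for s in samples:
            derived[(rule.applies(s.sediment), adjudicate_sample(s).label)] += 1
        for cell, count in spec.stratum_counts.items():
            p = count / spec.n_total
            se = np.sqrt(p * (1 - p) / n)
            assert abs(derived[cell] / n - p) <= 3 * se, cell


class TestSummaries:
    def test_growth_status_table(self, default_cohort):
        table = summarize_cohort(default_cohort)["growth_status"]
        rows = {r["result"]: (r["count"], r["percent"]) for _, r in table.iterrows()}
        assert rows["No bacterial growth"] == (1356, 48.1)
        assert rows["Mixed contaminants"] == (600, 21.3)
        assert rows["Bacterial growth"] == (865, 30.7)

    def test_species_table(self, default_cohort):
        table = summarize_cohort(default_cohort)["species"]
        rows = {r["species"]: (r["count"], r["percent"]) for _, r in table.iterrows()}
        assert rows["Escherichia coli"] == (408, 47.2)
        assert rows["Other"] == (90, 10.4)
        assert rows["Polymicrobial"] == (7, 0.8)
        assert table["count"].sum() == 865

    def test_empty_cohort_gives_empty_tables(self):
        tables = summarize_cohort([])
        assert all(t.empty for t in tables.values())
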