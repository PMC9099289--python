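"""Dichotomisation, combination carriers, class scan, backward elimination."""

from dataclasses import replace

import pytest

import snpsynergy as ss
from snpsynergy.locus import GenotypeTable
from snpsynergy.simulate import PlantedEffect
from snpsynergy.stats import AnalysisError
from snpsynergy.synergy import CombinationPattern
from snpsynergy.synergy import test_pattern as eval_pattern


def _pooled_table(locus, study_counts):
    cts = study_counts["genotype_counts"][locus.rsid]
    pooled = tuple(a + b for a, b in zip(cts["case"], cts["control"]))
    return GenotypeTable(locus=locus, stratum="all", counts=pooled)


class TestDeriveGrouping:
    def test_reproduces_published_grouping_all_snps(self, panel_loci,
                                                    study_counts):
        """Merge-then-smaller-P reconstructs the published split, 11/11."""
        matches = 0
        for locus in panel_loci:
            if locus.kind != "snp":
                continue
            ps = study_counts["model_p"][locus.rsid]
            g = ss.derive_grouping(
                locus, _pooled_table(locus, study_counts),
                dom_p=ps["dominant"], rec_p=ps["recessive"],
            )
            pub = study_counts["published_grouping"][locus.rsid]
            if (g.group1 == frozenset(pub["group1"])
                    and g.group2 == frozenset(pub["group2"])):
                matches += 1
        assert matches == 11

    def test_rare_homozygote_merge_takes_precedence(self, panel_loci,
                                                    study_counts):
        """rs12026: recessive P is smaller, yet the rare CC (27/1026)
        is merged into the heterozygote group."""
        locus = next(l for l in panel_loci if l.rsid == "rs12026")
        g = ss.derive_grouping(
            locus, _pooled_table(locus, study_counts),
            dom_p=0.90, rec_p=0.094,
        )
        assert g.rule_used == "rare_hom_merge"
        assert g.group1 == frozenset({"hom_ref"})
        assert g.group2 == frozenset({"het", "hom_alt"})

    def test_smaller_p_selects_model(self, panel_loci, study_counts):
        rs12441817 = next(l for l in panel_loci if l.rsid == "rs12441817")
        g = ss.derive_grouping(
            rs12441817, _pooled_table(rs12441817, study_counts),
            dom_p=0.68, rec_p=0.04,
        )
        assert g.rule_used == "recessive_by_p"
        assert g.group2 == frozenset({"hom_alt"})
        rs156697 = next(l for l in panel_loci if l.rsid == "rs156697")
        g = ss.derive_grouping(
            rs156697, _pooled_table(rs156697, study_counts),
            dom_p=0.049, rec_p=0.16,
        )
        assert g.rule_used == "dominant_by_p"
        assert g.group1 == frozenset({"hom_ref"})

    def test_missing_model_ps_fail_when_needed(self, panel_loci,
                                               study_counts):
        locus = next(l for l in panel_loci if l.rsid == "rs12441817")
        with pytest.raises(AnalysisError, match="P-values required"):
            ss.derive_grouping(locus, _pooled_table(locus, study_counts))

    def test_presence_locus_fixed_grouping(self, panel_loci):
        locus = next(l for l in panel_loci if l.rsid == "GSTM1")
        g = ss.derive_grouping(locus, GenotypeTable(locus, "all", (500, 500)))
        assert g.rule_used == "presence"
        assert g.token(1) == "P" and g.token(2) == "N"

    def test_footnote_rendering(self, panel_loci, study_counts):
        locus = next(l for l in panel_loci if l.rsid == "rs12441817")
        g = ss.derive_grouping(locus, _pooled_table(locus, study_counts),
                               dom_p=0.68, rec_p=0.04)
        assert g.describe() == "TT + TC and CC"


@pytest.fixture(scope="module")
def scanned_cohort():
    """Deterministic default cohort plus its derived groupings."""
    cohort, _ = ss.simulate_cohort(ss.default_config(seed=21))
    groupings = ss.derive_groupings(cohort)
    return cohort, groupings


class TestCarriers:
    def test_all_wildcard_pattern_carries_everyone(self, scanned_cohort):
        cohort, groupings = scanned_cohort
        loci = tuple(cohort.class_loci("GST"))
        pattern = CombinationPattern(loci, (None,) * 5, "GST")
        counts = ss.combination_carriers(cohort, pattern, groupings)
        assert counts["case"] == (527, 527)
        assert counts["control"] == (499, 499)

    def test_single_locus_pattern_equals_hand_tally(self, tiny_cohort):
        locus = tiny_cohort.locus("rs111")
        g = ss.GenotypeGrouping(locus, frozenset({"hom_ref"}),
                                frozenset({"het", "hom_alt"}),
                                "dominant_by_p")
        pattern = CombinationPattern((locus,), (2,), "CYP")
        counts = ss.combination_carriers(tiny_cohort, pattern,
                                         {"rs111": g})
        # hand tally: case carriers {a2}, controls {a3, a4}; a5 missing
        assert counts["case"] == (1, 2)
        assert counts["control"] == (2, 2)

    def test_complementary_patterns_partition_stratum(self, scanned_cohort):
        cohort, groupings = scanned_cohort
        locus = cohort.locus("rs156697")
        others = tuple(cohort.class_loci("GST"))
        i = others.index(locus)
        slots1 = tuple(1 if j == i else None for j in range(5))
        slots2 = tuple(2 if j == i else None for j in range(5))
        c1 = ss.combination_carriers(
            cohort, CombinationPattern(others, slots1, "GST"), groupings)
        c2 = ss.combination_carriers(
            cohort, CombinationPattern(others, slots2, "GST"), groupings)
        assert c1["case"][0] + c2["case"][0] == 527
        assert c1["control"][0] + c2["control"][0] == 499


class TestScan:
    def test_scan_emits_all_patterns(self, scanned_cohort):
        cohort, groupings = scanned_cohort
        gst = ss.scan_class(cohort, "GST", groupings)
        assert len(gst) == 32
        est = ss.scan_class(cohort, "esterase", groupings)
        assert len(est) == 8

    def test_exact_patterns_partition_subjects(self, scanned_cohort):
        cohort, groupings = scanned_cohort
        est = ss.scan_class(cohort, "esterase", groupings)
        assert sum(r.carriers["case"][0] for r in est) == 527
        assert sum(r.carriers["control"][0] for r in est) == 499

    def test_results_sorted_by_p(self, scanned_cohort):
        cohort, groupings = scanned_cohort
        gst = ss.scan_class(cohort, "GST", groupings)
        ps = [r.p_value for r in gst if r.p_value is not None]
        assert ps == sorted(ps)

    def test_unknown_class_fails(self, scanned_cohort):
        cohort, groupings = scanned_cohort
        with pytest.raises(AnalysisError, match="no loci"):
            ss.scan_class(cohort, "kinase", groupings)

    def test_planted_pattern_ranks_first_in_two_locus_class(self):
        """With a 2-locus class the planted pattern is itself enumerated
        and should top the scan in most replicates."""
        loci = (
            ss.LocusDef(rsid="rsA", gene="A", enzyme_class="CYP",
                        kind="snp", alleles=("T", "C")),
            ss.LocusDef(rsid="rsB", gene="B", enzyme_class="CYP",
                        kind="snp", alleles=("G", "C")),
        )
        eff = PlantedEffect(
            loci=("rsA", "rsB"),
            states=(frozenset({"hom_alt"}), frozenset({"hom_ref", "het"})),
            odds_ratio=0.35,
        )
        cfg = ss.SimConfig(
            n_cases=527, n_controls=499, n_female_cases=257,
            n_female_controls=229, loci=loci,
            effect_freq={"rsA": 0.48, "rsB": 0.82},
            planted_effects=(eff,),
        )
        groupings = {
            "rsA": ss.GenotypeGrouping(
                loci[0], frozenset({"hom_ref", "het"}),
                frozenset({"hom_alt"}), "recessive_by_p"),
            "rsB": ss.GenotypeGrouping(
                loci[1], frozenset({"hom_ref", "het"}),
                frozenset({"hom_alt"}), "recessive_by_p"),
        }
        first = 0
        n_rep = 15
        for seed in range(n_rep):
            cohort, _ = ss.simulate_cohort(replace(cfg, seed=700 + seed))
            scan = ss.scan_class(cohort, "CYP", groupings, m=13)
            if scan[0].pattern.slots == (2, 1):
                first += 1
        assert first / n_rep >= 0.8


class TestBackwardElimination:
    def test_start_with_two_loci_is_terminal(self):
        loci = (
            ss.LocusDef(rsid="rsA", gene="A", enzyme_class="CYP",
                        kind="snp", alleles=("T", "C")),
            ss.LocusDef(rsid="rsB", gene="B", enzyme_class="CYP",
                        kind="snp", alleles=("G", "C")),
        )
        cfg = ss.SimConfig(
            n_cases=200, n_controls=200, n_female_cases=100,
            n_female_controls=100, loci=loci,
            effect_freq={"rsA": 0.4, "rsB": 0.4}, seed=2,
        )
        cohort, _ = ss.simulate_cohort(cfg)
        groupings = ss.derive_groupings(cohort)
        start = CombinationPattern(loci, (1, 1), "CYP")
        path = ss.backward_eliminate(cohort, start, groupings)
        assert len(path.steps) == 1
        assert path.core.pattern is start

    def test_start_must_be_fully_constrained(self, scanned_cohort):
        cohort, groupings = scanned_cohort
        loci = tuple(cohort.class_loci("GST"))
        with pytest.raises(AnalysisError, match="fully constrained"):
            ss.backward_eliminate(
                cohort, CombinationPattern(loci, (1, 1, 1, 1, None), "GST"),
                groupings)

    def test_path_visits_decreasing_constraint_counts(self, scanned_cohort):
        cohort, groupings = scanned_cohort
        scan = ss.scan_class(cohort, "GST", groupings)
        start = next(r.pattern for r in scan if r.p_value is not None)
        path = ss.backward_eliminate(cohort, start, groupings)
        assert [s.pattern.n_constrained for s in path.steps] == [5, 4, 3, 2]

    def test_carrier_counts_non_decreasing_along_path(self, scanned_cohort):
        cohort, groupings = scanned_cohort
        for cls in ("CYP", "esterase", "GST"):
            scan = ss.scan_class(cohort, cls, groupings)
            start = next(r.pattern for r in scan if r.p_value is not None)
            path = ss.backward_eliminate(cohort, start, groupings)
            for grp in ("case", "control"):
                counts = [s.carriers[grp][0] for s in path.steps]
                assert counts == sorted(counts)

    def test_greedy_step_equals_brute_force_minimum(self, scanned_cohort):
        """Each greedy move matches the exhaustive single-wildcard min."""
        cohort, groupings = scanned_cohort
        loci = tuple(cohort.class_loci("esterase"))
        scan = ss.scan_class(cohort, "esterase", groupings)
        start = next(r.pattern for r in scan if r.p_value is not None)
        path = ss.backward_eliminate(cohort, start, groupings)
        for prev, chosen in zip(path.steps, path.steps[1:]):
            candidates = []
            for idx in prev.pattern.constrained_indices():
                cand = prev.pattern.wildcard(idx)
                res = eval_pattern(cohort, cand, groupings)
                candidates.append(res)
            best_p = min(r.p_value for r in candidates
                         if r.p_value is not None)
            assert chosen.p_value == pytest.approx(best_p)

    def test_core_is_minimum_p_on_path(self, scanned_cohort):
        cohort, groupings = scanned_cohort
        scan = ss.scan_class(cohort, "CYP", groupings)
        start = next(r.pattern for r in scan if r.p_value is not None)
        path = ss.backward_eliminate(cohort, start, groupings)
        ps = [s.p_value for s in path.steps if s.p_value is not None]
        assert path.core.p_value == min(ps)


class TestStratified:
    def test_female_specific_effect_detected(self):
        """An effect planted in females should test stronger in females."""
        eff = PlantedEffect(
            loci=("GSTT1", "rs156697"),
            states=(frozenset({"null"}), frozenset({"het", "hom_alt"})),
            odds_ratio=0.3, sex=1,
        )
        stronger = 0
        n_rep = 10
        for seed in range(n_rep):
            cfg = replace(ss.default_config(seed=800 + seed),
                          planted_effects=(eff,))
            cohort, _ = ss.simulate_cohort(cfg)
            loci = tuple(cohort.class_loci("GST"))
            groupings = ss.derive_groupings(cohort)
            slots = tuple(
                {"GSTT1": 2, "rs156697": 2}.get(l.rsid) for l in loci
            )
            pattern = CombinationPattern(loci, slots, "GST")
            f = eval_pattern(cohort, pattern, groupings, adjust=("age",),
                             sex=1)
            m = eval_pattern(cohort, pattern, groupings, adjust=("age",),
                             sex=0)
            if f.p_value is not None and m.p_value is not None \
                    and f.p_value < m.p_value:
                stronger += 1
        assert stronger / n_rep >= 0.9

    def test_zero_carrier_stratum_flagged(self, scanned_cohort):
        cohort, groupings = scanned_cohort
        scan = ss.scan_class(cohort, "GST", groupings)
        start = next(r.pattern for r in scan if r.p_value is not None)
        path = ss.backward_eliminate(cohort, start, groupings)
        strata = ss.stratified_results(cohort, path, groupings)
        for sex in (0, 1):
            assert len(strata[sex]) == len(path.steps)
            for res in strata[sex]:
                if res.carriers["case"][0] == 0 or \
                        res.carriers["control"][0] == 0:
                    assert res.result.separated or res.p_value is None \
                        or res.result.haldane
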