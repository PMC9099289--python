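"""Genotype-combination synergy analysis within enzyme classes.

Each SNP's three genotypes are first dichotomised into two groups: a
homozygote rarer than 5% in the pooled cohort is merged into its
heterozygote (this merge takes precedence), otherwise the dominant or
recessive split with the smaller covariate-adjusted P is adopted;
deletion loci keep their natural present/null split.  Within an enzyme
class, every fully-constrained assignment of loci to groups (2^k
patterns) is tested as a carrier indicator in an age- and sex-adjusted
logistic model.  From the smallest-P pattern, backward elimination
greedily wildcards one locus at a time, keeping the relaxation with the
smallest P, down to two constrained loci; the minimum-P pattern along
the path is the "core" synergistic combination.  Path patterns can be
re-tested within each sex (age-adjusted only).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, LocusDef
from . import stats
from .locus import (
    AssociationResult,
    GenotypeTable,
    _result_from_fit,
    genotype_counts,
    run_model,
)
from .stats import AnalysisError, fit_logistic

WILDCARD_TOKEN = "-"
RARE_HOM_THRESHOLD = 0.05


@dataclass(frozen=True)
class GenotypeGrouping:
    """Two-group dichotomisation of one locus's genotype states."""

    locus: LocusDef
    group1: frozenset[str]
    group2: frozenset[str]
    rule_used: str  # rare_hom_merge | dominant_by_p | recessive_by_p | presence

    def __post_init__(self) -> None:
        states = set(self.locus.states)
        if (self.group1 | self.group2) != states or (self.group1 & self.group2):
            raise AnalysisError(
                f"{self.locus.rsid}: groups must partition {sorted(states)}"
            )
        if not self.group1 or not self.group2:
            raise AnalysisError(f"{self.locus.rsid}: empty genotype group")

    def group_states(self, slot: int) -> frozenset[str]:
        return self.group1 if slot == 1 else self.group2

    def token(self, slot: int) -> str:
        """Display token for a slot: 1/2 for SNPs, P/N for deletions."""
        if self.locus.kind == "presence":
            return "P" if slot == 1 else "N"
        return str(slot)

    def describe(self) -> str:
        """Footnote-style description, e.g. ``TT + TC and CC``."""
        def render(states: frozenset[str]) -> str:
            order = [s for s in self.locus.states if s in states]
            return " + ".join(self.locus.state_token(s) for s in order)

        return f"{render(self.group1)} and {render(self.group2)}"


def derive_grouping(locus: LocusDef, pooled_counts: GenotypeTable,
                    dom_p: float | None = None, rec_p: float | None = None,
                    rare_threshold: float = RARE_HOM_THRESHOLD) -> GenotypeGrouping:
    """Dichotomise one locus per the merge-then-smaller-P rule.

    The rare-homozygote merge (pooled hom_alt frequency below
    ``rare_threshold``) takes precedence over model choice; otherwise
    the dominant or recessive split with the smaller P wins, dominant
    on ties.
    """
    if locus.kind == "presence":
        return GenotypeGrouping(
            locus=locus, group1=frozenset({"present"}),
            group2=frozenset({"null"}), rule_used="presence",
        )
    n = pooled_counts.n_total
    hom_alt_freq = pooled_counts.counts[2] / n if n else 0.0
    if hom_alt_freq < rare_threshold:
        return GenotypeGrouping(
            locus=locus, group1=frozenset({"hom_ref"}),
            group2=frozenset({"het", "hom_alt"}), rule_used="rare_hom_merge",
        )
    if dom_p is None or rec_p is None:
        raise AnalysisError(
            f"{locus.rsid}: dominant/recessive P-values required when the "
            "homozygote is not rare"
        )
    if dom_p <= rec_p:
        return GenotypeGrouping(
            locus=locus, group1=frozenset({"hom_ref"}),
            group2=frozenset({"het", "hom_alt"}), rule_used="dominant_by_p",
        )
    return GenotypeGrouping(
        locus=locus, group1=frozenset({"hom_ref", "het"}),
        group2=frozenset({"hom_alt"}), rule_used="recessive_by_p",
    )


def derive_groupings(cohort: Cohort, adjust: tuple[str, ...] = ("age", "sex"),
                     rare_threshold: float = RARE_HOM_THRESHOLD,
                     pool: str = "all") -> dict[str, GenotypeGrouping]:
    """Dichotomise every cohort locus, fitting model Ps where needed.

    ``pool`` selects the stratum whose genotype frequencies decide the
    rare-homozygote merge (default: cases and controls pooled).
    """
    groupings = {}
    for locus in cohort.loci:
        pooled = genotype_counts(cohort, locus, pool)
        dom_p = rec_p = None
        if locus.kind == "snp" and not (
            pooled.n_total and pooled.counts[2] / pooled.n_total < rare_threshold
        ):
            dom_p = run_model(cohort, locus, "dominant", adjust).p_value
            rec_p = run_model(cohort, locus, "recessive", adjust).p_value
        groupings[locus.rsid] = derive_grouping(
            locus, pooled, dom_p, rec_p, rare_threshold
        )
    return groupings


@dataclass(frozen=True)
class CombinationPattern:
    """Per-locus group assignment with wildcards, within one class.

    ``slots`` holds 1 (group1), 2 (group2) or ``None`` (wildcard) per
    locus, in class locus order.
    """

    loci: tuple[LocusDef, ...]
    slots: tuple[int | None, ...]
    enzyme_class: str

    def __post_init__(self) -> None:
        if len(self.loci) != len(self.slots):
            raise AnalysisError("pattern slots/loci length mismatch")
        if all(s is None for s in self.slots):
            pass  # all-wildcard allowed: vacuous pattern carries everyone
        for s in self.slots:
            if s not in (1, 2, None):
                raise AnalysisError(f"bad slot value {s!r}")
        classes = {l.enzyme_class for l in self.loci}
        if len(classes) > 1:
            raise AnalysisError("pattern mixes enzyme classes")

    @property
    def n_constrained(self) -> int:
        return sum(1 for s in self.slots if s is not None)

    def constrained_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.slots) if s is not None]

    def wildcard(self, index: int) -> "CombinationPattern":
        if self.slots[index] is None:
            raise AnalysisError(f"slot {index} already wildcarded")
        slots = list(self.slots)
        slots[index] = None
        return CombinationPattern(self.loci, tuple(slots), self.enzyme_class)

    def label(self, groupings: dict[str, "GenotypeGrouping"]) -> str:
        toks = []
        for locus, slot in zip(self.loci, self.slots):
            if slot is None:
                toks.append(WILDCARD_TOKEN)
            else:
                toks.append(groupings[locus.rsid].token(slot))
        return "/".join(toks)


def pattern_from_string(slots: str, loci, enzyme_class: str) -> CombinationPattern:
    """Parse a slot string like ``2/-/-/-/1`` or ``P/N/-/2/1``."""
    parts = slots.split("/")
    loci = tuple(loci)
    if len(parts) != len(loci):
        raise AnalysisError(
            f"pattern {slots!r} has {len(parts)} slots for {len(loci)} loci"
        )
    decoded: list[int | None] = []
    for tok, locus in zip(parts, loci):
        tok = tok.strip()
        if tok in (WILDCARD_TOKEN, "−"):  # ASCII hyphen or minus sign
            decoded.append(None)
        elif locus.kind == "presence":
            decoded.append({"P": 1, "N": 2}[tok])
        else:
            decoded.append(int(tok))
    return CombinationPattern(loci, tuple(decoded), enzyme_class)


@dataclass
class CombinationResult:
    """Carrier association of one pattern, with per-group counts."""

    pattern: CombinationPattern
    label: str
    result: AssociationResult
    carriers: dict[str, tuple[int, int]]  # group -> (n_carriers, n_evaluated)
    threshold: float
    sex: int | None = None

    @property
    def p_value(self) -> float | None:
        return self.result.p_value

    @property
    def significant(self) -> bool:
        return self.p_value is not None and self.p_value < self.threshold

    def frequency(self, group: str) -> float:
        k, n = self.carriers[group]
        return k / n if n else float("nan")


def _carrier_flags(cohort: Cohort, pattern: CombinationPattern,
                   groupings: dict[str, GenotypeGrouping],
                   sex: int | None = None):
    """(subject, is_carrier) over complete cases at constrained loci."""
    required = [
        (locus, groupings[locus.rsid].group_states(slot))
        for locus, slot in zip(pattern.loci, pattern.slots)
        if slot is not None
    ]
    for locus, _ in required:
        if locus.rsid not in groupings:
            raise AnalysisError(f"no grouping for pattern locus {locus.rsid}")
    out = []
    for s in cohort.subjects:
        if sex is not None and s.sex != sex:
            continue
        calls = [s.genotypes.get(locus.rsid) for locus, _ in required]
        if any(c is None for c in calls):
            continue  # missing a required genotype: excluded
        carrier = all(
            c in states for c, (_, states) in zip(calls, required)
        )
        out.append((s, carrier))
    return out


def combination_carriers(cohort: Cohort, pattern: CombinationPattern,
                         groupings: dict[str, GenotypeGrouping],
                         sex: int | None = None) -> dict[str, tuple[int, int]]:
    """Per-group (carriers, evaluated) counts for a pattern.

    A subject carries the pattern when its genotype lies in the named
    group at every non-wildcard locus; subjects missing any required
    genotype are excluded from both numerator and denominator.
    """
    flags = _carrier_flags(cohort, pattern, groupings, sex)
    counts = {}
    for grp, status in (("case", 1), ("control", 0)):
        rows = [c for s, c in flags if s.status == status]
        counts[grp] = (sum(rows), len(rows))
    return counts


def test_pattern(cohort: Cohort, pattern: CombinationPattern,
                 groupings: dict[str, GenotypeGrouping],
                 adjust: tuple[str, ...] = ("age", "sex"),
                 sex: int | None = None,
                 threshold: float = 0.05) -> CombinationResult:
    """Age/sex-adjusted logistic association of carrying a pattern."""
    flags = _carrier_flags(cohort, pattern, groupings, sex)
    label = pattern.label(groupings)
    carriers = {}
    for grp, status in (("case", 1), ("control", 0)):
        rows = [c for s, c in flags if s.status == status]
        carriers[grp] = (sum(rows), len(rows))
    rows = []
    ys = []
    for s, carrier in flags:
        row = [1.0, 1.0 if carrier else 0.0]
        for cov in adjust:
            row.append(s.age if cov == "age" else float(s.sex))
        rows.append(row)
        ys.append(float(s.status))
    if not rows:
        raise AnalysisError(f"pattern {label}: no evaluable subjects")
    X = pd.DataFrame(rows, columns=["const", "exposure", *adjust])
    fit = fit_logistic(np.asarray(ys), X)
    res = _result_from_fit(label, "carrier", fit, "exposure", adjust,
                           {g: c for g, c in carriers.items()})
    return CombinationResult(
        pattern=pattern, label=label, result=res, carriers=carriers,
        threshold=threshold, sex=sex,
    )


def scan_class(cohort: Cohort, enzyme_class: str,
               groupings: dict[str, GenotypeGrouping] | None = None,
               alpha: float = 0.05, m: int | None = None,
               adjust: tuple[str, ...] = ("age", "sex")) -> list[CombinationResult]:
    """Test all 2^k fully-constrained patterns of one enzyme class.

    ``m`` sets the Bonferroni family size (default: the number of loci
    in the cohort, mirroring the reuse of the locus-level threshold);
    results come back sorted by P, untestable (separated) fits last.
    """
    loci = tuple(cohort.class_loci(enzyme_class))
    if not loci:
        raise AnalysisError(f"no loci in class {enzyme_class!r}")
    if groupings is None:
        groupings = derive_groupings(cohort, adjust)
    if m is None:
        m = len(cohort.loci)
    threshold = stats.bonferroni(alpha, m)
    results = []
    for combo in itertools.product((1, 2), repeat=len(loci)):
        pattern = CombinationPattern(loci, combo, enzyme_class)
        results.append(
            test_pattern(cohort, pattern, groupings, adjust,
                         threshold=threshold)
        )
    results.sort(key=lambda r: (r.p_value is None,
                                r.p_value if r.p_value is not None else 0.0))
    return results


@dataclass
class EliminationPath:
    """Patterns visited by backward elimination, most constrained first."""

    steps: list[CombinationResult]

    @property
    def core(self) -> CombinationResult:
        """Minimum-P visited pattern; ties favour fewer constrained loci."""
        def key(r: CombinationResult):
            p = r.p_value if r.p_value is not None else float("inf")
            return (p, r.pattern.n_constrained)

        return min(self.steps, key=key)


def backward_eliminate(cohort: Cohort, start: CombinationPattern,
                       groupings: dict[str, GenotypeGrouping],
                       adjust: tuple[str, ...] = ("age", "sex"),
                       alpha: float = 0.05, m: int | None = None,
                       stop_at: int = 2) -> EliminationPath:
    """Greedy relaxation from a fully-constrained pattern.

    At each step every single-wildcard successor is tested and the one
    with the smallest P is kept (ties: larger absolute log-OR, then
    lower locus index); the walk stops once ``stop_at`` constrained
    loci remain.
    """
    if start.n_constrained != len(start.loci):
        raise AnalysisError("backward elimination must start fully constrained")
    if m is None:
        m = len(cohort.loci)
    threshold = stats.bonferroni(alpha, m)
    current = start
    steps = [test_pattern(cohort, current, groupings, adjust,
                          threshold=threshold)]
    while current.n_constrained > stop_at:
        candidates = []
        for idx in current.constrained_indices():
            cand = current.wildcard(idx)
            res = test_pattern(cohort, cand, groupings, adjust,
                               threshold=threshold)
            candidates.append((idx, res))

        def key(item):
            idx, res = item
            p = res.p_value if res.p_value is not None else float("inf")
            log_or = res.result.log_or
            mag = abs(log_or) if log_or is not None else -float("inf")
            return (p, -mag, idx)

        _, best = min(candidates, key=key)
        steps.append(best)
        current = best.pattern
    return EliminationPath(steps=steps)


def stratified_results(cohort: Cohort, path: EliminationPath,
                       groupings: dict[str, GenotypeGrouping],
                       adjust: tuple[str, ...] = ("age",),
                       ) -> dict[int, list[CombinationResult]]:
    """Re-test every path pattern within each sex (age-adjusted).

    Sex is constant within a stratum, so the default covariate set is
    age only.  Strata where the fit degenerates (e.g. zero carriers)
    come back with the separation flag set rather than failing.
    """
    out: dict[int, list[CombinationResult]] = {0: [], 1: []}
    for sex in (0, 1):
        for step in path.steps:
            try:
                res = test_pattern(cohort, step.pattern, groupings, adjust,
                                   sex=sex, threshold=step.threshold)
            except AnalysisError:
                res = CombinationResult(
                    pattern=step.pattern, label=step.label,
                    result=AssociationResult(
                        label=step.label, model="carrier", odds_ratio=None,
                        ci_low=None, ci_high=None, p_value=None,
                        log_or=None, se_log_or=None, adjusted=bool(adjust),
                        separated=True,
                    ),
                    carriers={"case": (0, 0), "control": (0, 0)},
                    threshold=step.threshold, sex=sex,
                )
            out[sex].append(res)
    return out
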