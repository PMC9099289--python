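"""Single-locus pipeline: frequency tables, HWE screening, genetic models.

Covers the classic candidate-gene workflow: per-stratum genotype and
allele counts, a control-group Hardy-Weinberg screen that drops failing
loci from all downstream analyses, covariate-adjusted logistic fits
under genotypic / allelic / dominant / recessive / log-additive
codings, Bonferroni bookkeeping, and a demographic summary of the two
groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, LocusDef
from . import stats
from .stats import (
    AnalysisError,
    HWEResult,
    RegressionFit,
    fit_logistic,
    likelihood_ratio_test,
    or_2x2,
)

GENETIC_MODELS = ("genotypic", "allelic", "dominant", "recessive", "additive")
#: the only valid coding for presence/null (gene-deletion) loci
PRESENCE_MODEL = "binary"


@dataclass(frozen=True)
class GenotypeTable:
    """Genotype counts for one locus in one stratum."""

    locus: LocusDef
    stratum: str
    counts: tuple[int, ...]  # (hom_ref, het, hom_alt) or (present, null)

    @property
    def n_total(self) -> int:
        return sum(self.counts)

    @property
    def frequencies(self) -> tuple[float, ...]:
        n = self.n_total
        return tuple(c / n if n else float("nan") for c in self.counts)


@dataclass(frozen=True)
class AlleleTable:
    """Allele counts derived from a SNP genotype table."""

    locus: LocusDef
    stratum: str
    counts: tuple[int, int]  # (allele1, allele2)

    @property
    def n_total(self) -> int:
        return sum(self.counts)

    @property
    def frequencies(self) -> tuple[float, float]:
        n = self.n_total
        return tuple(c / n if n else float("nan") for c in self.counts)


@dataclass
class AssociationResult:
    """Effect estimate for one exposure coding of one locus or pattern."""

    label: str
    model: str
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    log_or: float | None
    se_log_or: float | None
    adjusted: bool
    separated: bool = False
    haldane: bool = False
    n_used: int = 0
    counts: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "label": self.label, "model": self.model,
            "odds_ratio": self.odds_ratio, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "p_value": self.p_value,
            "adjusted": self.adjusted, "separated": self.separated,
            "haldane": self.haldane, "n_used": self.n_used,
            "counts": self.counts,
        }


def _select(cohort: Cohort, stratum: str, sex: int | None = None):
    if stratum not in ("all", "case", "control"):
        raise AnalysisError(f"unknown stratum {stratum!r}")
    subs = cohort.subjects
    if stratum == "case":
        subs = [s for s in subs if s.status == 1]
    elif stratum == "control":
        subs = [s for s in subs if s.status == 0]
    if sex is not None:
        subs = [s for s in subs if s.sex == sex]
    return subs


def genotype_counts(cohort: Cohort, locus: LocusDef, stratum: str = "all",
                    sex: int | None = None) -> GenotypeTable:
    """Complete-case genotype counts in the selected stratum."""
    subs = _select(cohort, stratum, sex)
    states = locus.states
    calls = [s.genotypes.get(locus.rsid) for s in subs]
    counts = tuple(sum(1 for c in calls if c == st) for st in states)
    return GenotypeTable(locus=locus, stratum=stratum, counts=counts)


def allele_counts(table: GenotypeTable) -> AlleleTable:
    """Allele counts: allele1 = 2*hom_ref + het, allele2 = 2*hom_alt + het."""
    if table.locus.kind != "snp":
        raise AnalysisError(
            f"{table.locus.rsid}: allele counts undefined for presence loci"
        )
    n_rr, n_ra, n_aa = table.counts
    return AlleleTable(
        locus=table.locus, stratum=table.stratum,
        counts=(2 * n_rr + n_ra, 2 * n_aa + n_ra),
    )


@dataclass
class HweScreenRecord:
    locus: LocusDef
    result: HWEResult | None  # None for untestable (presence) loci
    testable: bool
    keep: bool


def hwe_screen(cohort: Cohort, alpha: float = 0.05) -> list[HweScreenRecord]:
    """Control-group HWE screen; loci with P < alpha are dropped.

    Presence/null loci cannot be tested in this coding and are kept,
    flagged untestable.
    """
    records = []
    for locus in cohort.loci:
        if locus.kind != "snp":
            records.append(HweScreenRecord(locus, None, False, True))
            continue
        table = genotype_counts(cohort, locus, "control")
        res = stats.hwe_chi2(table.counts)
        records.append(
            HweScreenRecord(locus, res, True, res.p_value >= alpha)
        )
    return records


def _design(cohort: Cohort, locus: LocusDef, code_fn, adjust):
    """Complete-case response and design for one exposure coding.

    ``code_fn`` maps a genotype state to a scalar or a tuple of
    exposure columns.
    """
    rows, ys = [], []
    for s in cohort.subjects:
        state = s.genotypes.get(locus.rsid)
        if state is None:
            continue
        exp = code_fn(state)
        if not isinstance(exp, tuple):
            exp = (exp,)
        row = [1.0, *exp]
        for cov in adjust:
            row.append(s.age if cov == "age" else float(s.sex))
        rows.append(row)
        ys.append(float(s.status))
    if not rows:
        raise AnalysisError(f"{locus.rsid}: no complete cases to analyse")
    n_exp = len(rows[0]) - 1 - len(adjust)
    cols = ["const"] + [f"exposure{i}" if n_exp > 1 else "exposure"
                        for i in range(n_exp)] + list(adjust)
    X = pd.DataFrame(rows, columns=cols)
    return np.asarray(ys), X


def _result_from_fit(label: str, model: str, fit: RegressionFit,
                     term: str, adjust, counts: dict) -> AssociationResult:
    if fit.separated:
        return AssociationResult(
            label=label, model=model, odds_ratio=None, ci_low=None,
            ci_high=None, p_value=None, log_or=None, se_log_or=None,
            adjusted=bool(adjust), separated=True, n_used=fit.nobs,
            counts=counts,
        )
    ci = fit.conf_int(term)
    return AssociationResult(
        label=label, model=model,
        odds_ratio=fit.odds_ratio(term),
        ci_low=ci[0], ci_high=ci[1],
        p_value=fit.p_value(term),
        log_or=float(fit.params[term]), se_log_or=float(fit.bse[term]),
        adjusted=bool(adjust), n_used=fit.nobs, counts=counts,
    )


_CODINGS = {
    "dominant": lambda st: 0.0 if st == "hom_ref" else 1.0,
    "recessive": lambda st: 1.0 if st == "hom_alt" else 0.0,
    "additive": lambda st: {"hom_ref": 0.0, "het": 1.0, "hom_alt": 2.0}[st],
    PRESENCE_MODEL: lambda st: 1.0 if st == "null" else 0.0,
}


def run_model(cohort: Cohort, locus: LocusDef, model: str,
              adjust: tuple[str, ...] = ("age", "sex")) -> AssociationResult:
    """Association of one locus with case status under one genetic model.

    SNP models: ``dominant`` (hom_ref vs het+hom_alt), ``recessive``
    (hom_ref+het vs hom_alt), ``additive`` (log-additive effect-allele
    dose), ``genotypic`` (two genotype indicators, 2-df likelihood-ratio
    P), ``allelic`` (unadjusted allele-count 2x2 OR; the adjusted
    log-additive result rides along in ``extra`` since alleles are not
    independent subjects).  Presence loci take only the ``binary``
    null-vs-present coding.
    """
    counts = {
        grp: genotype_counts(cohort, locus, grp).counts
        for grp in ("case", "control")
    }
    if locus.kind == "presence":
        if model not in (PRESENCE_MODEL, "dominant"):
            raise AnalysisError(
                f"{locus.rsid}: presence loci support only the "
                f"{PRESENCE_MODEL!r} coding"
            )
        model = PRESENCE_MODEL
    elif model not in GENETIC_MODELS:
        raise AnalysisError(f"unknown genetic model {model!r}")

    if model == "allelic":
        case_t = allele_counts(genotype_counts(cohort, locus, "case"))
        ctrl_t = allele_counts(genotype_counts(cohort, locus, "control"))
        raw = or_2x2(case_t.counts[1], case_t.counts[0],
                     ctrl_t.counts[1], ctrl_t.counts[0])
        res = AssociationResult(
            label=locus.rsid, model="allelic",
            odds_ratio=raw.odds_ratio, ci_low=raw.ci_low,
            ci_high=raw.ci_high, p_value=raw.p_value,
            log_or=raw.log_or, se_log_or=raw.se_log_or,
            adjusted=False, haldane=raw.haldane,
            n_used=(case_t.n_total + ctrl_t.n_total) // 2, counts=counts,
        )
        if adjust:
            res.extra["adjusted_additive"] = run_model(
                cohort, locus, "additive", adjust
            ).as_dict()
        return res

    if model == "genotypic":
        y, X = _design(
            cohort, locus,
            lambda st: (1.0 if st == "het" else 0.0,
                        1.0 if st == "hom_alt" else 0.0),
            adjust,
        )
        full = fit_logistic(y, X)
        reduced = fit_logistic(y, X.drop(columns=["exposure0", "exposure1"]))
        if full.separated or reduced.separated:
            return _result_from_fit(locus.rsid, model, full, "exposure0",
                                    adjust, counts)
        p = likelihood_ratio_test(full, reduced, df=2)
        res = _result_from_fit(locus.rsid, model, full, "exposure1",
                               adjust, counts)
        res.p_value = p
        res.extra["lrt_df"] = 2
        res.extra["or_het"] = full.odds_ratio("exposure0")
        res.extra["or_hom_alt"] = full.odds_ratio("exposure1")
        return res

    y, X = _design(cohort, locus, _CODINGS[model], adjust)
    fit = fit_logistic(y, X)
    return _result_from_fit(locus.rsid, model, fit, "exposure", adjust, counts)


@dataclass
class LocusReport:
    """Everything reported for one locus: tables, HWE, model results."""

    locus: LocusDef
    genotype_tables: dict[str, GenotypeTable]
    allele_tables: dict[str, AlleleTable] | None
    hwe_controls: HWEResult | None
    results: dict[str, AssociationResult]
    bonferroni_m: int
    threshold: float

    def significant(self, model: str) -> bool:
        res = self.results.get(model)
        return bool(res and res.p_value is not None
                    and res.p_value < self.threshold)


def locus_table(cohort: Cohort, models=GENETIC_MODELS, alpha: float = 0.05,
                adjust: tuple[str, ...] = ("age", "sex"),
                screen_alpha: float = 0.05) -> list[LocusReport]:
    """Per-locus reports over the HWE-kept loci.

    The Bonferroni family size m is the number of kept loci; model
    codings that need three genotype classes are applied to SNP loci
    only (presence loci get the binary coding).
    """
    kept = [r.locus for r in hwe_screen(cohort, screen_alpha) if r.keep]
    m = len(kept)
    threshold = stats.bonferroni(alpha, m) if m else alpha
    reports = []
    for locus in kept:
        gtabs = {grp: genotype_counts(cohort, locus, grp)
                 for grp in ("case", "control")}
        if locus.kind == "snp":
            atabs = {grp: allele_counts(t) for grp, t in gtabs.items()}
            hwe = stats.hwe_chi2(gtabs["control"].counts)
            wanted = models
        else:
            atabs = None
            hwe = None
            wanted = (PRESENCE_MODEL,)
        results = {mname: run_model(cohort, locus, mname, adjust)
                   for mname in wanted}
        reports.append(LocusReport(
            locus=locus, genotype_tables=gtabs, allele_tables=atabs,
            hwe_controls=hwe, results=results, bonferroni_m=m,
            threshold=threshold,
        ))
    return reports


@dataclass
class CohortSummary:
    n_cases: int
    n_controls: int
    sex_counts: dict[str, tuple[int, int]]  # group -> (male, female)
    age_median: dict[str, float]
    age_iqr: dict[str, tuple[float, float]]
    sex_p: float | None
    age_p: float | None
    age_normality_p: dict[str, float]


def cohort_summary(cohort: Cohort) -> CohortSummary:
    """Demographics: group sizes, sex chi-square, age Mann-Whitney.

    The age comparison is rank-based (after a Kolmogorov-Smirnov check
    against a fitted normal, reported per group) and the sex comparison
    is a 2x2 Pearson chi-square.
    """
    groups = {
        "case": [s for s in cohort.subjects if s.status == 1],
        "control": [s for s in cohort.subjects if s.status == 0],
    }
    sex_counts, age_median, age_iqr, norm_p = {}, {}, {}, {}
    for grp, subs in groups.items():
        males = sum(1 for s in subs if s.sex == 0)
        sex_counts[grp] = (males, len(subs) - males)
        ages = np.array([s.age for s in subs])
        if len(ages):
            age_median[grp] = float(np.median(ages))
            age_iqr[grp] = (float(np.percentile(ages, 25)),
                            float(np.percentile(ages, 75)))
        if len(ages) >= 2 and np.std(ages) > 0:
            norm_p[grp] = stats.ks_normality(ages)[1]
    sex_p = age_p = None
    if all(len(v) >= 2 for v in groups.values()):
        table = [sex_counts["case"], sex_counts["control"]]
        try:
            sex_p = stats.chi2_independence(table)[2]
        except AnalysisError:
            sex_p = None
        age_p = stats.mann_whitney(
            [s.age for s in groups["case"]],
            [s.age for s in groups["control"]],
        )[1]
    return CohortSummary(
        n_cases=len(groups["case"]), n_controls=len(groups["control"]),
        sex_counts=sex_counts, age_median=age_median, age_iqr=age_iqr,
        sex_p=sex_p, age_p=age_p, age_normality_p=norm_p,
    )
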