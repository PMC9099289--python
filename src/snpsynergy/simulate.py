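"""Synthetic case-control cohort generator.

Emulates the statistical structure the downstream analyses assume: each
base-population subject gets genotypes drawn independently per locus
under Hardy-Weinberg proportions, an age from a truncated normal and a
sex label, and a case probability from a logistic model over age, sex
and any planted multi-locus carrier effects.  The logistic intercept is
calibrated by bisection so the expected case fraction matches the
requested design, and subjects are then quota-sampled until the exact
per-group, per-sex counts are reached.  Everything is driven by a
single seeded NumPy generator, so a seed pins the emitted cohort file
byte for byte.

The default configuration mirrors the reference candidate-gene study:
527 cases (257 female) vs 499 controls (229 female), 13 xenobiotic-
metabolism loci with control-population allele/null frequencies taken
from the packaged published counts, and an age effect that leaves cases
roughly eight years older than controls (group medians near 66 and 58).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.special import expit

from .cohort import Cohort, LocusDef, Subject, packaged_loci, packaged_study_counts

# genotype state codes used internally by the simulator
_SNP_CODE = {"hom_ref": 0, "het": 1, "hom_alt": 2}
_PRES_CODE = {"present": 0, "null": 1}


class SimulationError(ValueError):
    """Raised when a configuration cannot produce the requested cohort."""


@dataclass(frozen=True)
class PlantedEffect:
    """A multi-locus carrier effect injected into the disease model.

    A subject is a carrier when, at every listed locus, its genotype
    state is in the corresponding state set.  ``odds_ratio`` multiplies
    the subject's disease odds; ``sex`` restricts the effect to one sex
    (0 male, 1 female) when given.
    """

    loci: tuple[str, ...]
    states: tuple[frozenset[str], ...]
    odds_ratio: float
    sex: int | None = None

    def __post_init__(self) -> None:
        if len(self.loci) != len(self.states) or not self.loci:
            raise SimulationError("planted effect needs one state set per locus")
        if not self.odds_ratio > 0:
            raise SimulationError("planted odds ratio must be positive")
        object.__setattr__(
            self, "states", tuple(frozenset(s) for s in self.states)
        )


@dataclass(frozen=True)
class SimConfig:
    """Design of a synthetic cohort.

    ``effect_freq`` maps each rsid to its base-population second-allele
    frequency (SNP loci) or homozygous-null frequency (presence loci).
    Ages are drawn from a normal truncated to ``age_bounds``; the
    per-year log-odds ``beta_age`` makes cases older than controls.
    """

    n_cases: int
    n_controls: int
    n_female_cases: int
    n_female_controls: int
    loci: tuple[LocusDef, ...]
    effect_freq: dict[str, float]
    age_center: float = 62.0
    age_spread: float = 12.0
    age_bounds: tuple[float, float] = (30.0, 95.0)
    beta_age: float = 0.05  # log-OR per year of age
    beta_female: float = 0.0  # log-OR for female sex
    planted_effects: tuple[PlantedEffect, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cases, self.n_controls) <= 0:
            raise SimulationError("group sizes must be positive")
        if not (0 <= self.n_female_cases <= self.n_cases):
            raise SimulationError("female case count out of range")
        if not (0 <= self.n_female_controls <= self.n_controls):
            raise SimulationError("female control count out of range")
        for loc in self.loci:
            f = self.effect_freq.get(loc.rsid)
            if f is None:
                raise SimulationError(f"no frequency for locus {loc.rsid}")
            if not 0.0 <= f <= 1.0:
                raise SimulationError(f"{loc.rsid}: frequency {f} not in [0,1]")
        known = {l.rsid for l in self.loci}
        for eff in self.planted_effects:
            missing = set(eff.loci) - known
            if missing:
                raise SimulationError(
                    f"planted effect references unknown loci {sorted(missing)}"
                )

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class SimReport:
    """Realised frequencies and carrier counts of an emitted cohort."""

    seed: int
    intercept: float
    genotype_counts: dict[str, dict[str, tuple[int, ...]]]
    allele2_freq: dict[str, dict[str, float]]
    planted_carriers: list[dict[str, int]]

    def as_dict(self) -> dict:
        return {
            "seed": self.seed,
            "intercept": self.intercept,
            "genotype_counts": {
                rsid: {grp: list(cts) for grp, cts in by_grp.items()}
                for rsid, by_grp in self.genotype_counts.items()
            },
            "allele2_freq": self.allele2_freq,
            "planted_carriers": self.planted_carriers,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.as_dict(), indent=2) + "\n", encoding="utf-8"
        )


def default_config(seed: int = 0) -> SimConfig:
    """The packaged 13-locus design with published control frequencies."""
    loci = tuple(packaged_loci())
    counts = packaged_study_counts()["genotype_counts"]
    freq = {}
    for loc in loci:
        ctrl = counts[loc.rsid]["control"]
        if loc.kind == "snp":
            n_rr, n_ra, n_aa = ctrl
            freq[loc.rsid] = (2 * n_aa + n_ra) / (2 * sum(ctrl))
        else:
            freq[loc.rsid] = ctrl[1] / sum(ctrl)
    return SimConfig(
        n_cases=527, n_controls=499,
        n_female_cases=257, n_female_controls=229,
        loci=loci, effect_freq=freq, seed=seed,
    )


# ---------------------------------------------------------------------------


def _draw_batch(config: SimConfig, rng: np.random.Generator, size: int):
    """Draw ages, sexes and genotype codes for ``size`` base subjects."""
    lo, hi = config.age_bounds
    ages = np.empty(size)
    filled = 0
    while filled < size:  # truncated normal by rejection
        draw = rng.normal(config.age_center, config.age_spread, size=size)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(keep), size - filled)
        ages[filled:filled + take] = keep[:take]
        filled += take
    n_female = config.n_female_cases + config.n_female_controls
    sexes = (rng.random(size) < n_female / config.n_total).astype(np.int8)
    genos = np.empty((size, len(config.loci)), dtype=np.int8)
    for j, loc in enumerate(config.loci):
        f = config.effect_freq[loc.rsid]
        if loc.kind == "snp":
            # HWE: genotype code = number of effect alleles
            genos[:, j] = rng.binomial(2, f, size=size).astype(np.int8)
        else:
            genos[:, j] = (rng.random(size) < f).astype(np.int8)
    return ages, sexes, genos


def _carrier_matrix(config: SimConfig, sexes, genos) -> np.ndarray:
    """Boolean matrix (n x n_effects): planted-effect carrier status."""
    idx = {l.rsid: j for j, l in enumerate(config.loci)}
    out = np.ones((len(sexes), len(config.planted_effects)), dtype=bool)
    for k, eff in enumerate(config.planted_effects):
        mask = np.ones(len(sexes), dtype=bool)
        for rsid, states in zip(eff.loci, eff.states):
            loc = next(l for l in config.loci if l.rsid == rsid)
            codes = _SNP_CODE if loc.kind == "snp" else _PRES_CODE
            allowed = np.array(sorted(codes[s] for s in states))
            mask &= np.isin(genos[:, idx[rsid]], allowed)
        if eff.sex is not None:
            mask &= sexes == eff.sex
        out[:, k] = mask
    return out


def _linear_predictor(config: SimConfig, ages, sexes, genos) -> np.ndarray:
    eta = config.beta_age * ages + config.beta_female * sexes
    if config.planted_effects:
        carriers = _carrier_matrix(config, sexes, genos)
        log_ors = np.log([e.odds_ratio for e in config.planted_effects])
        eta = eta + carriers @ log_ors
    return eta


def calibrate_intercept(config: SimConfig, rng: np.random.Generator,
                        mc_size: int = 20000) -> float:
    """Bisection for the logistic intercept giving the design case fraction."""
    target = config.n_cases / config.n_total
    ages, sexes, genos = _draw_batch(config, rng, mc_size)
    eta = _linear_predictor(config, ages, sexes, genos)
    lo, hi = -40.0, 40.0
    if not expit(lo + eta).mean() < target < expit(hi + eta).mean():
        raise SimulationError(
            "intercept calibration failed: case fraction "
            f"{target:.3f} unreachable under the configured effects"
        )
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expit(mid + eta).mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(config: SimConfig) -> tuple[Cohort, SimReport]:
    """Generate a cohort with exact group and sex counts.

    Deterministic for a given ``config.seed``; see module docstring for
    the sampling scheme.
    """
    rng = np.random.default_rng(config.seed)
    b0 = calibrate_intercept(config, rng)

    quotas = {
        (1, 1): config.n_female_cases,
        (1, 0): config.n_cases - config.n_female_cases,
        (0, 1): config.n_female_controls,
        (0, 0): config.n_controls - config.n_female_controls,
    }
    kept_status: list[int] = []
    kept_sex: list[int] = []
    kept_age: list[float] = []
    kept_geno: list[np.ndarray] = []
    batch = 4096
    guard = 0
    while any(v > 0 for v in quotas.values()):
        guard += 1
        if guard > 2000:  # ~8M draws; statistically unreachable
            raise SimulationError("quota sampling failed to converge")
        ages, sexes, genos = _draw_batch(config, rng, batch)
        p_case = expit(b0 + _linear_predictor(config, ages, sexes, genos))
        statuses = (rng.random(batch) < p_case).astype(np.int8)
        for i in range(batch):
            key = (int(statuses[i]), int(sexes[i]))
            if quotas[key] > 0:
                quotas[key] -= 1
                kept_status.append(key[0])
                kept_sex.append(key[1])
                kept_age.append(float(np.round(ages[i], 1)))
                kept_geno.append(genos[i].copy())
            if all(v == 0 for v in quotas.values()):
                break

    n = len(kept_status)
    width = len(str(n))
    subjects = []
    for i in range(n):
        genotypes = {}
        for j, loc in enumerate(config.loci):
            code = int(kept_geno[i][j])
            if loc.kind == "snp":
                state = ("hom_ref", "het", "hom_alt")[code]
            else:
                state = ("present", "null")[code]
            genotypes[loc.rsid] = state
        subjects.append(Subject(
            id=f"S{i + 1:0{width}d}", status=kept_status[i],
            sex=kept_sex[i], age=kept_age[i], genotypes=genotypes,
        ))
    cohort = Cohort(subjects=subjects, loci=list(config.loci))
    report = _build_report(config, cohort, b0)
    return cohort, report


def _build_report(config: SimConfig, cohort: Cohort, b0: float) -> SimReport:
    geno_counts: dict[str, dict[str, tuple[int, ...]]] = {}
    a2_freq: dict[str, dict[str, float]] = {}
    by_group = {
        "case": [s for s in cohort.subjects if s.status == 1],
        "control": [s for s in cohort.subjects if s.status == 0],
    }
    for loc in config.loci:
        geno_counts[loc.rsid] = {}
        a2_freq[loc.rsid] = {}
        for grp, subs in by_group.items():
            states = [s.genotypes[loc.rsid] for s in subs]
            if loc.kind == "snp":
                cts = tuple(states.count(x) for x in ("hom_ref", "het", "hom_alt"))
                total = 2 * len(subs)
                freq = (2 * cts[2] + cts[1]) / total if total else float("nan")
            else:
                cts = tuple(states.count(x) for x in ("present", "null"))
                freq = cts[1] / len(subs) if subs else float("nan")
            geno_counts[loc.rsid][grp] = cts
            a2_freq[loc.rsid][grp] = freq
    planted = []
    for eff in config.planted_effects:
        row = {}
        for grp, subs in by_group.items():
            n_carr = 0
            for s in subs:
                if eff.sex is not None and s.sex != eff.sex:
                    continue
                if all(
                    s.genotypes.get(rsid) in states
                    for rsid, states in zip(eff.loci, eff.states)
                ):
                    n_carr += 1
            row[grp] = n_carr
        planted.append(row)
    return SimReport(
        seed=config.seed, intercept=b0,
        genotype_counts=geno_counts, allele2_freq=a2_freq,
        planted_carriers=planted,
    )
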