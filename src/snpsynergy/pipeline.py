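"""End-to-end orchestration with a reproducibility manifest.

``run_pipeline`` sequences the analyses — HWE screen, locus-level
frequency/association tables, genetic models, per-class combination
scans, backward elimination with sex strata — and writes every artifact
under one output prefix together with a JSON manifest (input hashes,
seed, thresholds, package version) so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

from . import __version__, report, stats
from .cohort import Cohort, ENZYME_CLASSES, read_cohort, validate_cohort
from .locus import cohort_summary, hwe_screen, locus_table
from .synergy import backward_eliminate, derive_groupings, scan_class, stratified_results

log = logging.getLogger("snpsynergy")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    cohort_path: str
    meta_path: str
    out_prefix: str
    alpha: float = 0.05
    screen_alpha: float = 0.05
    run_screen: bool = True
    run_single_locus: bool = True
    run_models: bool = True
    run_synergy: bool = True
    classes: tuple[str, ...] = ENZYME_CLASSES
    m_override: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise PipelineError("alpha must lie in (0, 1)")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _out(prefix: Path, ext: str) -> Path:
    return Path(str(prefix) + "." + ext)


def _write(path: Path, text: str, manifest: dict) -> None:
    path.write_text(text, encoding="utf-8")
    manifest["outputs"].append(str(path))


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns (and writes) the manifest."""
    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "inputs": {
            "cohort": {"path": str(config.cohort_path),
                       "sha256": _sha256(config.cohort_path)},
            "meta": {"path": str(config.meta_path),
                     "sha256": _sha256(config.meta_path)},
        },
        "outputs": [],
        "stages": [],
    }
    stage = "load"
    try:
        cohort = read_cohort(config.cohort_path, config.meta_path)
        vrep = validate_cohort(cohort)
        manifest["cohort"] = vrep.as_dict()
        summary = cohort_summary(cohort)
        manifest["demographics"] = {
            "sex_p": summary.sex_p, "age_p": summary.age_p,
            "age_median": summary.age_median,
        }
        manifest["stages"].append(stage)

        kept = cohort
        if config.run_screen:
            stage = "screen"
            t0 = time.perf_counter()
            records = hwe_screen(cohort, config.screen_alpha)
            dropped = [r.locus.rsid for r in records if not r.keep]
            lines = ["rsid\ttestable\tchi2\tp\tkeep"]
            for r in records:
                chi2 = f"{r.result.chi2:.3f}" if r.result else "NA"
                p = f"{r.result.p_value:.3g}" if r.result else "NA"
                lines.append(
                    f"{r.locus.rsid}\t{r.testable}\t{chi2}\t{p}\t{r.keep}"
                )
            _write(_out(prefix, "screen.tsv"),
                   "\n".join(lines) + "\n", manifest)
            if dropped:
                keep_ids = {r.locus.rsid for r in records if r.keep}
                kept = Cohort(
                    subjects=[
                        _strip(s, keep_ids) for s in cohort.subjects
                    ],
                    loci=[l for l in cohort.loci if l.rsid in keep_ids],
                )
            manifest["screen"] = {"dropped": dropped,
                                  "kept": len(cohort.loci) - len(dropped)}
            manifest["stages"].append(stage)
            log.info("screen: %d dropped (%.2fs)", len(dropped),
                     time.perf_counter() - t0)

        reports = None
        if config.run_single_locus or config.run_models:
            stage = "single-locus"
            reports = locus_table(kept, alpha=config.alpha,
                                  screen_alpha=config.screen_alpha)
            if reports:
                manifest["bonferroni"] = {
                    "m_loci": reports[0].bonferroni_m,
                    "threshold": stats.bonferroni_display(
                        config.alpha, reports[0].bonferroni_m
                    ),
                }
        if config.run_single_locus:
            _write(_out(prefix, "table1.tsv"),
                   report.render_locus_table(reports), manifest)
            manifest["stages"].append("single-locus")
        if config.run_models:
            stage = "models"
            n_snp = sum(1 for r in reports if r.locus.kind == "snp")
            manifest["bonferroni_models"] = {
                "m_snp_loci": n_snp,
                "threshold": stats.bonferroni_display(config.alpha, n_snp)
                if n_snp else None,
            }
            _write(_out(prefix, "table2.tsv"),
                   report.render_model_table(reports), manifest)
            manifest["stages"].append(stage)

        if config.run_synergy:
            stage = "synergy"
            groupings = derive_groupings(kept)
            m = config.m_override or len(kept.loci)
            blocks = []
            path_records = {}
            for cls in config.classes:
                if not kept.class_loci(cls):
                    continue
                scan = scan_class(kept, cls, groupings,
                                  alpha=config.alpha, m=m)
                start = next(
                    (r.pattern for r in scan if r.p_value is not None), None
                )
                if start is None:
                    continue
                path = backward_eliminate(kept, start, groupings,
                                          alpha=config.alpha, m=m)
                strata = stratified_results(kept, path, groupings)
                blocks.append((cls, path, strata))
                path_records[cls] = {
                    "scan_best": scan[0].label,
                    "path": [
                        {"pattern": s.label, "p": s.p_value,
                         "or": s.result.odds_ratio,
                         "carriers": s.carriers}
                        for s in path.steps
                    ],
                    "core": path.core.label,
                }
            _write(_out(prefix, "table3.tsv"),
                   report.render_synergy_table(blocks, groupings), manifest)
            _write(_out(prefix, "synergy.json"),
                   json.dumps(path_records, indent=2) + "\n", manifest)
            manifest["stages"].append(stage)
    except Exception as exc:
        marker = _out(prefix, "FAILED")
        marker.write_text(f"stage {stage}: {exc}\n", encoding="utf-8")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    _write(_out(prefix, "manifest.json"),
           json.dumps(manifest, indent=2, sort_keys=True) + "\n", manifest)
    return manifest


def _strip(subject, keep_ids):
    from dataclasses import replace

    return replace(
        subject,
        genotypes={k: v for k, v in subject.genotypes.items()
                   if k in keep_ids},
    )
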