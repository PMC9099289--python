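"""Paper-style plain-text (TSV) renderers for analysis results.

Display conventions: frequencies to 3 decimals, odds ratios and
confidence limits to 3 decimals, P-values to 3 significant figures;
a ``*`` marks odds ratios computed with the Haldane-Anscombe zero-cell
correction.
"""

from __future__ import annotations

from .locus import LocusReport
from .stats import AnalysisError
from .synergy import CombinationResult, EliminationPath, GenotypeGrouping


def _fmt_p(p: float | None) -> str:
    return "NA" if p is None else f"{p:.3g}"


def _fmt_or(res) -> str:
    if res.odds_ratio is None:
        return "NA (separated)" if res.separated else "NA"
    star = "*" if getattr(res, "haldane", False) else ""
    return (f"{res.odds_ratio:.3f}{star} "
            f"({res.ci_low:.3f}-{res.ci_high:.3f})")


def render_locus_table(reports: list[LocusReport]) -> str:
    """Genotype/allele frequency table with adjusted association columns."""
    _check(reports, LocusReport, "table1")
    lines = ["\t".join([
        "polymorphism", "group", "genotype_counts", "genotype_freq",
        "genotype_p", "allele_counts", "allele_freq", "allele_p",
        "allele_or_95ci",
    ])]
    for rep in reports:
        name = f"{rep.locus.gene} ({rep.locus.rsid})"
        geno_p = rep.results.get("genotypic") or rep.results.get("binary")
        allelic = rep.results.get("allelic")
        for grp in ("control", "case"):
            gt = rep.genotype_tables[grp]
            cells = [name if grp == "control" else "", grp,
                     "/".join(str(c) for c in gt.counts),
                     "/".join(f"{f:.3f}" for f in gt.frequencies)]
            if grp == "case":
                cells.append(_fmt_p(geno_p.p_value if geno_p else None))
            else:
                cells.append("")
            if rep.allele_tables is not None:
                at = rep.allele_tables[grp]
                cells.append("/".join(str(c) for c in at.counts))
                cells.append("/".join(f"{f:.3f}" for f in at.frequencies))
            else:
                cells.extend(["", ""])
            if grp == "case" and allelic is not None:
                cells.append(_fmt_p(allelic.p_value))
                cells.append(_fmt_or(allelic))
            elif grp == "case" and geno_p is not None:
                cells.append("")
                cells.append(_fmt_or(geno_p))
            else:
                cells.extend(["", ""])
            lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def render_model_table(reports: list[LocusReport]) -> str:
    """Dominant/recessive/additive model table for SNP loci."""
    _check(reports, LocusReport, "table2")
    lines = ["\t".join([
        "polymorphism", "model", "coding", "p", "or_95ci",
    ])]
    for rep in reports:
        if rep.locus.kind != "snp":
            continue
        a1, a2 = rep.locus.alleles
        rr, ra, aa = (a1 + a1, a1 + a2, a2 + a2)
        codings = {
            "dominant": f"{rr} vs. {ra} + {aa}",
            "recessive": f"{rr} + {ra} vs. {aa}",
            "additive": f"{rr} vs. {ra} vs. {aa}",
        }
        name = f"{rep.locus.gene} ({rep.locus.rsid})"
        for model, coding in codings.items():
            res = rep.results.get(model)
            if res is None:
                continue
            lines.append("\t".join([
                name, model, coding, _fmt_p(res.p_value), _fmt_or(res),
            ]))
    return "\n".join(lines) + "\n"


def render_synergy_table(
    blocks: list[tuple[str, EliminationPath, dict[int, list[CombinationResult]]]],
    groupings: dict[str, GenotypeGrouping],
) -> str:
    """Backward-elimination table: one block per enzyme class.

    ``blocks`` pairs a class name with its elimination path and the
    per-sex re-tests keyed by sex code (0 male, 1 female).
    """
    if not isinstance(blocks, list):
        raise AnalysisError("table3 renderer expects a list of class blocks")
    lines = ["\t".join([
        "class", "pattern", "stratum", "control_n(freq)", "case_n(freq)",
        "p", "or_95ci",
    ])]
    for class_name, path, strata in blocks:
        if not isinstance(path, EliminationPath):
            raise AnalysisError("table3 renderer expects EliminationPath blocks")
        locus_header = "/".join(l.rsid for l in path.steps[0].pattern.loci)
        lines.append(f"{class_name}: {locus_header}\t\t\t\t\t\t")
        for i, step in enumerate(path.steps):
            rows = [("all", step)]
            for sex, sex_name in ((1, "female"), (0, "male")):
                if strata and len(strata.get(sex, [])) > i:
                    rows.append((sex_name, strata[sex][i]))
            for stratum, res in rows:
                kc, nc = res.carriers["control"]
                kp, np_ = res.carriers["case"]
                lines.append("\t".join([
                    class_name, res.label, stratum,
                    f"{kc} ({kc / nc:.3f})" if nc else "0 (NA)",
                    f"{kp} ({kp / np_:.3f})" if np_ else "0 (NA)",
                    _fmt_p(res.p_value), _fmt_or(res.result),
                ]))
    footnote = render_grouping_footnote(groupings)
    return "\n".join(lines) + "\n# " + footnote + "\n"


def render_grouping_footnote(groupings: dict[str, GenotypeGrouping]) -> str:
    """Footnote describing every dichotomisation, in locus order."""
    parts = [
        f"{g.describe()} for {rsid}"
        for rsid, g in groupings.items()
        if g.locus.kind == "snp"
    ]
    presence = [rsid for rsid, g in groupings.items()
                if g.locus.kind == "presence"]
    text = ("group 1 and group 2 respectively denote "
            + ", ".join(parts))
    if presence:
        text += ("; P and N respectively denote present and null for "
                 + " and ".join(presence))
    return text


_STYLES = {"table1": render_locus_table, "table2": render_model_table}


def render_table(results, style: str, **kwargs) -> str:
    """Dispatch to a renderer by style name (table1 | table2 | table3)."""
    if style in _STYLES:
        return _STYLES[style](results)
    if style == "table3":
        return render_synergy_table(results, **kwargs)
    raise AnalysisError(f"unknown table style {style!r}")


def _check(reports, cls, style) -> None:
    if not isinstance(reports, list) or not all(
        isinstance(r, cls) for r in reports
    ):
        raise AnalysisError(f"{style} renderer expects a list of {cls.__name__}")
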