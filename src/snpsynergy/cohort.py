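"""Cohort and locus containers, on-disk formats, validation.

The canonical interchange format is a UTF-8 tab-separated table with a
header row ``subject_id  status  sex  age  <rsid> ...`` — one genotype
column per locus.  SNP genotypes are two-letter allele pairs ("TC" and
"CT" are the same call and are normalised against the declared allele
order); deletion polymorphisms use the literal tokens ``present`` /
``null``; ``NA`` marks a missing call.  Locus metadata travels in a
small YAML document (see :func:`read_locus_metadata`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd
import yaml

try:  # Python >= 3.9
    from importlib.resources import files as _pkg_files
except ImportError:  # pragma: no cover
    _pkg_files = None

ENZYME_CLASSES = ("CYP", "esterase", "GST")
SNP_STATES = ("hom_ref", "het", "hom_alt")
PRESENCE_STATES = ("present", "null")
MISSING = "NA"


class CohortFormatError(ValueError):
    """Raised for malformed cohort tables or locus metadata."""


@dataclass(frozen=True)
class LocusDef:
    """Metadata for one polymorphism.

    ``alleles`` orders the two alleles of a SNP: the first defines the
    reference homozygote, the second is the effect allele.  Deletion
    (presence/null) loci carry the fixed state pair instead.
    """

    rsid: str
    gene: str
    enzyme_class: str
    kind: str
    alleles: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.enzyme_class not in ENZYME_CLASSES:
            raise CohortFormatError(
                f"locus {self.rsid}: enzyme_class {self.enzyme_class!r} "
                f"not in {ENZYME_CLASSES}"
            )
        if self.kind not in ("snp", "presence"):
            raise CohortFormatError(
                f"locus {self.rsid}: kind must be 'snp' or 'presence'"
            )
        if self.kind == "snp":
            if self.alleles is None or len(self.alleles) != 2:
                raise CohortFormatError(
                    f"locus {self.rsid}: snp loci need exactly two alleles"
                )
            if self.alleles[0] == self.alleles[1]:
                raise CohortFormatError(
                    f"locus {self.rsid}: alleles must be distinct"
                )
            object.__setattr__(self, "alleles", tuple(self.alleles))
        elif self.alleles is not None:
            raise CohortFormatError(
                f"locus {self.rsid}: presence loci carry no allele pair"
            )

    @property
    def states(self) -> tuple[str, ...]:
        return SNP_STATES if self.kind == "snp" else PRESENCE_STATES

    def state_token(self, state: str) -> str:
        """Canonical on-disk token for an internal state."""
        if self.kind == "presence":
            if state not in PRESENCE_STATES:
                raise CohortFormatError(f"{self.rsid}: bad state {state!r}")
            return state
        a1, a2 = self.alleles  # type: ignore[misc]
        return {"hom_ref": a1 + a1, "het": a1 + a2, "hom_alt": a2 + a2}[state]

    def parse_token(self, token: str) -> str | None:
        """Normalise a genotype token to an internal state.

        Returns ``None`` for the missing sentinel; raises on anything
        else that is not a valid call for this locus.
        """
        token = token.strip()
        if token == MISSING:
            return None
        if self.kind == "presence":
            if token in PRESENCE_STATES:
                return token
            raise CohortFormatError(
                f"{self.rsid}: invalid presence token {token!r}"
            )
        a1, a2 = self.alleles  # type: ignore[misc]
        if len(token) == 2 and set(token) <= {a1, a2}:
            n_alt = token.count(a2)
            return SNP_STATES[n_alt]
        raise CohortFormatError(
            f"{self.rsid}: invalid genotype token {token!r} "
            f"for alleles {a1}/{a2}"
        )

    def normalize_token(self, token: str) -> str:
        """Canonicalise an on-disk token (unordered allele pair)."""
        state = self.parse_token(token)
        return MISSING if state is None else self.state_token(state)


@dataclass
class Subject:
    """One study participant: case/control status, covariates, calls."""

    id: str
    status: int  # 1 = case, 0 = control
    sex: int  # 0 = male, 1 = female
    age: float  # years
    genotypes: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status not in (0, 1):
            raise CohortFormatError(f"subject {self.id}: status must be 0/1")
        if self.sex not in (0, 1):
            raise CohortFormatError(f"subject {self.id}: sex must be 0/1")
        if not self.age > 0:
            raise CohortFormatError(f"subject {self.id}: age must be > 0")


@dataclass
class Cohort:
    """A validated set of subjects plus the loci they are typed at."""

    subjects: list[Subject]
    loci: list[LocusDef]

    def __post_init__(self) -> None:
        rsids = [loc.rsid for loc in self.loci]
        if len(set(rsids)) != len(rsids):
            raise CohortFormatError("duplicate rsid in locus metadata")
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortFormatError(f"duplicate subject id(s): {dup[:5]}")
        known = set(rsids)
        for subj in self.subjects:
            extra = set(subj.genotypes) - known
            if extra:
                raise CohortFormatError(
                    f"subject {subj.id}: genotype at undeclared locus "
                    f"{sorted(extra)}"
                )

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def locus_map(self) -> dict[str, LocusDef]:
        return {loc.rsid: loc for loc in self.loci}

    def locus(self, rsid: str) -> LocusDef:
        try:
            return self.locus_map[rsid]
        except KeyError:
            raise KeyError(f"locus {rsid!r} not in cohort") from None

    def class_loci(self, enzyme_class: str) -> list[LocusDef]:
        return [l for l in self.loci if l.enzyme_class == enzyme_class]

    def to_frame(self) -> pd.DataFrame:
        """Subject-level DataFrame with one state column per locus."""
        records = []
        for s in self.subjects:
            row = {"subject_id": s.id, "status": s.status, "sex": s.sex,
                   "age": s.age}
            for loc in self.loci:
                row[loc.rsid] = s.genotypes.get(loc.rsid)
            records.append(row)
        cols = ["subject_id", "status", "sex", "age"] + [
            l.rsid for l in self.loci
        ]
        return pd.DataFrame(records, columns=cols)


@dataclass
class ValidationReport:
    n_subjects: int
    n_cases: int
    n_controls: int
    n_female_cases: int
    n_female_controls: int
    missingness: dict[str, float]
    age_range: tuple[float, float] | None

    def as_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "n_female_cases": self.n_female_cases,
            "n_female_controls": self.n_female_controls,
            "missingness": dict(self.missingness),
            "age_range": list(self.age_range) if self.age_range else None,
        }


def read_locus_metadata(path: str | Path) -> list[LocusDef]:
    """Load locus definitions from a YAML document with a ``loci`` list."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return _loci_from_doc(doc, str(path))


def _loci_from_doc(doc: object, source: str) -> list[LocusDef]:
    if not isinstance(doc, dict) or "loci" not in doc:
        raise CohortFormatError(f"{source}: metadata must map a 'loci' list")
    loci = []
    for entry in doc["loci"]:
        alleles = entry.get("alleles")
        loci.append(
            LocusDef(
                rsid=str(entry["rsid"]),
                gene=str(entry["gene"]),
                enzyme_class=str(entry["enzyme_class"]),
                kind=str(entry["kind"]),
                alleles=tuple(str(a) for a in alleles) if alleles else None,
            )
        )
    if len({l.rsid for l in loci}) != len(loci):
        raise CohortFormatError(f"{source}: duplicate rsid in metadata")
    return loci


def packaged_loci() -> list[LocusDef]:
    """The packaged 13-locus xenobiotic-metabolism panel."""
    text = (_pkg_files("snpsynergy") / "data" / "loci_13.yaml").read_text(
        encoding="utf-8"
    )
    return _loci_from_doc(yaml.safe_load(text), "loci_13.yaml")


def packaged_study_counts() -> dict:
    """Published per-locus summary counts and model P-values."""
    text = (_pkg_files("snpsynergy") / "data" / "study_counts.yaml").read_text(
        encoding="utf-8"
    )
    return yaml.safe_load(text)


def read_cohort(cohort_path: str | Path, meta_path: str | Path) -> Cohort:
    """Read a cohort TSV against its locus metadata and validate it.

    Every genotype column must be declared in the metadata; genotype
    tokens are normalised against the declared allele order; any token
    other than a valid call or ``NA`` fails with the offending
    row/column named.
    """
    loci = read_locus_metadata(meta_path)
    table = pd.read_csv(
        cohort_path, sep="\t", dtype=str, keep_default_na=False, na_values=[]
    )
    required = ["subject_id", "status", "sex", "age"]
    if list(table.columns[:4]) != required:
        raise CohortFormatError(
            f"{cohort_path}: header must start with {required}, "
            f"got {list(table.columns[:4])}"
        )
    locus_map = {l.rsid: l for l in loci}
    geno_cols = list(table.columns[4:])
    unknown = [c for c in geno_cols if c not in locus_map]
    if unknown:
        raise CohortFormatError(
            f"{cohort_path}: undeclared locus column(s) {unknown}"
        )
    subjects = []
    for idx, row in enumerate(table.itertuples(index=False), start=2):
        rec = dict(zip(table.columns, row))
        try:
            status = int(rec["status"])
            sex = int(rec["sex"])
            age = float(rec["age"])
        except ValueError as exc:
            raise CohortFormatError(
                f"{cohort_path} line {idx}: bad status/sex/age field ({exc})"
            ) from None
        genotypes: dict[str, str | None] = {}
        for col in geno_cols:
            try:
                genotypes[col] = locus_map[col].parse_token(rec[col])
            except CohortFormatError as exc:
                raise CohortFormatError(
                    f"{cohort_path} line {idx}, column {col}: {exc}"
                ) from None
        subjects.append(
            Subject(id=rec["subject_id"], status=status, sex=sex, age=age,
                    genotypes=genotypes)
        )
    missing_cols = [l.rsid for l in loci if l.rsid not in geno_cols]
    if missing_cols:
        raise CohortFormatError(
            f"{cohort_path}: metadata loci missing from table: {missing_cols}"
        )
    return Cohort(subjects=subjects, loci=list(loci))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the canonical TSV; a read-back reproduces the cohort."""
    lines = ["\t".join(
        ["subject_id", "status", "sex", "age"]
        + [l.rsid for l in cohort.loci]
    )]
    for s in cohort.subjects:
        cells = [s.id, str(s.status), str(s.sex), _fmt_age(s.age)]
        for loc in cohort.loci:
            state = s.genotypes.get(loc.rsid)
            cells.append(MISSING if state is None else loc.state_token(state))
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _fmt_age(age: float) -> str:
    # integral ages render without a trailing ".0" so round trips are exact
    return str(int(age)) if float(age).is_integer() else repr(float(age))


def validate_cohort(cohort: Cohort) -> ValidationReport:
    """Report-only summary: group sizes, missingness, age range."""
    n = len(cohort.subjects)
    cases = [s for s in cohort.subjects if s.status == 1]
    controls = [s for s in cohort.subjects if s.status == 0]
    missingness = {}
    for loc in cohort.loci:
        miss = sum(
            1 for s in cohort.subjects if s.genotypes.get(loc.rsid) is None
        )
        missingness[loc.rsid] = miss / n if n else 0.0
    ages = [s.age for s in cohort.subjects]
    return ValidationReport(
        n_subjects=n,
        n_cases=len(cases),
        n_controls=len(controls),
        n_female_cases=sum(s.sex for s in cases),
        n_female_controls=sum(s.sex for s in controls),
        missingness=missingness,
        age_range=(min(ages), max(ages)) if ages else None,
    )
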