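import pytest

import snpsynergy as ss


@pytest.fixture(scope="session")
def panel_loci():
    return ss.packaged_loci()


@pytest.fixture(scope="session")
def study_counts():
    return ss.packaged_study_counts()


@pytest.fixture(scope="session")
def default_cohort():
    """One deterministic synthetic cohort under the default design."""
    cohort, report = ss.simulate_cohort(ss.default_config(seed=1))
    return cohort, report


@pytest.fixture
def two_loci():
    return [
        ss.LocusDef(rsid="rs111", gene="GENE1", enzyme_class="CYP",
                    kind="snp", alleles=("T", "C")),
        ss.LocusDef(rsid="GENEDEL", gene="GENEDEL", enzyme_class="GST",
                    kind="presence"),
    ]


@pytest.fixture
def tiny_cohort(two_loci):
    """Hand-written 5-subject cohort over one SNP and one deletion locus."""
    rows = [
        ("a1", 1, 0, 61.0, {"rs111": "hom_ref", "GENEDEL": "present"}),
        ("a2", 1, 1, 70.0, {"rs111": "het", "GENEDEL": "null"}),
        ("a3", 0, 0, 55.0, {"rs111": "hom_alt", "GENEDEL": "null"}),
        ("a4", 0, 1, 58.0, {"rs111": "het", "GENEDEL": "present"}),
        ("a5", 0, 0, 63.0, {"rs111": None, "GENEDEL": "present"}),
    ]
    subjects = [
        ss.Subject(id=i, status=st, sex=sx, age=a, genotypes=dict(g))
        for i, st, sx, a, g in rows
    ]
    return ss.Cohort(subjects=subjects, loci=list(two_loci))


@pytest.fixture
def tiny_files(tmp_path, tiny_cohort):
    """The tiny cohort written to disk as TSV + YAML metadata."""
    meta = tmp_path / "meta.yaml"
    meta.write_text(
        "loci:\n"
        "  - {rsid: rs111, gene: GENE1, enzyme_class: CYP, kind: snp,"
        " alleles: [T, C]}\n"
        "  - {rsid: GENEDEL, gene: GENEDEL, enzyme_class: GST,"
        " kind: presence}\n"
    )
    tsv = tmp_path / "cohort.tsv"
    ss.write_cohort(tiny_cohort, tsv)
    return tsv, meta
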