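# Locus metadata for the 13-polymorphism xenobiotic-metabolism panel:
# five cytochrome P450 (CYP) loci, three esterase loci and five
# glutathione S-transferase (GST) loci.  GSTM1 and GSTT1 are whole-gene
# deletion polymorphisms scored only as gene-present vs homozygous-null.
#
# Allele order is significant: the first allele defines hom_ref, the
# second is the effect allele whose dose is modelled in association
# analyses.  For presence-kind loci the fixed states are (present, null)
# and "null" is the effect state.
loci:
  - rsid: rs12441817
    gene: CYP1A1
    enzyme_class: CYP
    kind: snp
    alleles: [T, C]
  - rsid: rs1048943
    gene: CYP1A1
    enzyme_class: CYP
    kind: snp
    alleles: [T, C]
  - rsid: rs762551
    gene: CYP1A2
    enzyme_class: CYP
    kind: snp
    alleles: [C, A]
  - rsid: rs4244285
    gene: CYP2C19
    enzyme_class: CYP
    kind: snp
    alleles: [G, A]
  - rsid: rs2070676
    gene: CYP2E1
    enzyme_class: CYP
    kind: snp
    alleles: [G, C]
  - rsid: rs662
    gene: PON1
    enzyme_class: esterase
    kind: snp
    alleles: [T, C]
  - rsid: rs12026
    gene: PON2
    enzyme_class: esterase
    kind: snp
    alleles: [G, C]
  - rsid: rs1803274
    gene: BCHE
    enzyme_class: esterase
    kind: snp
    alleles: [C, T]
  - rsid: GSTM1
    gene: GSTM1
    enzyme_class: GST
    kind: presence
  - rsid: GSTT1
    gene: GSTT1
    enzyme_class: GST
    kind: presence
  - rsid: rs4925
    gene: GSTO1
    enzyme_class: GST
    kind: snp
    alleles: [C, A]
  - rsid: rs156697
    gene: GSTO2
    enzyme_class: GST
    kind: snp
    alleles: [A, G]
  - rsid: rs1695
    gene: GSTP1
    enzyme_class: GST
    kind: snp
    alleles: [A, G]
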