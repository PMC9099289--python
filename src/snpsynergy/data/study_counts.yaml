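# Published summary statistics from the source case-control study of
# xenobiotic-metabolism polymorphisms and Parkinson's disease (527
# sporadic cases, 499 controls, Han Chinese cohort from eastern China).
#
# genotype_counts: per-locus genotype counts in locus state order
#   (hom_ref, het, hom_alt) for SNPs or (present, null) for deletion
#   polymorphisms, per group.  These control counts are the source of
#   the default simulation allele frequencies; the full table is the
#   input for grouping-reconstruction and arithmetic oracle checks.
# model_p: age- and sex-adjusted dominant/recessive-model P-values as
#   printed in the study, used for reconstructing the published
#   genotype dichotomisation.
# combination_counts: published carrier counts (control, case) for
#   selected multi-locus genotype combinations (slot string uses the
#   class locus order; "-" is a wildcard).
cohort:
  n_cases: 527
  n_controls: 499
  n_female_cases: 257
  n_female_controls: 229
  case_age_median: 66
  case_age_iqr: [59, 73]
  control_age_median: 58
  control_age_iqr: [50, 68]
genotype_counts:
  rs12441817:
    control: [138, 242, 119]
    case: [150, 280, 97]
  rs1048943:
    control: [288, 174, 37]
    case: [328, 177, 22]
  rs762551:
    control: [66, 232, 201]
    case: [77, 277, 173]
  rs4244285:
    control: [213, 226, 60]
    case: [223, 246, 58]
  rs2070676:
    control: [12, 157, 330]
    case: [9, 152, 366]
  rs662:
    control: [60, 235, 204]
    case: [75, 225, 227]
  rs12026:
    control: [329, 153, 17]
    case: [347, 170, 10]
  rs1803274:
    control: [393, 101, 5]
    case: [417, 105, 5]
  GSTM1:
    control: [279, 220]
    case: [270, 257]
  GSTT1:
    control: [258, 241]
    case: [295, 232]
  rs4925:
    control: [343, 141, 15]
    case: [380, 132, 15]
  rs156697:
    control: [263, 192, 44]
    case: [305, 189, 33]
  rs1695:
    control: [320, 159, 20]
    case: [333, 174, 20]
model_p:
  rs12441817: {dominant: 0.68, recessive: 0.04}
  rs1048943: {dominant: 0.13, recessive: 0.14}
  rs762551: {dominant: 0.36, recessive: 0.025}
  rs4244285: {dominant: 0.72, recessive: 0.90}
  rs2070676: {dominant: 0.40, recessive: 0.31}
  rs662: {dominant: 0.39, recessive: 0.49}
  rs12026: {dominant: 0.90, recessive: 0.094}
  rs1803274: {dominant: 0.76, recessive: 0.87}
  rs4925: {dominant: 0.14, recessive: 0.56}
  rs156697: {dominant: 0.049, recessive: 0.16}
  rs1695: {dominant: 0.67, recessive: 0.72}
# Published two-group genotype dichotomisation (group1 / group2 as sets
# of locus states), used to verify grouping reconstruction.
published_grouping:
  rs12441817: {group1: [hom_ref, het], group2: [hom_alt]}
  rs1048943: {group1: [hom_ref], group2: [het, hom_alt]}
  rs762551: {group1: [hom_ref, het], group2: [hom_alt]}
  rs4244285: {group1: [hom_ref], group2: [het, hom_alt]}
  rs2070676: {group1: [hom_ref, het], group2: [hom_alt]}
  rs662: {group1: [hom_ref], group2: [het, hom_alt]}
  rs12026: {group1: [hom_ref], group2: [het, hom_alt]}
  rs1803274: {group1: [hom_ref], group2: [het, hom_alt]}
  rs4925: {group1: [hom_ref], group2: [het, hom_alt]}
  rs156697: {group1: [hom_ref], group2: [het, hom_alt]}
  rs1695: {group1: [hom_ref], group2: [het, hom_alt]}
combination_counts:
  CYP:
    # locus order: rs12441817/rs1048943/rs762551/rs4244285/rs2070676
    - {slots: "2/2/2/1/1", control: 14, case: 4}
    - {slots: "2/2/2/-/1", control: 27, case: 12}
    - {slots: "2/-/2/-/1", control: 34, case: 15}
    - {slots: "2/-/-/-/1", control: 40, case: 18}
  esterase:
    # locus order: rs662/rs12026/rs1803274
    - {slots: "1/1/1", control: 21, case: 28}
    - {slots: "1/1/-", control: 28, case: 36}
  GST:
    # locus order: GSTM1/GSTT1/rs4925/rs156697/rs1695
    - {slots: "P/N/1/2/1", control: 17, case: 5}
    - {slots: "P/N/-/2/1", control: 34, case: 17}
    - {slots: "P/N/-/2/-", control: 57, case: 32}
    - {slots: "-/N/-/2/-", control: 117, case: 89}
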