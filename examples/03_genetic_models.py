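"""Dominant / recessive / log-additive model fits for one locus.

The models recode genotypes into an exposure (hom_ref vs rest; rest vs
hom_alt; effect-allele dose) and fit a logistic regression of case
status with age and sex as covariates.
"""

import snpsynergy as ss

cohort, _ = ss.simulate_cohort(ss.default_config(seed=1))
locus = cohort.locus("rs12441817")
a1, a2 = locus.alleles
codings = {
    "dominant": f"{a1}{a1} vs. {a1}{a2} + {a2}{a2}",
    "recessive": f"{a1}{a1} + {a1}{a2} vs. {a2}{a2}",
    "additive": f"{a1}{a1} vs. {a1}{a2} vs. {a2}{a2}",
}

print(f"{locus.gene} ({locus.rsid}), adjusted for age and sex")
for model, coding in codings.items():
    res = ss.run_model(cohort, locus, model)
    print(f"  {model:<10}{coding:<22}"
          f"OR {res.odds_ratio:.2f} ({res.ci_low:.2f}-{res.ci_high:.2f})  "
          f"P = {res.p_value:.2f}")
# An OR below 1 means carrying the effect allele (second listed, here C)
# under that coding lowers the odds of being a case.
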