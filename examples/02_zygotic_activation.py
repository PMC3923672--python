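"""Track zygotic genome activation through the doubled paternal fraction.

Maternally deposited transcript carries only maternal alleles; zygotic
transcript from biallelic loci is split evenly between parental alleles.
Doubling the paternal read fraction therefore estimates the zygotic share
of each gene's transcript pool. A species profile with a one-stage
activation delay lags visibly at every early stage.
"""

import pandas as pd

import embryocomp as ec

rows = {}
for profile in ("pse_like", "mir_like"):
    _, allele, sheet, ann, _ = ec.simulate_experiment(
        ec.default_config(profile, seed=23))
    zf = ec.zygotic_fraction(ec.allele_fractions(allele), sheet, ann)
    pooled = zf.groupby("stage").apply(
        lambda g: (g["mean_z"] * g["n_genes"]).sum() / g["n_genes"].sum(),
        include_groups=False)
    rows[profile] = pooled.round(3)

table = pd.DataFrame(rows)
table.index.name = "stage"
print("mean zygotic transcript fraction per gene (female embryos):")
print(table.to_string())
print("\nThe delayed profile (mir_like) reaches each zygotic-fraction level "
      "about one stage later, then converges late in the timecourse.")
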