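"""Detect the onset of dosage compensation from the maternal allele.

Both sexes carry exactly one maternal copy of each chromosome, so the mean
maternal-allele transcript level should agree between the sexes — until the
single male X is upregulated. A stage is flagged when the male mean rises
above the 97.5% quantile of the gene-resampling bootstrap distribution of
the female mean. Genes are classified zygotic by total transcript level
(no deposition at the first stage) to keep the allele-level comparison
non-circular.
"""

import warnings

import embryocomp as ec

for profile in ("pse_like", "mir_like"):
    expr, allele, sheet, ann, _ = ec.simulate_experiment(
        ec.default_config(profile, seed=31))
    norm = ec.normalize_autosomal(expr, ann)
    tl = ec.call_transcript_level(norm, sheet)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = ec.maternal_allele_onset(allele, norm, sheet, ann, tl,
                                          n_boot=1000, seed=1)
    print(f"\n{profile}: earliest stage with significantly higher male "
          f"maternal-allele level: {report.onset_stage}")
    t = report.table
    x = t[(t["class"] == "XL") & (t["stage"] >= 4)]
    print(x[["stage", "n_genes", "male_mean", "female_mean", "ratio",
             "significant"]].round(2).to_string(index=False))

print("\nAutosomes never separate; the X onset appears one stage later in "
      "the delayed (mir_like) profile, and the male:female maternal-allele "
      "ratio reaches ~2 when compensation completes.")
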