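"""Polygenic risk scores: established variants, group means, down-sampling
and the cumulative-threshold sweep.

Scores are built from genome-wide-significant clumped variants of each base
study and evaluated by the full-vs-null Nagelkerke pseudo-R² logistic
regression (ten MDS covariates).  The headline pattern: each score
associates with its own disorder and with the comorbid group, not with the
other disorder, and the comorbid group's trait-2 score mean falls between
the trait-1-only and trait-2-only groups.
"""

import numpy as np
import pandas as pd

from comorbigen import prs

from common import SEED, clean_study, outpath, study

st = study()
clean, pheno, _ = clean_study()

established = {}
for key, ss in (("trait1", st.sumstats1), ("trait2", st.sumstats2)):
    clumped = prs.clump(ss, clean)
    established[key] = clumped[clumped["p"] < 5e-8]
    print(f"{key}: {len(clumped)} clumped variants, "
          f"{len(established[key])} genome-wide significant")

pairs = [("SCZ", "CONTROL"), ("T2D", "CONTROL"), ("SCZplusT2D", "CONTROL"),
         ("T2D", "SCZ"), ("SCZplusT2D", "SCZ"), ("SCZplusT2D", "T2D")]
rows = []
for key in ("trait1", "trait2"):
    for case, ctrl in pairs:
        res = prs.prs_analysis(established[key], clean, pheno, case, ctrl)
        rows.append((key, f"{case}_vs_{ctrl}", res.n_variants_used,
                     round(100 * res.r2_final, 3), res.p_assoc))
summary = pd.DataFrame(rows, columns=["score", "comparison", "n_variants",
                                      "r2_final_pct", "p_assoc"])
summary.to_csv(outpath("04_prs_established.tsv"), sep="\t", index=False)
print("\nestablished-variant scores:")
print(summary.to_string(index=False))

means_rows = []
for key in ("trait1", "trait2"):
    matched, _ = prs.match_alleles(established[key], clean)
    s = prs.score_samples(matched, clean)
    std = (s - s.mean()) / s.std()
    for grp in ("CONTROL", "SCZ", "SCZplusT2D", "T2D"):
        members = pheno.group(grp)
        sem = std.loc[members].std(ddof=1) / np.sqrt(len(members))
        means_rows.append((key, grp, round(std.loc[members].mean(), 3),
                           round(sem, 3)))
means = pd.DataFrame(means_rows, columns=["score", "group",
                                          "mean_std_score", "sem"])
means.to_csv(outpath("04_group_score_means.tsv"), sep="\t", index=False)
print("\nstandardized score means by group:")
print(means.to_string(index=False))

down = prs.downsample_analysis(established["trait2"], clean, pheno,
                               "T2D", "CONTROL", n_per_group=500, reps=500,
                               seed=SEED)
print(f"\ndown-sampling (n=500/group, {down['reps']} reps): "
      f"mean R2_final = {100 * down['mean_r2_final']:.2f}%, "
      f"mean p = {down['mean_p']:.3g}")

sweep = prs.threshold_sweep(st.sumstats2, clean, pheno, "SCZplusT2D",
                            "CONTROL")
sweep.to_csv(outpath("04_threshold_sweep_trait2_comorbid.tsv"), sep="\t",
             index=False)
print("\ncumulative-threshold sweep (trait-2 score, comorbid vs controls):")
print(sweep.to_string(index=False))
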