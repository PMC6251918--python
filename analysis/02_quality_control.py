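"""Cohort quality control: sample filters, ancestry MDS, variant filters.

Removes low-call-rate samples, heterozygosity outliers (+/- 3 SD), one
member of each related pair (pi_hat > 0.2, estimated on an LD-pruned
marker subset) and MDS outliers, then filters variants on call rate,
Hardy-Weinberg exact p, imputation info score and MAF.
"""

from collections import Counter

import pandas as pd

from common import clean_study, outpath, study

st = study()
clean, pheno, report = clean_study()

sample_counts = Counter(r for _, r in report.removed_samples)
variant_counts = Counter(r for _, rs in report.removed_variants for r in rs)
summary = pd.DataFrame(
    [("sample", k, v) for k, v in sample_counts.items()]
    + [("variant", k, v) for k, v in variant_counts.items()],
    columns=["kind", "reason", "n_removed"],
)
summary.to_csv(outpath("02_qc_summary.tsv"), sep="\t", index=False)
print(summary.to_string(index=False))
print(f"\nkept {clean.n_samples}/{st.genotypes.n_samples} samples, "
      f"{clean.n_variants}/{st.genotypes.n_variants} variants")

post = pheno.table["GROUP"].value_counts().rename("post_qc")
pre = st.phenotypes.table["GROUP"].value_counts().rename("pre_qc")
table1 = pd.concat([pre, post], axis=1)
table1.to_csv(outpath("02_groups_pre_post_qc.tsv"), sep="\t")
print("\ngroup sizes before/after QC:")
print(table1.to_string())
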