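"""Extent of shared association signals between the two base studies.

LD-prunes the variants shared by the two summary-statistics tables
(p-value informed, r² > 0.1 removed), builds 2x2 tables at the ten
cumulative thresholds, and reports the chi-square overlap p-value and the
permutation-derived empirical p-value at each threshold.
"""

from comorbigen import overlap

from common import SEED, clean_study, outpath, study

st = study()
clean, _, _ = clean_study()

results = overlap.overlap_analysis(
    st.sumstats1, st.sumstats2, clean, B=100_000, seed=SEED,
)
frame = overlap.overlap_results_frame(results)
frame.to_csv(outpath("05_overlap.tsv"), sep="\t", index=False)
print(frame[["P_t", "variants", "chi2", "P", "P_perm"]].to_string(index=False))

rejected = int((frame["P_perm"] < 0.05).sum())
print(f"\nsignificant excess of shared signals (P_perm < 0.05) at "
      f"{rejected} of {len(frame)} thresholds")
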