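"""Polygenic risk scores: allele matching, p-value-informed LD clumping,
scoring, Nagelkerke pseudo-R² evaluation and the down-sampling robustness
analysis.

A score for sample *s* over the matched weight set is the average weighted
effect-allele count, score_s = (1/m) * sum_j dosage_sj * w_j, with missing
dosages replaced by the expected count 2*EAF_j.  Association strength is
the difference of Nagelkerke pseudo-R² between the full logistic model
(phenotype ~ score + C1..C10) and the null model (covariates only):
R2_final = R2_full - R2_null, with the score's Wald p from the full model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import (
    GenotypeDataset,
    PhenotypeTable,
    SummaryStatsTable,
    ValidationError,
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _comp(allele: str) -> str:
    return allele.translate(_COMPLEMENT)


def _is_palindromic(ea: str, nea: str) -> bool:
    return {ea, nea} in ({"A", "T"}, {"C", "G"})


# ---------------------------------------------------------------------------
# Allele matching


def match_alleles(
    base: pd.DataFrame, target: GenotypeDataset
) -> tuple[pd.DataFrame, dict]:
    """Reconcile base-study weights with the target's allele orientation.

    Weight frames carry columns id, ea, nea, weight (log OR) and optionally
    p.  Outcomes per variant: kept as-is; kept with the weight negated when
    the alleles are swapped; strand flips resolved via complements (with or
    without a swap); ambiguous palindromic (A/T, C/G) variants removed;
    unresolvable pairs removed.  Returns the matched frame (ea/nea in
    target orientation) and a count per outcome.
    """
    tv = target.variants.set_index("id")
    report = {k: 0 for k in ("kept", "swapped", "flipped", "flipped_swapped",
                             "ambiguous", "mismatch", "absent")}
    rows = []
    for r in base.itertuples(index=False):
        if r.id not in tv.index:
            report["absent"] += 1
            continue
        if _is_palindromic(r.ea, r.nea):
            report["ambiguous"] += 1
            continue
        tea, tnea = tv.at[r.id, "ea"], tv.at[r.id, "nea"]
        pair = (r.ea, r.nea)
        flipped = (_comp(r.ea), _comp(r.nea))
        if pair == (tea, tnea):
            w, action = r.weight, "kept"
        elif pair == (tnea, tea):
            w, action = -r.weight, "swapped"
        elif flipped == (tea, tnea):
            w, action = r.weight, "flipped"
        elif flipped == (tnea, tea):
            w, action = -r.weight, "flipped_swapped"
        else:
            report["mismatch"] += 1
            continue
        report[action] += 1
        rows.append((r.id, tea, tnea, w, getattr(r, "p", np.nan)))
    matched = pd.DataFrame(rows, columns=["id", "ea", "nea", "weight", "p"])
    return matched, report


# ---------------------------------------------------------------------------
# LD clumping


def _pairwise_r2(dosages: np.ndarray, idx: int, cols: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of variant ``idx`` with each of ``cols``,
    over jointly non-missing samples."""
    y = dosages[:, idx]
    x = dosages[:, cols]
    valid = ~np.isnan(y)[:, None] & ~np.isnan(x)
    yv = np.where(valid, y[:, None], 0.0)
    xv = np.where(valid, x, 0.0)
    n = valid.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sy, sx = yv.sum(axis=0), xv.sum(axis=0)
        syy = (yv**2).sum(axis=0) - sy**2 / n
        sxx = (xv**2).sum(axis=0) - sx**2 / n
        sxy = (yv * xv).sum(axis=0) - sy * sx / n
        r2 = sxy**2 / (syy * sxx)
    return np.where(np.isfinite(r2), r2, 0.0)


def clump(
    sumstats: SummaryStatsTable,
    genotypes: GenotypeDataset,
    r2_max: float = 0.1,
    window_kb: float = 250.0,
) -> pd.DataFrame:
    """P-value-informed LD clumping against the target LD.

    Greedily takes the smallest-p unclaimed variant as an index and removes
    unclaimed variants within +/- ``window_kb`` whose r² with the index
    exceeds ``r2_max``.  Returns the index set as a weight frame (id, ea,
    nea, weight = base log OR, p), ordered by p.
    """
    tv = genotypes.variants
    shared = sumstats.table[sumstats.table["id"].isin(set(tv["id"]))]
    if len(shared) == 0:
        raise ValidationError("no overlap between summary stats and LD reference")
    col_of = {v: j for j, v in enumerate(tv["id"])}
    cand = shared.sort_values(["p", "id"], kind="mergesort").reset_index(drop=True)
    cols = np.array([col_of[v] for v in cand["id"]])
    chrom = tv["chrom"].to_numpy()[cols]
    pos = tv["pos"].to_numpy()[cols]
    window = window_kb * 1000.0

    unclaimed = np.ones(len(cand), dtype=bool)
    picked = []
    d = genotypes.dosages.astype(np.float64)
    for i in range(len(cand)):
        if not unclaimed[i]:
            continue
        unclaimed[i] = False
        picked.append(i)
        near = unclaimed & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window)
        near_idx = np.flatnonzero(near)
        if len(near_idx):
            r2 = _pairwise_r2(d, cols[i], cols[near_idx])
            unclaimed[near_idx[r2 > r2_max]] = False
    out = cand.iloc[picked][["id", "ea", "nea", "beta", "p"]].rename(
        columns={"beta": "weight"}
    )
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Scoring and evaluation


def score_samples(weights: pd.DataFrame, genotypes: GenotypeDataset) -> pd.Series:
    """Per-sample mean weighted effect-allele count.

    ``weights`` must already be allele-matched to the target orientation.
    Missing dosages are replaced by the expected count 2*EAF (in-sample).
    """
    if len(weights) == 0:
        raise ValidationError("empty variant set: no score to compute")
    col_of = {v: j for j, v in enumerate(genotypes.variants["id"])}
    missing = [v for v in weights["id"] if v not in col_of]
    if missing:
        raise ValidationError(f"weights for variants absent from target: {missing[:5]}")
    cols = np.array([col_of[v] for v in weights["id"]])
    d = genotypes.dosages[:, cols].astype(np.float64)
    eaf = np.nanmean(d, axis=0) / 2.0
    idx = np.where(np.isnan(d))
    d[idx] = 2.0 * eaf[idx[1]]
    w = weights["weight"].to_numpy(dtype=float)
    return pd.Series(d @ w / len(w), index=genotypes.samples, name="score")


@dataclass
class ScoreResult:
    """Scores plus the full/null pseudo-R² evaluation of one comparison."""

    scores: pd.Series
    r2_full: float
    r2_null: float
    r2_final: float
    p_assoc: float
    n_variants_used: int
    converged: bool = True

    @property
    def scores_std(self) -> pd.Series:
        s = self.scores
        sd = s.std(ddof=0)
        return (s - s.mean()) / sd if sd > 0 else s - s.mean()


def _nagelkerke_from_ll(ll_model: float, ll_null: float, n: int) -> float:
    """Nagelkerke pseudo-R² of a model against the intercept-only fit:
    R2_CS = 1 - exp(2*(ll0 - ll)/n), rescaled by its maximum 1 - exp(2*ll0/n)."""
    r2_cs = 1.0 - np.exp(2.0 * (ll_null - ll_model) / n)
    denom = 1.0 - np.exp(2.0 * ll_null / n)
    return float(r2_cs / denom) if denom > 0 else 0.0


def nagelkerke_r2(
    phenotype: pd.Series,
    score: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> ScoreResult:
    """Evaluate a score by full-vs-null logistic regression.

    Fits phenotype ~ score + covariates (full) and phenotype ~ covariates
    (null); each model's Nagelkerke pseudo-R² is computed against the
    intercept-only likelihood and r2_final is their difference.  The
    association p is the Wald p of the score term in the full model.
    """
    y = phenotype.to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("phenotype is constant")
    s = score.loc[phenotype.index].to_numpy(dtype=float)
    n = len(y)
    c = (
        covariates.loc[phenotype.index].to_numpy(dtype=float)
        if covariates is not None and covariates.shape[1] > 0
        else np.zeros((n, 0))
    )
    pbar = y.mean()
    ll0 = n * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar))

    if np.ptp(s) == 0:
        x_null = sm.add_constant(c, has_constant="add")
        fit_null = sm.Logit(y, x_null).fit(disp=0, method="newton", maxiter=100)
        r2_null = _nagelkerke_from_ll(fit_null.llf, ll0, n)
        return ScoreResult(score, r2_null, r2_null, 0.0, np.nan, 0)

    x_full = sm.add_constant(np.column_stack([s, c]), has_constant="add")
    x_null = sm.add_constant(c, has_constant="add")
    converged = True
    try:
        fit_full = sm.Logit(y, x_full).fit(disp=0, method="newton", maxiter=100)
        fit_null = sm.Logit(y, x_null).fit(disp=0, method="newton", maxiter=100)
        converged = bool(fit_full.mle_retvals["converged"]
                         and fit_null.mle_retvals["converged"])
    except Exception:
        return ScoreResult(score, np.nan, np.nan, np.nan, np.nan, 0, converged=False)
    r2_full = _nagelkerke_from_ll(fit_full.llf, ll0, n)
    r2_null = _nagelkerke_from_ll(fit_null.llf, ll0, n)
    return ScoreResult(
        scores=score,
        r2_full=r2_full,
        r2_null=r2_null,
        r2_final=r2_full - r2_null,
        p_assoc=float(fit_full.pvalues[1]),
        n_variants_used=0,
        converged=converged,
    )


def _binary_phenotype(
    phenotypes: PhenotypeTable, case_group: str, control_group: str,
    genotypes: GenotypeDataset,
) -> pd.Series:
    present = set(genotypes.samples)
    cases = [s for s in phenotypes.group(case_group) if s in present]
    controls = [s for s in phenotypes.group(control_group) if s in present]
    if not cases or not controls:
        raise ValidationError(
            f"empty group in comparison {case_group} vs {control_group}"
        )
    return pd.Series(
        np.concatenate([np.ones(len(cases)), np.zeros(len(controls))]),
        index=cases + controls,
    )


def prs_analysis(
    weights: pd.DataFrame,
    genotypes: GenotypeDataset,
    phenotypes: PhenotypeTable,
    case_group: str,
    control_group: str,
    n_covariates: int | None = None,
) -> ScoreResult:
    """Match alleles, score every sample and evaluate one group comparison."""
    matched, _ = match_alleles(weights, genotypes)
    if len(matched) == 0:
        raise ValidationError("no variants left after allele matching")
    scores = score_samples(matched, genotypes)
    y = _binary_phenotype(phenotypes, case_group, control_group, genotypes)
    cov_cols = phenotypes.covariate_columns()
    if n_covariates is not None:
        cov_cols = cov_cols[:n_covariates]
    covars = phenotypes.table.loc[y.index, cov_cols].astype(float) if cov_cols else None
    res = nagelkerke_r2(y, scores, covars)
    res.n_variants_used = len(matched)
    return res


def threshold_sweep(
    base_sumstats: SummaryStatsTable,
    genotypes: GenotypeDataset,
    phenotypes: PhenotypeTable,
    case_group: str,
    control_group: str,
    thresholds: tuple = (5e-8, 0.001, 0.005, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 1.0),
    r2_max: float = 0.1,
    window_kb: float = 250.0,
) -> pd.DataFrame:
    """Cumulative-threshold polygenic scoring.

    Clumping runs once on the full base/target intersection; at each
    threshold P_t the clumped set is restricted to base p < P_t, scored and
    regressed.  Returns a table of (P_t, n_variants, r2_final, p_assoc).
    """
    clumped = clump(base_sumstats, genotypes, r2_max=r2_max, window_kb=window_kb)
    matched, _ = match_alleles(clumped, genotypes)
    rows = []
    for p_t in sorted(thresholds):
        sub = matched[matched["p"] < p_t]
        if len(sub) == 0:
            rows.append((p_t, 0, np.nan, np.nan))
            continue
        scores = score_samples(sub, genotypes)
        y = _binary_phenotype(phenotypes, case_group, control_group, genotypes)
        cov_cols = phenotypes.covariate_columns()
        covars = (
            phenotypes.table.loc[y.index, cov_cols].astype(float) if cov_cols else None
        )
        res = nagelkerke_r2(y, scores, covars)
        rows.append((p_t, len(sub), res.r2_final, res.p_assoc))
    return pd.DataFrame(rows, columns=["p_t", "n_variants", "r2_final", "p_assoc"])


def downsample_analysis(
    weights: pd.DataFrame,
    genotypes: GenotypeDataset,
    phenotypes: PhenotypeTable,
    case_group: str,
    control_group: str,
    n_per_group: int = 500,
    reps: int = 5000,
    seed: int = 0,
) -> dict:
    """Repeatedly down-sample both groups to ``n_per_group`` and average the
    pseudo-R² and association p over replicates."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    matched, _ = match_alleles(weights, genotypes)
    scores = score_samples(matched, genotypes)
    present = set(genotypes.samples)
    groups = {}
    for label in (case_group, control_group):
        members = [s for s in phenotypes.group(label) if s in present]
        if len(members) < n_per_group:
            raise ValidationError(
                f"group {label} has {len(members)} samples < n_per_group={n_per_group}"
            )
        groups[label] = np.array(members)
    cov_cols = phenotypes.covariate_columns()
    r2s, ps = [], []
    for _ in range(reps):
        cases = rng.choice(groups[case_group], size=n_per_group, replace=False)
        controls = rng.choice(groups[control_group], size=n_per_group, replace=False)
        idx = np.concatenate([cases, controls])
        y = pd.Series(np.r_[np.ones(n_per_group), np.zeros(n_per_group)], index=idx)
        covars = (
            phenotypes.table.loc[idx, cov_cols].astype(float) if cov_cols else None
        )
        res = nagelkerke_r2(y, scores, covars)
        r2s.append(res.r2_final)
        ps.append(res.p_assoc)
    return {
        "mean_r2_final": float(np.mean(r2s)),
        "mean_p": float(np.mean(ps)),
        "sd_r2_final": float(np.std(r2s, ddof=1)) if reps > 1 else 0.0,
        "reps": reps,
        "n_per_group": n_per_group,
        "n_variants_used": len(matched),
    }
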