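"""Sample and variant quality control, relatedness and MDS ancestry components.

Filter order follows the study protocol: sample call rate, heterozygosity
outliers (recomputed on survivors), one member of each related pair
(pi_hat > 0.2), MDS outliers on the first two components, then variant
filters (call rate, Hardy-Weinberg exact test, imputation info, MAF).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import gammaln

from .datatypes import GenotypeDataset, RunConfig, ValidationError

_MIN_JOINT_VARIANTS = 100


@dataclass
class QCReport:
    """Removed samples/variants with reason codes, plus the thresholds used."""

    removed_samples: list = field(default_factory=list)   # (id, reason)
    removed_variants: list = field(default_factory=list)  # (id, (reasons, ...))
    kept_samples: list = field(default_factory=list)
    kept_variants: list = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def sample_reasons(self) -> dict:
        return dict(self.removed_samples)

    def variant_reasons(self) -> dict:
        return dict(self.removed_variants)


@dataclass(frozen=True)
class RelatednessEstimate:
    """Method-of-moments IBD sharing for one sample pair."""

    pair: tuple
    pihat: float


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditions on the allele counts and sums the probabilities of all
    heterozygote counts whose probability does not exceed that of the
    observed count.  Returns a value in (0, 1].
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValidationError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValidationError("all genotype counts are zero")
    n_a = 2 * n_aa + n_Aa  # minor-allele count by convention below
    n_A = 2 * n_AA + n_Aa
    rare = min(n_A, n_a)
    # possible het counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = (n - hets - homr)
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1) - gammaln(hets + 1) - gammaln(homr + 1) - gammaln(homc + 1)
        + gammaln(n_A + 1) + gammaln(n_a + 1) - gammaln(2 * n + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[hets == n_Aa][0]
    return float(min(1.0, prob[prob <= obs * (1.0 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# Identity-by-state / identity-by-descent machinery


def _indicator_stacks(genotypes: GenotypeDataset):
    g = genotypes.hard_genotypes()
    a0 = (g == 0).astype(np.float32)
    a1 = (g == 1).astype(np.float32)
    a2 = (g == 2).astype(np.float32)
    mask = (g >= 0).astype(np.float32)
    return a0, a1, a2, mask


def _expectation_terms(p: np.ndarray):
    q = 1.0 - p
    e0 = 2.0 * p**2 * q**2
    e1_ibd0 = 4.0 * p**3 * q + 4.0 * p * q**3
    e2_ibd0 = p**4 + q**4 + 4.0 * p**2 * q**2
    e1_ibd1 = 2.0 * p * q
    e2_ibd1 = p**2 + q**2
    return e0, e1_ibd0, e2_ibd0, e1_ibd1, e2_ibd1


def pihat_matrix(genotypes: GenotypeDataset) -> np.ndarray:
    """All-pairs pi_hat (proportion IBD) via the method-of-moments estimator.

    IBS sharing counts are compared with their expectations under the
    in-sample allele frequencies, restricted per pair to jointly observed
    variants.  Pairs with fewer than 100 jointly observed variants get NaN.
    """
    a0, a1, a2, mask = _indicator_stacks(genotypes)
    nonmiss = mask.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (a1.sum(axis=0) + 2.0 * a2.sum(axis=0)) / (2.0 * nonmiss)
    p = np.clip(np.where(np.isfinite(p), p, 0.5), 1e-6, 1 - 1e-6).astype(np.float32)

    ibs0 = a0 @ a2.T + a2 @ a0.T
    a02 = a0 + a2
    ibs1 = a1 @ a02.T + a02 @ a1.T
    ibs2 = a0 @ a0.T + a1 @ a1.T + a2 @ a2.T
    n_joint = mask @ mask.T

    e0, e1_0, e2_0, e1_1, e2_1 = _expectation_terms(p.astype(np.float64))

    def pairsum(term: np.ndarray) -> np.ndarray:
        w = (mask * term.astype(np.float32)[None, :])
        return w @ mask.T

    E0 = pairsum(e0)
    E1_0 = pairsum(e1_0)
    E2_0 = pairsum(e2_0)
    E1_1 = pairsum(e1_1)
    E2_1 = pairsum(e2_1)

    # the IBD-state chain is left unclamped (clamping the intermediate
    # proportions biases pi_hat upward); only the final estimate is bounded
    with np.errstate(invalid="ignore", divide="ignore"):
        p0 = ibs0 / E0
        p1 = (ibs1 - p0 * E1_0) / E1_1
        p2 = (ibs2 - p0 * E2_0 - p1 * E2_1) / n_joint
        out = np.clip(p2 + 0.5 * p1, 0.0, 1.0)
    out = np.asarray(out, dtype=np.float64)
    out[n_joint < _MIN_JOINT_VARIANTS] = np.nan
    return out


def pihat(genotypes: GenotypeDataset, pair: tuple) -> RelatednessEstimate:
    """pi_hat for one sample pair (allele frequencies from the whole dataset)."""
    s1, s2 = pair
    for s in pair:
        if s not in genotypes.samples:
            raise KeyError(f"unknown sample {s!r}")
    i, j = genotypes.samples.index(s1), genotypes.samples.index(s2)
    g = genotypes.hard_genotypes()
    joint = (g[i] >= 0) & (g[j] >= 0)
    if joint.sum() < _MIN_JOINT_VARIANTS:
        raise ValidationError(
            f"only {int(joint.sum())} jointly observed variants for pair {pair}; "
            f"need >= {_MIN_JOINT_VARIANTS}"
        )
    # frequencies from the full dataset, sharing from the pair
    value = pihat_matrix_for_pair(genotypes, i, j, joint)
    return RelatednessEstimate((s1, s2), value)


def pihat_matrix_for_pair(
    genotypes: GenotypeDataset, i: int, j: int, joint: np.ndarray
) -> float:
    g = genotypes.hard_genotypes()
    nonmiss = (g >= 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = ((g == 1).sum(axis=0) + 2.0 * (g == 2).sum(axis=0)) / (2.0 * nonmiss)
    p = np.clip(np.where(np.isfinite(p), p, 0.5), 1e-6, 1 - 1e-6)
    gi, gj = g[i][joint].astype(int), g[j][joint].astype(int)
    ibs = 2 - np.abs(gi - gj)
    ibs0 = float((ibs == 0).sum())
    ibs1 = float((ibs == 1).sum())
    ibs2 = float((ibs == 2).sum())
    e0, e1_0, e2_0, e1_1, e2_1 = (t[joint].sum() for t in _expectation_terms(p))
    p0 = ibs0 / e0
    p1 = (ibs1 - p0 * e1_0) / e1_1
    p2 = (ibs2 - p0 * e2_0 - p1 * e2_1) / joint.sum()
    return float(np.clip(p2 + 0.5 * p1, 0.0, 1.0))


def ld_prune_for_ibd(
    genotypes: GenotypeDataset, r2_max: float = 0.1, window_kb: float = 250.0
) -> np.ndarray:
    """Boolean mask of a quasi-independent variant subset for IBD estimation.

    Greedy along each chromosome in position order: a variant is kept when
    its r² with every already-kept variant inside the window is <= r2_max.
    Relatedness thresholding needs approximately independent markers;
    estimating pi_hat on raw LD-correlated variants inflates its variance.
    """
    from .prs import _pairwise_r2

    v = genotypes.variants
    chrom = v["chrom"].to_numpy()
    pos = v["pos"].to_numpy()
    d = genotypes.dosages.astype(np.float64)
    keep = np.zeros(len(v), dtype=bool)
    window = window_kb * 1000.0
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        idx = idx[np.argsort(pos[idx], kind="mergesort")]
        kept_here: list = []
        for j in idx:
            near = [k for k in kept_here if abs(pos[k] - pos[j]) <= window]
            if near and (_pairwise_r2(d, j, np.array(near)) > r2_max).any():
                continue
            kept_here.append(j)
            keep[j] = True
    return keep


# ---------------------------------------------------------------------------
# Sample QC


def heterozygosity_rate(genotypes: GenotypeDataset) -> np.ndarray:
    """Observed per-sample het-call fraction over non-missing genotypes."""
    g = genotypes.hard_genotypes()
    nonmiss = (g >= 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(nonmiss > 0, (g == 1).sum(axis=1) / nonmiss, np.nan)


def sample_qc(
    genotypes: GenotypeDataset,
    call_rate_min: float = 0.90,
    het_sd: float = 3.0,
    pihat_max: float = 0.2,
) -> QCReport:
    """Remove low-call-rate samples, heterozygosity outliers and one member
    of each related pair, in that order."""
    if genotypes.n_samples < 2:
        raise ValidationError("sample QC needs >= 2 samples")
    report = QCReport(thresholds={"call_rate_min": call_rate_min,
                                  "het_sd": het_sd, "pihat_max": pihat_max})
    samples = np.array(genotypes.samples)
    call_rate = genotypes.sample_call_rate()

    keep = call_rate >= call_rate_min
    for s in samples[~keep]:
        report.removed_samples.append((s, "low_call_rate"))

    surv = genotypes.subset(samples=list(samples[keep]))
    het = heterozygosity_rate(surv)
    mu, sd = float(np.nanmean(het)), float(np.nanstd(het))
    het_out = np.abs(het - mu) > het_sd * sd if sd > 0 else np.zeros(len(het), bool)
    for s in np.array(surv.samples)[het_out]:
        report.removed_samples.append((s, "het_outlier"))

    surv = surv.subset(samples=list(np.array(surv.samples)[~het_out]))
    pm = pihat_matrix(surv.subset(variant_mask=ld_prune_for_ibd(surv)))
    cr = dict(zip(surv.samples, surv.sample_call_rate()))
    alive = dict.fromkeys(surv.samples, True)
    hit = np.triu(np.isfinite(pm) & (pm > pihat_max), k=1)
    pairs = [
        (surv.samples[i], surv.samples[j]) for i, j in zip(*np.nonzero(hit))
    ]
    for s1, s2 in sorted(pairs):
        if alive[s1] and alive[s2]:
            if cr[s1] < cr[s2]:
                drop = s1
            elif cr[s2] < cr[s1]:
                drop = s2
            else:
                drop = max(s1, s2)  # tie: drop the lexicographically later id
            alive[drop] = False
            report.removed_samples.append((drop, "related"))

    report.kept_samples = [s for s in genotypes.samples
                           if s not in report.sample_reasons()]
    if not report.kept_samples:
        raise ValidationError("sample QC removed every sample")
    return report


# ---------------------------------------------------------------------------
# Variant QC


def variant_qc(
    genotypes: GenotypeDataset,
    call_rate_min: float = 0.98,
    hwe_p_min: float = 1e-4,
    info_min: float = 0.4,
    maf_min: float = 0.01,
) -> QCReport:
    """Remove variants failing ANY of call rate, HWE, info or MAF filters;
    every violated reason is recorded."""
    report = QCReport(thresholds={"call_rate_min": call_rate_min,
                                  "hwe_p_min": hwe_p_min,
                                  "info_min": info_min, "maf_min": maf_min})
    cr = genotypes.variant_call_rate()
    maf = genotypes.maf_observed()
    g = genotypes.hard_genotypes()
    info = genotypes.variants["info"].to_numpy(dtype=float)
    for j, vid in enumerate(genotypes.variants["id"]):
        reasons = []
        if cr[j] < call_rate_min:
            reasons.append("low_call_rate")
        col = g[:, j]
        n_aa = int((col == 0).sum())
        n_ab = int((col == 1).sum())
        n_bb = int((col == 2).sum())
        if n_aa + n_ab + n_bb > 0 and hwe_exact_p(n_aa, n_ab, n_bb) < hwe_p_min:
            reasons.append("hwe_fail")
        if np.isfinite(info[j]) and info[j] < info_min:
            reasons.append("low_info")
        if not (maf[j] >= maf_min):
            reasons.append("low_maf")
        if reasons:
            report.removed_variants.append((vid, tuple(reasons)))
    removed = report.variant_reasons()
    report.kept_variants = [v for v in genotypes.variants["id"] if v not in removed]
    return report


# ---------------------------------------------------------------------------
# Classical MDS on 1 - IBS distances


def ibs_distance_matrix(genotypes: GenotypeDataset) -> np.ndarray:
    """Pairwise 1 - mean IBS similarity over jointly observed variants."""
    a0, a1, a2, mask = _indicator_stacks(genotypes)
    a02 = a0 + a2
    ibs1 = a1 @ a02.T + a02 @ a1.T
    ibs2 = a0 @ a0.T + a1 @ a1.T + a2 @ a2.T
    n_joint = mask @ mask.T
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = (ibs2 + 0.5 * ibs1) / n_joint
    d = 1.0 - np.asarray(sim, dtype=np.float64)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 1.0)


def classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson MDS of a distance matrix: double-centred squared-distance
    eigendecomposition, top-k coordinates scaled by sqrt(eigenvalue),
    ordered by eigenvalue and sign-fixed (largest-magnitude loading
    positive)."""
    n = d.shape[0]
    if k > n - 1:
        raise ValidationError(f"k={k} exceeds n-1={n - 1}")
    d2 = np.asarray(d, dtype=np.float64) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0
    vals, vecs = linalg.eigh(b, subset_by_index=[n - k, n - 1])
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = vecs * np.sqrt(np.clip(vals, 0.0, None))[None, :]
    for c in range(k):
        if coords[np.argmax(np.abs(coords[:, c])), c] < 0:
            coords[:, c] *= -1.0
    return coords


def mds_components(genotypes: GenotypeDataset, k: int = 10) -> pd.DataFrame:
    """Classical MDS of the 1 - IBS distance matrix (ancestry components)."""
    d = ibs_distance_matrix(genotypes)
    if np.allclose(d, 0.0):
        raise ValidationError("degenerate distance matrix: all samples identical")
    coords = classical_mds(d, k)
    return pd.DataFrame(coords, index=genotypes.samples,
                        columns=[f"C{i}" for i in range(1, k + 1)])


def mds_outlier_filter(
    components: pd.DataFrame, sd: float = 3.0, dims: int = 2
) -> list:
    """Flag samples beyond ``sd`` standard deviations on any of the first
    ``dims`` components; returns (sample, "mds_outlier") entries."""
    flagged = []
    if not np.isfinite(sd):
        return flagged
    cols = list(components.columns[:dims])
    z = (components[cols] - components[cols].mean()) / components[cols].std(ddof=0)
    out = (z.abs() > sd).any(axis=1)
    for s in components.index[out]:
        flagged.append((s, "mds_outlier"))
    return flagged


# ---------------------------------------------------------------------------
# Orchestrated QC (the order used by the pipeline)


def run_qc(genotypes: GenotypeDataset, cfg: RunConfig | None = None):
    """Full QC pass: sample filters, MDS outliers, variant filters.

    Returns (clean dataset, MDS components of the survivors, QCReport).
    """
    cfg = cfg or RunConfig()
    srep = sample_qc(genotypes, cfg.sample_call_rate_min, cfg.het_sd, cfg.pihat_max)
    ds = genotypes.subset(samples=srep.kept_samples)
    comps = mds_components(ds, k=cfg.mds_k)
    out = mds_outlier_filter(comps, sd=cfg.mds_outlier_sd)
    srep.removed_samples.extend(out)
    srep.kept_samples = [s for s in srep.kept_samples
                         if s not in dict(out)]
    ds = ds.subset(samples=srep.kept_samples)
    comps = comps.loc[srep.kept_samples]
    vrep = variant_qc(ds, cfg.variant_call_rate_min, cfg.hwe_p_min,
                      cfg.info_min, cfg.maf_min)
    keep_mask = ds.variants["id"].isin(vrep.kept_variants).to_numpy()
    ds = ds.subset(variant_mask=keep_mask)
    report = QCReport(
        removed_samples=srep.removed_samples,
        removed_variants=vrep.removed_variants,
        kept_samples=srep.kept_samples,
        kept_variants=vrep.kept_variants,
        thresholds={**srep.thresholds, **vrep.thresholds,
                    "mds_outlier_sd": cfg.mds_outlier_sd},
    )
    return ds, comps, report
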