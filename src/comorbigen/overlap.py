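"""Excess of shared association signals between two GWAS.

All variants present in both studies are LD-pruned (p-value informed,
r² > 0.1 removed) to an approximately independent set; at each cumulative
threshold P_t a 2x2 table counts variants below/above P_t in each study;
a Pearson chi-square tests for excess concordance, and an empirical p-value
is obtained by permuting one study's p-values against the other.

Permutation note: at a fixed threshold, shuffling study-2 p-values leaves
both marginal counts unchanged, so the permuted concordant count ``a`` is
exactly hypergeometric.  ``permutation_pvalue`` therefore draws ``a`` from
that distribution B times (seeded), which reproduces the shuffle
distribution without materialising index permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeDataset, SummaryStatsTable, ValidationError

from .prs import _pairwise_r2

DEFAULT_OVERLAP_THRESHOLDS = (0.5, 0.1, 0.05, 0.04, 0.03, 0.02, 0.01, 0.005, 0.001, 5e-4)


@dataclass
class OverlapThresholdResult:
    """Shared-signal test at one cumulative threshold P_t."""

    p_t: float
    n_overlap: int  # variants below P_t in BOTH studies (= a)
    a: int
    b: int
    c: int
    d: int
    chi2: float
    p_asymptotic: float
    p_perm: float
    permutations: int


# ---------------------------------------------------------------------------
# Pruning


def prune_by_pvalue(
    sumstats1: SummaryStatsTable,
    sumstats2: SummaryStatsTable,
    ld_reference: GenotypeDataset,
    r2_max: float = 0.1,
    window_kb: float = 250.0,
    rank: str = "study1",
) -> pd.DataFrame:
    """P-value-informed LD pruning of the two studies' shared variants.

    Variants are ranked by ``rank`` in {"min", "study1", "study2"}.  The
    default priority is study 1's p-value: ranking by min(p1, p2) makes
    retention depend on both studies jointly, which induces a selection
    (Berkson) dependence between the two p-value columns of the retained
    set that the within-set permutation null cannot reproduce; ranking by
    one study keeps the other study's p-values exactly independent of
    retention under trait independence.  The
    greedy rule retains the best-ranked unclaimed variant and discards
    unclaimed variants within the window at r² > ``r2_max`` to it.
    Returns a frame with columns id, chrom, pos, p1, p2.
    """
    t1 = sumstats1.table.set_index("id")
    t2 = sumstats2.table.set_index("id")
    ref_ids = set(ld_reference.variants["id"])
    shared = [v for v in t1.index if v in t2.index and v in ref_ids]
    if not shared:
        raise ValidationError("empty intersection of variant ids")
    p1 = t1.loc[shared, "p"].to_numpy(dtype=float)
    p2 = t2.loc[shared, "p"].to_numpy(dtype=float)
    if rank == "min":
        key = np.minimum(p1, p2)
    elif rank == "study1":
        key = p1
    elif rank == "study2":
        key = p2
    else:
        raise ValidationError(f"unknown rank rule {rank!r}")

    col_of = {v: j for j, v in enumerate(ld_reference.variants["id"])}
    cols = np.array([col_of[v] for v in shared])
    chrom = ld_reference.variants["chrom"].to_numpy()[cols]
    pos = ld_reference.variants["pos"].to_numpy()[cols]
    order = np.lexsort((np.array(shared), key))  # p rank, ties by id
    window = window_kb * 1000.0
    unclaimed = np.ones(len(shared), dtype=bool)
    kept = []
    d = ld_reference.dosages.astype(np.float64)
    for i in order:
        if not unclaimed[i]:
            continue
        unclaimed[i] = False
        kept.append(i)
        near = unclaimed & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window)
        near_idx = np.flatnonzero(near)
        if len(near_idx):
            r2 = _pairwise_r2(d, cols[i], cols[near_idx])
            unclaimed[near_idx[r2 > r2_max]] = False
    kept = np.array(kept)
    return pd.DataFrame(
        {
            "id": np.array(shared)[kept],
            "chrom": chrom[kept],
            "pos": pos[kept],
            "p1": p1[kept],
            "p2": p2[kept],
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Contingency machinery


def contingency_at_threshold(pruned: pd.DataFrame, p_t: float) -> tuple:
    """2x2 counts (a, b, c, d) at a cumulative threshold.

    a = both studies below P_t (strict <); b = study 1 only; c = study 2
    only; d = neither.
    """
    if not (0 < p_t <= 1):
        raise ValidationError(f"P_t={p_t} outside (0, 1]")
    lo1 = pruned["p1"].to_numpy() < p_t
    lo2 = pruned["p2"].to_numpy() < p_t
    a = int((lo1 & lo2).sum())
    b = int((lo1 & ~lo2).sum())
    c = int((~lo1 & lo2).sum())
    d = int((~lo1 & ~lo2).sum())
    return a, b, c, d


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple:
    """Pearson chi-square (no continuity correction) and its 1-df tail p.

    chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); requires all marginals
    positive.
    """
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) <= 0:
        raise ValidationError("chi-square undefined: zero marginal")
    chi2 = n * (a * d - b * c) ** 2 / float(r1) / float(r2) / float(c1) / float(c2)
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def _chi2_from_a(a: np.ndarray, r1: int, r2: int, n: int) -> np.ndarray:
    """Vectorized chi-square over concordant counts with fixed marginals."""
    a = a.astype(np.float64)
    b = r1 - a
    c = r2 - a
    d = n - r1 - r2 + a
    denom = float(r1) * float(n - r1) * float(r2) * float(n - r2)
    if denom == 0:
        return np.zeros_like(a)
    return n * (a * d - b * c) ** 2 / denom


def permutation_pvalue(
    pruned: pd.DataFrame,
    p_t: float,
    B: int = 1_000_000,
    seed: int = 0,
    estimator: str = "proportion",
) -> float:
    """Empirical overlap p-value by permuting one study's p-values.

    Each permutation shuffles study-2 p-values against study-1, rebuilds
    the table at ``p_t`` and recomputes the chi-square (tables with a zero
    marginal contribute 0).  The reported value is the plain proportion of
    permuted statistics >= the observed one, so exact zeros are reportable;
    ``estimator="add_one"`` gives (r+1)/(B+1) instead.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    a, b, c, d = contingency_at_threshold(pruned, p_t)
    n = a + b + c + d
    r1, r2 = a + b, a + c
    if min(r1, n - r1, r2, n - r2) <= 0:
        chi2_obs = 0.0
    else:
        chi2_obs, _ = chi2_2x2(a, b, c, d)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    # a under a random shuffle is hypergeometric with both marginals fixed
    a_perm = rng.hypergeometric(ngood=r2, nbad=n - r2, nsample=r1, size=B)
    chi2_perm = _chi2_from_a(a_perm, r1, r2, n)
    exceed = int((chi2_perm >= chi2_obs).sum())
    if estimator == "proportion":
        return exceed / B
    if estimator == "add_one":
        return (exceed + 1) / (B + 1)
    raise ValidationError(f"unknown estimator {estimator!r}")


def overlap_analysis(
    sumstats1: SummaryStatsTable,
    sumstats2: SummaryStatsTable,
    ld_reference: GenotypeDataset,
    thresholds: tuple = DEFAULT_OVERLAP_THRESHOLDS,
    r2_max: float = 0.1,
    window_kb: float = 250.0,
    B: int = 1_000_000,
    seed: int = 0,
    rank: str = "study1",
) -> list:
    """Full shared-signal analysis: prune once, test every threshold."""
    pruned = prune_by_pvalue(sumstats1, sumstats2, ld_reference,
                             r2_max=r2_max, window_kb=window_kb, rank=rank)
    results = []
    for p_t in thresholds:
        a, b, c, d = contingency_at_threshold(pruned, p_t)
        try:
            chi2, p_asym = chi2_2x2(a, b, c, d)
        except ValidationError:
            chi2, p_asym = np.nan, np.nan
        p_perm = permutation_pvalue(pruned, p_t, B=B, seed=seed)
        results.append(
            OverlapThresholdResult(p_t, a, a, b, c, d, chi2, p_asym, p_perm, B)
        )
    return results


def overlap_results_frame(results: list) -> pd.DataFrame:
    """Tabulate threshold results (columns mirror the study's overlap table)."""
    return pd.DataFrame(
        [
            {
                "P_t": r.p_t, "variants": r.n_overlap, "chi2": r.chi2,
                "P": r.p_asymptotic, "P_perm": r.p_perm,
                "a": r.a, "b": r.b, "c": r.c, "d": r.d, "B": r.permutations,
            }
            for r in results
        ]
    )
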