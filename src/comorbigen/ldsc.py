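"""LD scores from a reference panel and cross-trait LD-score regression.

The LD score of variant j is the sum of bias-adjusted squared correlations
to variants within a window, l_j = sum_k r2_adj(j,k) with
r2_adj = r2 - (1 - r2)/(n - 2) (including k = j, which contributes 1).
Regressing per-variant chi-square statistics on l_j estimates the
observed-scale SNP heritability of each trait (slope = N h2 / M); the
cross-trait regression of z1*z2 on l_j estimates the genetic covariance
(slope = sqrt(N1 N2) rho_g / M) with a free intercept that absorbs sample
overlap.  Standard errors come from a delete-one block jackknife over
contiguous variant blocks.

Weights: inverse of max(l_j, 1), a simple heteroskedasticity proxy (no
iterative reweighting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeDataset, SummaryStatsTable, ValidationError


@dataclass
class LDScoreTable:
    """Per-variant LD scores, aligned with a variant metadata frame."""

    table: pd.DataFrame  # columns id, chrom, pos, l


@dataclass
class RgEstimate:
    """Cross-trait LD-score regression estimates.

    ``rg`` = rho_g / sqrt(h2_1 * h2_2); it is reported even when outside
    [-1, 1] (estimation noise) and ``out_of_range`` flags that case.
    """

    h2_1: float
    h2_2: float
    rho_g: float
    rg: float
    intercept1: float
    intercept2: float
    cross_intercept: float
    rg_se: float
    p_value: float
    n_variants: int
    n_blocks: int

    @property
    def out_of_range(self) -> bool:
        return bool(np.isnan(self.rg) or abs(self.rg) > 1)


def ld_scores(reference: GenotypeDataset, window_kb: float = 1000.0) -> LDScoreTable:
    """Window-based LD scores from a reference genotype panel (>= 50 samples)."""
    n = reference.n_samples
    if n < 50:
        raise ValidationError(f"reference panel has {n} samples; need >= 50")
    d = reference.imputed_dosages()
    sd = d.std(axis=0)
    sd[sd == 0] = 1.0
    z = (d - d.mean(axis=0)) / sd
    m = reference.n_variants
    chrom = reference.variants["chrom"].to_numpy()
    pos = reference.variants["pos"].to_numpy()
    window = window_kb * 1000.0
    ell = np.zeros(m)
    any_neighbour = False
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        zc = z[:, idx]
        r = (zc.T @ zc) / n
        r2 = r**2
        r2_adj = r2 - (1.0 - r2) / (n - 2)
        inwin = np.abs(pos[idx][:, None] - pos[idx][None, :]) <= window
        if inwin.sum() > len(idx):
            any_neighbour = True
        ell[idx] = (r2_adj * inwin).sum(axis=1)
    if not any_neighbour:
        warnings.warn("window smaller than all inter-variant spacings: "
                      "LD scores reduce to the self term", stacklevel=2)
    return LDScoreTable(
        pd.DataFrame({"id": reference.variants["id"], "chrom": chrom,
                      "pos": pos, "l": ell})
    )


def _wls_slope_intercept(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple:
    """Weighted least squares of y on [1, x]; returns (intercept, slope)."""
    sw = w.sum()
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    if sxx <= 1e-12 * sw * max(xm * xm, 1.0):
        raise ValidationError("degenerate design: constant LD score")
    slope = (w * (x - xm) * (y - ym)).sum() / sxx
    return ym - slope * xm, slope


def _estimate(
    ell: np.ndarray, chi1: np.ndarray, chi2: np.ndarray, zz: np.ndarray,
    w: np.ndarray, n1: float, n2: float, m_total: int,
) -> tuple:
    i1, s1 = _wls_slope_intercept(ell, chi1, w)
    i2, s2 = _wls_slope_intercept(ell, chi2, w)
    ix, sx = _wls_slope_intercept(ell, zz, w)
    h2_1 = s1 * m_total / n1
    h2_2 = s2 * m_total / n2
    rho_g = sx * m_total / np.sqrt(n1 * n2)
    denom = h2_1 * h2_2
    rg = rho_g / np.sqrt(denom) if denom > 0 else np.nan
    return h2_1, h2_2, rho_g, rg, i1, i2, ix


def rg_regression(
    sumstats1: SummaryStatsTable,
    sumstats2: SummaryStatsTable,
    ld: LDScoreTable,
    n_blocks: int = 200,
) -> RgEstimate:
    """Genome-wide genetic correlation between two traits.

    Merges the two studies and the LD scores on variant id, fits the three
    weighted regressions, and jackknifes rg over ``n_blocks`` contiguous
    variant blocks.  Requires at least 10 * n_blocks shared variants.
    """
    t1 = sumstats1.table.set_index("id")
    t2 = sumstats2.table.set_index("id")
    lt = ld.table.set_index("id")
    shared = [v for v in lt.index if v in t1.index and v in t2.index]
    m_total = len(shared)
    if m_total < 10 * n_blocks:
        raise ValidationError(
            f"{m_total} shared variants < 10 * n_blocks = {10 * n_blocks}"
        )
    sub = lt.loc[shared].sort_values(["chrom", "pos"])
    order = list(sub.index)
    ell = sub["l"].to_numpy(dtype=float)
    z1 = (t1.loc[order, "beta"] / t1.loc[order, "se"]).to_numpy(dtype=float)
    z2 = (t2.loc[order, "beta"] / t2.loc[order, "se"]).to_numpy(dtype=float)
    n1 = float(t1.loc[order, "n"].mean())
    n2 = float(t2.loc[order, "n"].mean())
    chi1 = z1**2
    chi2 = z2**2
    zz = z1 * z2
    w = 1.0 / np.maximum(ell, 1.0)

    full = _estimate(ell, chi1, chi2, zz, w, n1, n2, m_total)
    h2_1, h2_2, rho_g, rg, i1, i2, ix = full

    # delete-one block jackknife over contiguous variant blocks
    bounds = np.linspace(0, m_total, n_blocks + 1).astype(int)
    reps = []
    for g in range(n_blocks):
        keep = np.ones(m_total, dtype=bool)
        keep[bounds[g] : bounds[g + 1]] = False
        rep = _estimate(ell[keep], chi1[keep], chi2[keep], zz[keep], w[keep],
                        n1, n2, m_total)
        reps.append(rep[3])
    reps = np.asarray(reps, dtype=float)
    finite = reps[np.isfinite(reps)]
    g = len(finite)
    if g >= 2:
        rg_se = float(np.sqrt((g - 1) / g * ((finite - finite.mean()) ** 2).sum()))
    else:
        rg_se = np.nan
    p = (
        float(2.0 * stats.norm.sf(abs(rg) / rg_se))
        if np.isfinite(rg) and rg_se and rg_se > 0
        else np.nan
    )
    return RgEstimate(h2_1, h2_2, rho_g, rg, i1, i2, ix, rg_se, p,
                      m_total, n_blocks)


def simulate_ldsc_zscores(
    ell: np.ndarray,
    h2_1: float,
    h2_2: float,
    rg: float,
    n1: float,
    n2: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw z-score pairs from the LD-score regression generative model.

    Per variant j: (z1j, z2j) is bivariate normal with variances
    1 + N_t h2_t l_j / M and covariance sqrt(N1 N2) rg sqrt(h2_1 h2_2)
    l_j / M.  Used for parameter-recovery checks.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    m = len(ell)
    v1 = 1.0 + n1 * h2_1 * ell / m
    v2 = 1.0 + n2 * h2_2 * ell / m
    cov = np.sqrt(n1 * n2) * rg * np.sqrt(h2_1 * h2_2) * ell / m
    rho = np.clip(cov / np.sqrt(v1 * v2), -1.0, 1.0)
    e1 = rng.standard_normal(m)
    e2 = rng.standard_normal(m)
    z1 = np.sqrt(v1) * e1
    z2 = np.sqrt(v2) * (rho * e1 + np.sqrt(1.0 - rho**2) * e2)
    return z1, z2


def sumstats_from_z(
    z: np.ndarray, n: float, prefix: str = "var", seed_eaf: float = 0.3
) -> SummaryStatsTable:
    """Wrap raw z-scores as a summary-statistics table (unit-information se)."""
    m = len(z)
    eaf = np.full(m, seed_eaf)
    se = 1.0 / np.sqrt(2.0 * n * eaf * (1.0 - eaf))
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)
    return SummaryStatsTable(
        pd.DataFrame(
            {
                "id": [f"{prefix}{j:06d}" for j in range(m)],
                "chrom": "1",
                "pos": np.arange(1, m + 1) * 1000,
                "ea": "A",
                "nea": "G",
                "eaf": eaf,
                "beta": z * se,
                "se": se,
                "p": p,
                "n": float(n),
            }
        )
    )
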