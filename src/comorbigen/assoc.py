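"""Case-case / case-control additive GWAS and genomic-inflation diagnostics.

Per variant, the binary phenotype is regressed on the expected dosage plus
covariates by logistic IRLS (Newton) with Wald tests — the additive test on
imputed expected genotypes.  Missing dosages are mean-imputed per variant
within the analysis sample.  Fits that fail to converge, or that show
(quasi-)separation, are flagged and reported with the p-value absent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeDataset, PhenotypeTable, SummaryStatsTable, ValidationError

#: median of the chi-square distribution with 1 df
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))

_MAX_ITER = 25
_LL_TOL = 1e-8
_BETA_CAP = 15.0  # |log OR| beyond this is treated as separation
_SE_CAP = 100.0

#: the six pairwise analyses of the study design (case group, reference group)
DEFAULT_GWAS_PAIRS = (
    ("SCZ", "CONTROL"),
    ("T2D", "CONTROL"),
    ("SCZplusT2D", "CONTROL"),
    ("T2D", "SCZ"),
    ("SCZplusT2D", "SCZ"),
    ("SCZplusT2D", "T2D"),
)


@dataclass
class GwasResult:
    """Per-variant association estimates for one group comparison."""

    table: pd.DataFrame  # id, chrom, pos, ea, nea, eaf, beta, se, or_, ci_low,
    #                      ci_high, p, converged
    n_cases: int
    n_controls: int

    def to_sumstats(self) -> SummaryStatsTable:
        t = self.table
        ok = t["converged"] & np.isfinite(t["p"])
        sub = t[ok]
        return SummaryStatsTable(
            pd.DataFrame(
                {
                    "id": sub["id"], "chrom": sub["chrom"], "pos": sub["pos"],
                    "ea": sub["ea"], "nea": sub["nea"], "eaf": sub["eaf"],
                    "beta": sub["beta"], "se": sub["se"],
                    "p": np.clip(sub["p"], np.nextafter(0, 1), 1.0),
                    "n": float(self.n_cases + self.n_controls),
                }
            )
        )


def _check_covariates(covars: np.ndarray, names: list) -> None:
    if covars.shape[1] == 0:
        return
    x = np.column_stack([np.ones(covars.shape[0]), covars])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify a minimal offending column by incremental rank
        bad = []
        cur = np.ones((covars.shape[0], 1))
        for i in range(covars.shape[1]):
            cand = np.column_stack([cur, covars[:, i]])
            if np.linalg.matrix_rank(cand) == cur.shape[1]:
                bad.append(names[i])
            else:
                cur = cand
        raise ValidationError(f"collinear covariate columns: {bad}")


def _batched_logistic(
    y: np.ndarray, dosage: np.ndarray, covars: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Newton/IRLS logistic fits for every variant at once.

    ``dosage`` is (n, m); the design per variant is [1, dosage_j, covars].
    Returns (beta_dosage, se_dosage, converged) each of length m.
    """
    n, m = dosage.shape
    k = 2 + covars.shape[1]
    shared = np.column_stack([np.ones(n), covars])  # intercept + covariates
    beta = np.zeros((m, k))
    converged = np.zeros(m, dtype=bool)
    active = np.arange(m)
    ll_prev = np.full(m, -np.inf)
    for _ in range(_MAX_ITER):
        if len(active) == 0:
            break
        g = dosage[:, active]  # (n, a)
        b = beta[active]  # (a, k)
        eta = shared @ b[:, [0, *range(2, k)]].T + g * b[:, 1][None, :]
        eta = np.clip(eta, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        resid = y[:, None] - mu
        ll = (y[:, None] * eta - np.log1p(np.exp(eta))).sum(axis=0)

        # score vector and Hessian blocks per variant
        grad = np.empty((len(active), k))
        grad[:, 0] = resid.sum(axis=0)
        grad[:, 1] = (resid * g).sum(axis=0)
        if k > 2:
            grad[:, 2:] = resid.T @ covars

        hess = np.empty((len(active), k, k))
        # shared x shared block: einsum over samples with per-variant weights
        hess_ss = np.einsum("na,nb,nv->vab", shared, shared, w, optimize=True)
        hess_gg = (w * g * g).sum(axis=0)
        hess_gs = np.einsum("nv,nv,na->va", w, g, shared, optimize=True)
        order = [0, *range(2, k)]  # positions of shared columns in the design
        for ai, pos in enumerate(order):
            for bi, pos2 in enumerate(order):
                hess[:, pos, pos2] = hess_ss[:, ai, bi]
            hess[:, pos, 1] = hess_gs[:, ai]
            hess[:, 1, pos] = hess_gs[:, ai]
        hess[:, 1, 1] = hess_gg

        try:
            step = np.linalg.solve(hess, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.array([np.linalg.lstsq(h, gr, rcond=None)[0]
                             for h, gr in zip(hess, grad)])
        beta[active] += step
        done = np.abs(ll - ll_prev[active]) < _LL_TOL
        converged[active[done]] = True
        ll_prev[active] = ll
        active = active[~done]

    # standard errors from the final observed information
    se = np.full(m, np.nan)
    eta = shared @ beta[:, [0, *range(2, k)]].T + dosage * beta[:, 1][None, :]
    eta = np.clip(eta, -30.0, 30.0)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    hess_ss = np.einsum("na,nb,nv->vab", shared, shared, w, optimize=True)
    hess_gg = (w * dosage * dosage).sum(axis=0)
    hess_gs = np.einsum("nv,nv,na->va", w, dosage, shared, optimize=True)
    order = [0, *range(2, k)]
    hess = np.empty((m, k, k))
    for ai, pos in enumerate(order):
        for bi, pos2 in enumerate(order):
            hess[:, pos, pos2] = hess_ss[:, ai, bi]
        hess[:, pos, 1] = hess_gs[:, ai]
        hess[:, 1, pos] = hess_gs[:, ai]
    hess[:, 1, 1] = hess_gg
    for v in range(m):
        try:
            cov = np.linalg.inv(hess[v])
            if cov[1, 1] > 0:
                se[v] = np.sqrt(cov[1, 1])
        except np.linalg.LinAlgError:
            pass
    return beta[:, 1], se, converged


def logistic_gwas(
    genotypes: GenotypeDataset,
    phenotypes: PhenotypeTable,
    case_group: str,
    control_group: str,
    covariate_names: list | None = None,
) -> GwasResult:
    """Additive logistic GWAS of ``case_group`` vs ``control_group``.

    Covariates (default: every C* column of the phenotype table, i.e. the
    MDS components) enter every model; Wald p-values are reported.
    """
    cases = [s for s in phenotypes.group(case_group) if s in set(genotypes.samples)]
    controls = [s for s in phenotypes.group(control_group) if s in set(genotypes.samples)]
    samples = cases + controls
    if not cases or not controls:
        raise ValidationError("phenotype is constant: a group is empty")
    y = np.concatenate([np.ones(len(cases)), np.zeros(len(controls))])

    if covariate_names is None:
        covariate_names = phenotypes.covariate_columns()
    covars = (
        phenotypes.table.loc[samples, covariate_names].to_numpy(dtype=float)
        if covariate_names
        else np.zeros((len(samples), 0))
    )
    _check_covariates(covars, list(covariate_names))

    ds = genotypes.subset(samples=samples)
    dosage = ds.imputed_dosages()
    # flag exact case/control separation per variant before fitting
    beta, se, converged = _batched_logistic(y, dosage, covars)
    bad = (~converged) | (np.abs(beta) > _BETA_CAP) | ~np.isfinite(se) | (se > _SE_CAP)
    ok = ~bad
    zstat = np.where(ok, beta / se, np.nan)
    pval = np.where(ok, 2.0 * stats.norm.sf(np.abs(zstat)), np.nan)

    t = ds.variants
    with np.errstate(over="ignore", invalid="ignore"):
        table = pd.DataFrame(
            {
                "id": t["id"], "chrom": t["chrom"], "pos": t["pos"],
                "ea": t["ea"], "nea": t["nea"],
                "eaf": ds.eaf_observed(),
                "beta": np.where(ok, beta, np.nan),
                "se": np.where(ok, se, np.nan),
                "or_": np.where(ok, np.exp(beta), np.nan),
                "ci_low": np.where(ok, np.exp(beta - 1.96 * se), np.nan),
                "ci_high": np.where(ok, np.exp(beta + 1.96 * se), np.nan),
                "p": pval,
                "converged": ok,
            }
        )
    return GwasResult(table, n_cases=len(cases), n_controls=len(controls))


@dataclass(frozen=True)
class InflationEstimate:
    """Genomic inflation factor: median observed 1-df chi-square / 0.4549."""

    lam: float
    n_variants: int


def lambda_gc(p_values: np.ndarray | pd.Series | GwasResult) -> InflationEstimate:
    """Genomic control lambda from association p-values.

    Back-transforms p to 1-df chi-square quantiles and divides the median
    by the null median (~0.45494).  Requires >= 100 usable p-values.
    """
    if isinstance(p_values, GwasResult):
        p_values = p_values.table["p"]
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) < 100:
        raise ValidationError(f"need >= 100 p-values for lambda, got {len(p)}")
    chi2 = stats.chi2.isf(p, 1)
    return InflationEstimate(float(np.median(chi2) / CHI2_1DF_MEDIAN), len(p))


def run_all_gwas(
    genotypes: GenotypeDataset,
    phenotypes: PhenotypeTable,
    pairs: tuple = DEFAULT_GWAS_PAIRS,
    covariate_names: list | None = None,
) -> dict:
    """The six case-case and case-control analyses of the study design."""
    return {
        f"{a}_vs_{b}": logistic_gwas(genotypes, phenotypes, a, b, covariate_names)
        for a, b in pairs
    }
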