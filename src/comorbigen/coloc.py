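"""Five-hypothesis Bayesian colocalisation over LD blocks.

For one region with m shared variants, Z-scores and standard errors from
two association studies are combined through per-variant approximate Bayes
factors into posterior probabilities of five hypotheses (study-numbering
used throughout this package):

* H0 — no causal variant in the region;
* H1 — one causal variant for disease 1 only;
* H2 — one causal variant for disease 2 only;
* H3 — ONE SHARED causal variant for both diseases;
* H4 — TWO DISTINCT causal variants, one per disease.

Note this hypothesis order swaps H3/H4 relative to a widely used
colocalisation software convention; ``numbering="coloc"`` relabels the
output for interoperability.

The per-variant ABF uses the normal approximation with prior effect
variance W: with V = se², r = W/(V+W), ABF = sqrt(1-r) * exp(z² r / 2),
evaluated and aggregated entirely in log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .datatypes import LDBlockSet, SummaryStatsTable, ValidationError


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP prior probabilities of causality and prior effect variances.

    ``p1``/``p2``: causal for disease 1/2 only; ``p12``: causal for both.
    ``w1``/``w2``: prior variance of the (log-odds scale) effect size.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    w1: float = 0.04
    w2: float = 0.04

    def __post_init__(self) -> None:
        if min(self.p1, self.p2, self.p12) <= 0:
            raise ValidationError("priors must be positive")
        if min(self.w1, self.w2) <= 0:
            raise ValidationError("prior effect variances must be positive")

    def h0_weight(self, m: int) -> float:
        """Prior mass of the no-causal configuration for an m-variant block."""
        total = m * (self.p1 + self.p2 + self.p12) + m * (m - 1) * self.p1 * self.p2
        if total >= 1:
            raise ValidationError(
                f"priors leave no mass for H0 at block size m={m}"
            )
        return 1.0 - total


@dataclass
class ColocRegionResult:
    """Posterior probabilities and top signals for one LD block."""

    block: int
    m: int
    pp: np.ndarray  # PP0..PP4
    max_abs_z1: float
    max_abs_z2: float
    top_variants1: list
    top_variants2: list

    @property
    def flagged(self) -> bool:
        return bool(self.pp[3] >= 0.9 or self.pp[4] >= 0.9)


def wakefield_abf(z: float | np.ndarray, se: float | np.ndarray, W: float) -> np.ndarray:
    """Log approximate Bayes factor for a single-variant association.

    With V = se² and r = W/(V+W): log ABF = 0.5*log(1-r) + z²*r/2.
    Returned in log space to avoid overflow at large |z|.
    """
    z = np.asarray(z, dtype=float)
    se = np.asarray(se, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValidationError("non-finite z-score")
    if np.any(se <= 0) or W <= 0:
        raise ValidationError("se and W must be positive")
    v = se**2
    r = W / (v + W)
    return 0.5 * np.log1p(-r) + z**2 * r / 2.0


def region_posteriors(
    variant_ids: list,
    z1: np.ndarray,
    se1: np.ndarray,
    z2: np.ndarray,
    se2: np.ndarray,
    priors: ColocPriors = ColocPriors(),
    block: int = 0,
) -> ColocRegionResult:
    """Posterior probabilities of H0..H4 for one block.

    Summation over causal configurations runs in log space:
    S1 = sum_i p1*ABF1_i, S2 = sum_i p2*ABF2_i, S3 = sum_i p12*ABF1_i*ABF2_i,
    S4 = sum_{i != j} p1*p2*ABF1_i*ABF2_j, and the H0 term is the residual
    prior mass.  Ties in the per-trait max |Z| are reported as lists.
    """
    m = len(variant_ids)
    arrays = [np.asarray(a, dtype=float) for a in (z1, se1, z2, se2)]
    if any(len(a) != m for a in arrays) or m < 1:
        raise ValidationError("mismatched variant lists in block")
    z1, se1, z2, se2 = arrays
    lab1 = wakefield_abf(z1, se1, priors.w1)
    lab2 = wakefield_abf(z2, se2, priors.w2)

    ls1 = logsumexp(lab1)
    ls2 = logsumexp(lab2)
    ls_same = logsumexp(lab1 + lab2)
    log_s0 = np.log(priors.h0_weight(m))
    log_s1 = np.log(priors.p1) + ls1
    log_s2 = np.log(priors.p2) + ls2
    log_s3 = np.log(priors.p12) + ls_same
    if m < 2:
        log_s4 = -np.inf
    else:
        # sum over ordered distinct pairs = (sum_i)(sum_j) - sum_i (i=j)
        diff = ls_same - (ls1 + ls2)
        log_s4 = (
            np.log(priors.p1) + np.log(priors.p2) + ls1 + ls2 + np.log1p(-np.exp(diff))
            if diff < 0
            else -np.inf
        )
    logs = np.array([log_s0, log_s1, log_s2, log_s3, log_s4])
    pp = np.exp(logs - logsumexp(logs))
    pp /= pp.sum()

    a1 = np.abs(z1)
    a2 = np.abs(z2)
    ids = np.asarray(variant_ids)
    top1 = list(ids[a1 == a1.max()])
    top2 = list(ids[a2 == a2.max()])
    return ColocRegionResult(block, m, pp, float(a1.max()), float(a2.max()), top1, top2)


def scan_genome(
    sumstats1: SummaryStatsTable,
    sumstats2: SummaryStatsTable,
    blocks: LDBlockSet,
    priors: ColocPriors = ColocPriors(),
    pp_threshold: float = 0.9,
) -> tuple[list, list]:
    """Colocalisation over every LD block containing shared variants.

    Blocks without any variant shared between the studies are skipped.
    Returns (all block results, flagged results with PP3 or PP4 >=
    ``pp_threshold``, ordered by the flagging probability, descending).
    """
    t1 = sumstats1.table.set_index("id")
    t2 = sumstats2.table.set_index("id")
    shared = [v for v in t1.index if v in t2.index]
    if not shared:
        raise ValidationError("no variants shared between the studies")
    sub1 = t1.loc[shared]
    assignment = blocks.assign(sub1.reset_index())
    results = []
    for b in range(len(blocks)):
        ids = [v for v, blk in zip(shared, assignment) if blk == b]
        if not ids:
            continue
        s1 = t1.loc[ids]
        s2 = t2.loc[ids]
        res = region_posteriors(
            ids,
            (s1["beta"] / s1["se"]).to_numpy(),
            s1["se"].to_numpy(),
            (s2["beta"] / s2["se"]).to_numpy(),
            s2["se"].to_numpy(),
            priors=priors,
            block=b,
        )
        results.append(res)
    if not results:
        raise ValidationError("no LD block contains any shared variant")
    flagged = [r for r in results
               if r.pp[3] >= pp_threshold or r.pp[4] >= pp_threshold]
    flagged.sort(key=lambda r: max(r.pp[3], r.pp[4]), reverse=True)
    return results, flagged


def coloc_results_frame(results: list, numbering: str = "study") -> pd.DataFrame:
    """Tabulate block results; ``numbering="coloc"`` swaps the PP3/PP4
    labels to the H3=distinct / H4=shared convention of common software."""
    rows = []
    for r in results:
        pp = r.pp
        if numbering == "coloc":
            pp = pp[[0, 1, 2, 4, 3]]
        elif numbering != "study":
            raise ValidationError(f"unknown numbering {numbering!r}")
        rows.append(
            {
                "block": r.block, "m": r.m,
                **{f"PP{k}": pp[k] for k in range(5)},
                "max_abs_z1": r.max_abs_z1, "max_abs_z2": r.max_abs_z2,
                "top_variants1": ",".join(map(str, r.top_variants1)),
                "top_variants2": ",".join(map(str, r.top_variants2)),
                "flagged": r.flagged,
            }
        )
    return pd.DataFrame(rows)
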