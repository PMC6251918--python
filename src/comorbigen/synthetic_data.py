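"""Synthetic study generator: LD-blocked genotypes, a two-liability
comorbidity cohort, and paired base-study summary statistics.

The generator stands in for access-controlled inputs of the real study
design: a target cohort with four groups (trait-1-only, trait-2-only,
comorbid, population controls) and two large external GWAS whose causal
architectures overlap by a configurable shared set.

Model
-----
* Genotypes: within each LD block, each haplotype is a latent Gaussian
  AR(1) chain with parameter ``rho`` thresholded at the allele frequency
  quantile; two independent haplotypes per individual give Hardy-Weinberg
  genotypes with tunable within-block LD and exactly zero LD across blocks.
* Phenotypes: liability_t = sum_j g_std_j * beta_tj + e_t for traits
  t in {1, 2}; shared causal variants get correlated effects in the two
  traits; an individual is a case when its liability exceeds the
  (1 - prevalence) quantile.  Groups are formed from the two disease
  indicators and down-sampled to the requested sizes by rejection from a
  large pool (``pool_multiplier`` times the requested total), so group
  counts are exact.
* Base summary statistics: per variant, E[z_t] = sqrt(N_t) * beta_t * scale
  with unit-variance noise, correlated between studies when they share
  ``n_overlap`` samples; se = 1 / sqrt(2 N_t p (1-p)); beta = z * se.

Everything is deterministic under (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    GenotypeDataset,
    LDBlockSet,
    PhenotypeTable,
    SummaryStatsTable,
    ValidationError,
)

_NONPALINDROMIC_PAIRS = [
    ("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
    ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"),
]

#: intra-block inter-variant spacing and inter-block gap, in bp
_SPACING_BP = 5_000
_BLOCK_GAP_BP = 500_000


@dataclass
class SimulationSpec:
    """All knobs of one synthetic study; defaults mirror the study design
    (group sizes 924 / 822 / 505 cases and 1,125 controls)."""

    # target-cohort group sizes
    n_trait1: int = 924          # trait-1-only (SCZ-like)
    n_trait2: int = 822          # trait-2-only (T2D-like)
    n_comorbid: int = 505
    n_control: int = 1125
    pool_multiplier: float = 20.0

    # genotypes; the variant count keeps enough quasi-independent markers
    # (post LD pruning) for stable pi_hat screening across millions of pairs
    n_variants: int = 4800
    n_blocks: int = 120
    rho: float = 0.8             # latent AR(1) parameter per adjacent pair
    maf_range: tuple = (0.05, 0.5)
    missing_rate: float = 0.01   # missing completely at random
    inject_info: bool = True
    info_range: tuple = (0.3, 1.0)

    # causal architecture: polygenic (several hundred causals) with a shared
    # set whose effect sizes are uncorrelated by default, so the studies
    # share association signals (overlapping loci) while the genome-wide
    # genetic correlation stays near zero
    m1: int = 280                # trait-1-only causal variants
    m2: int = 280                # trait-2-only causal variants
    m12: int = 100               # shared causal variants
    effect_sd: float = 0.03      # per-causal-variant effect SD (standardized scale)
    shared_beta_corr: float = 0.0
    h2_1: float = 0.4            # liability-scale heritabilities
    h2_2: float = 0.4
    prevalence1: float = 0.10
    prevalence2: float = 0.10
    # non-genetic cross-trait pathway: a random fraction of trait-1 cases
    # ("susceptible" to the medication/lifestyle route of the comorbidity)
    # gets this many liability SDs added to trait 2.  The mixture places the
    # comorbid group's trait-2 genetic burden between the trait-1-only and
    # trait-2-only groups while leaving the trait-1-only survivors nearly
    # undepleted of trait-2 risk alleles
    comorbidity_effect: float = 2.2
    comorbidity_fraction: float = 0.22

    # base studies
    n_study1: int = 70_000
    n_study2: int = 80_000
    n_overlap: int = 0
    sumstats_scale: float = 0.4  # maps liability-scale beta to expected z / sqrt(N)

    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_trait1, self.n_trait2, self.n_comorbid, self.n_control,
                  self.n_variants, self.n_blocks, self.m1, self.m2, self.m12)
        if any(c < 0 for c in counts):
            raise ValidationError("all counts must be >= 0")
        if not (0 <= self.rho < 1):
            raise ValidationError("rho must lie in [0, 1)")
        for k in (self.prevalence1, self.prevalence2):
            if not (0 < k < 1):
                raise ValidationError("prevalences must lie in (0, 1)")
        if self.n_variants < self.n_blocks:
            raise ValidationError("n_variants must be >= n_blocks")
        if self.m1 + self.m2 + self.m12 > self.n_variants:
            raise ValidationError("causal sets exceed variant count")
        if self.n_overlap > min(self.n_study1, self.n_study2):
            raise ValidationError("n_overlap exceeds the smaller study size")

    @property
    def group_sizes(self) -> dict:
        return {"SCZ": self.n_trait1, "T2D": self.n_trait2,
                "SCZplusT2D": self.n_comorbid, "CONTROL": self.n_control}

    @property
    def pool_size(self) -> int:
        total = sum(self.group_sizes.values())
        return int(np.ceil(self.pool_multiplier * total))


@dataclass
class TruthRecord:
    """Ground truth of one simulated study, for parameter-recovery tests.

    ``variants``: per variant causal flags and true effects for both traits.
    ``samples``: per pool sample the genetic values, liabilities, disease
    indicators, group and whether it was selected into the final cohort.
    ``thresholds``: the liability case cut-offs actually applied, so every
    phenotype can be recomputed exactly from this record.
    """

    variants: pd.DataFrame
    samples: pd.DataFrame
    thresholds: tuple


@dataclass
class StudyData:
    """One complete synthetic study (cohort + two base GWAS)."""

    genotypes: GenotypeDataset
    blocks: LDBlockSet
    phenotypes: PhenotypeTable
    truth: TruthRecord
    sumstats1: SummaryStatsTable
    sumstats2: SummaryStatsTable


def _block_sizes(n_variants: int, n_blocks: int) -> np.ndarray:
    sizes = np.full(n_blocks, n_variants // n_blocks, dtype=np.int64)
    sizes[: n_variants % n_blocks] += 1
    return sizes


def _layout(spec: SimulationSpec, rng: np.random.Generator):
    """Variant metadata (maf, alleles, positions) and the block table."""
    sizes = _block_sizes(spec.n_variants, spec.n_blocks)
    maf = rng.uniform(*spec.maf_range, size=spec.n_variants)
    pair_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=spec.n_variants)
    chroms, positions, brows = [], [], []
    offset_by_chrom: dict = {}
    for b, mb in enumerate(sizes):
        chrom = str(b % 22 + 1)
        start = offset_by_chrom.get(chrom, 0)
        pos = start + _SPACING_BP * (1 + np.arange(mb))
        chroms.extend([chrom] * int(mb))
        positions.append(pos)
        brows.append((chrom, start, int(pos[-1]) + 1))  # 0-based half-open
        offset_by_chrom[chrom] = int(pos[-1]) + _BLOCK_GAP_BP
    positions = np.concatenate(positions)
    variants = pd.DataFrame(
        {
            "id": [f"var{j:06d}" for j in range(spec.n_variants)],
            "chrom": chroms,
            "pos": positions.astype(np.int64),
            "ea": [_NONPALINDROMIC_PAIRS[i][0] for i in pair_idx],
            "nea": [_NONPALINDROMIC_PAIRS[i][1] for i in pair_idx],
            "eaf": maf,
            "info": np.nan,
        }
    )
    blocks = LDBlockSet(pd.DataFrame(brows, columns=["chrom", "start", "end"]))
    return variants, blocks, sizes


def _ar1_haplotypes(rng: np.random.Generator, n_hap: int, maf: np.ndarray,
                    rho: float) -> np.ndarray:
    """One block of haplotypes: latent AR(1) Gaussians thresholded at maf."""
    m = len(maf)
    x = np.empty((n_hap, m), dtype=np.float64)
    x[:, 0] = rng.standard_normal(n_hap)
    if m > 1:
        innov = rng.standard_normal((n_hap, m - 1)) * np.sqrt(1.0 - rho * rho)
        for j in range(1, m):
            x[:, j] = rho * x[:, j - 1] + innov[:, j - 1]
    thresh = stats.norm.ppf(maf)
    return (x < thresh[None, :]).astype(np.float32)


def simulate_genotypes(
    spec: SimulationSpec, n_samples: int | None = None
) -> tuple[GenotypeDataset, LDBlockSet]:
    """Generate the genotype pool and its LD-block definitions.

    ``n_samples`` defaults to the rejection-sampling pool size.  Missing
    calls (MCAR) and per-variant info scores are injected as configured.
    """
    n = spec.pool_size if n_samples is None else int(n_samples)
    ss = np.random.SeedSequence([spec.seed, 1])
    children = ss.spawn(spec.n_blocks + 2)
    meta_rng = np.random.default_rng(children[0])
    variants, blocks, sizes = _layout(spec, meta_rng)
    dosages = np.empty((n, spec.n_variants), dtype=np.float32)
    j0 = 0
    for b, mb in enumerate(sizes):
        rng_b = np.random.default_rng(children[b + 1])
        maf = variants["eaf"].to_numpy()[j0 : j0 + mb]
        h1 = _ar1_haplotypes(rng_b, n, maf, spec.rho)
        h2 = _ar1_haplotypes(rng_b, n, maf, spec.rho)
        dosages[:, j0 : j0 + mb] = h1 + h2
        j0 += mb
    noise_rng = np.random.default_rng(children[-1])
    if spec.missing_rate > 0:
        # chunked so the uniform draw never materialises a pool-sized float64
        for j in range(0, spec.n_variants, 256):
            sl = slice(j, min(j + 256, spec.n_variants))
            miss = noise_rng.random((n, sl.stop - sl.start)) < spec.missing_rate
            block = dosages[:, sl]
            block[miss] = np.nan
            dosages[:, sl] = block
    if spec.inject_info:
        variants["info"] = noise_rng.uniform(*spec.info_range, size=spec.n_variants)
    samples = [f"S{i:06d}" for i in range(n)]
    return GenotypeDataset(samples, variants, dosages), blocks


def _standardized(genotypes: GenotypeDataset, cols: np.ndarray) -> np.ndarray:
    """Mean-imputed, per-variant standardized dosages for selected columns."""
    d = np.asarray(genotypes.dosages[:, cols], dtype=np.float64)
    mean = np.nanmean(d, axis=0)
    idx = np.where(np.isnan(d))
    d[idx] = mean[idx[1]]
    sd = d.std(axis=0)
    sd[sd == 0] = 1.0
    return (d - mean) / sd


def simulate_phenotypes(
    genotypes: GenotypeDataset, spec: SimulationSpec
) -> tuple[PhenotypeTable, TruthRecord]:
    """Assign two-liability phenotypes and build the four study groups.

    Returns the phenotype table of the *selected* cohort (down-sampled to
    the requested group sizes) and the full ground truth over the pool.
    Raises when a requested group size cannot be met, with a hint to
    enlarge the pool.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    n, m = genotypes.n_samples, genotypes.n_variants
    if spec.m1 + spec.m2 + spec.m12 > m:
        raise ValidationError("causal sets exceed variant count")
    picked = rng.choice(m, size=spec.m12 + spec.m1 + spec.m2, replace=False)
    shared = picked[: spec.m12]
    only1 = picked[spec.m12 : spec.m12 + spec.m1]
    only2 = picked[spec.m12 + spec.m1 :]

    beta1 = np.zeros(m)
    beta2 = np.zeros(m)
    if spec.m12 > 0:
        cov = spec.shared_beta_corr * spec.effect_sd**2
        cmat = np.array([[spec.effect_sd**2, cov], [cov, spec.effect_sd**2]])
        bb = rng.multivariate_normal([0.0, 0.0], cmat, size=spec.m12)
        if spec.shared_beta_corr == 0 and spec.m12 > 1:
            # pin the realized genetic covariance of the shared set at its
            # target of exactly zero (shared loci, orthogonal effects)
            b1, b2 = bb[:, 0], bb[:, 1]
            b2 = b2 - (b1 @ b2) / (b1 @ b1) * b1
            bb[:, 1] = b2 / b2.std() * spec.effect_sd if b2.std() > 0 else b2
        beta1[shared] = bb[:, 0]
        beta2[shared] = bb[:, 1]
    beta1[only1] = rng.normal(0.0, spec.effect_sd, size=spec.m1)
    beta2[only2] = rng.normal(0.0, spec.effect_sd, size=spec.m2)
    if spec.h2_1 == 0:
        beta1[:] = 0.0
    if spec.h2_2 == 0:
        beta2[:] = 0.0

    causal_cols = np.unique(np.concatenate([shared, only1, only2])) if len(picked) else np.array([], dtype=int)
    gstd = _standardized(genotypes, causal_cols) if len(causal_cols) else np.zeros((n, 0))
    g1 = gstd @ beta1[causal_cols]
    g2 = gstd @ beta2[causal_cols]

    def liability(g: np.ndarray, h2: float) -> np.ndarray:
        var_g = float(np.var(g))
        if h2 <= 0 or var_g == 0:
            return rng.standard_normal(n)
        sigma_e = np.sqrt(var_g * (1.0 - h2) / h2)
        return g + sigma_e * rng.standard_normal(n)

    l1 = liability(g1, spec.h2_1)
    t1 = float(np.quantile(l1, 1.0 - spec.prevalence1))
    case1 = l1 > t1
    l2 = liability(g2, spec.h2_2)
    # non-genetic pathway from trait-1 disease into trait-2 liability,
    # restricted to a susceptible fraction of trait-1 cases
    susceptible = rng.random(n) < spec.comorbidity_fraction
    boosted = case1 & susceptible
    if spec.comorbidity_effect != 0:
        l2 = l2 + spec.comorbidity_effect * float(np.std(l2)) * boosted
    t2 = float(np.quantile(l2, 1.0 - spec.prevalence2))
    case2 = l2 > t2
    group = np.where(case1 & case2, "SCZplusT2D",
             np.where(case1, "SCZ", np.where(case2, "T2D", "CONTROL")))

    selected = np.zeros(n, dtype=bool)
    for label, want in spec.group_sizes.items():
        avail = np.flatnonzero(group == label)
        if len(avail) < want:
            raise ValidationError(
                f"group {label}: only {len(avail)} pool samples for {want} requested; "
                f"increase pool_multiplier or adjust prevalences"
            )
        selected[rng.choice(avail, size=want, replace=False)] = True

    vt = genotypes.variants
    truth_variants = pd.DataFrame(
        {
            "id": vt["id"], "chrom": vt["chrom"], "pos": vt["pos"],
            "ea": vt["ea"], "nea": vt["nea"], "eaf": vt["eaf"],
            "causal1": np.isin(np.arange(m), np.concatenate([shared, only1])),
            "causal2": np.isin(np.arange(m), np.concatenate([shared, only2])),
            "beta1": beta1, "beta2": beta2,
        }
    )
    truth_samples = pd.DataFrame(
        {
            "iid": genotypes.samples, "g1": g1, "g2": g2,
            "liability1": l1, "liability2": l2, "comorbid_boost": boosted,
            "case1": case1, "case2": case2, "group": group, "selected": selected,
        }
    )
    truth = TruthRecord(truth_variants, truth_samples, (t1, t2))
    sel = truth_samples[selected]
    pheno = PhenotypeTable(
        pd.DataFrame({"GROUP": sel["group"].to_numpy()}, index=sel["iid"].to_numpy())
    )
    return pheno, truth


def simulate_base_sumstats(
    truth: TruthRecord, spec: SimulationSpec
) -> tuple[SummaryStatsTable, SummaryStatsTable]:
    """Emit the two external studies' summary statistics from the truth.

    Per variant j: E[z_tj] = sqrt(N_t) * beta_tj * scale, unit noise
    correlated across studies by n_overlap / sqrt(N1 N2);
    se_t = 1 / sqrt(2 N_t p (1-p)), beta = z * se, two-sided normal p.
    """
    if spec.n_overlap > min(spec.n_study1, spec.n_study2):
        raise ValidationError("n_overlap exceeds the smaller study size")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    v = truth.variants
    m = len(v)
    rho = spec.n_overlap / np.sqrt(spec.n_study1 * spec.n_study2)
    e1 = rng.standard_normal(m)
    e_ind = rng.standard_normal(m)
    e2 = rho * e1 + np.sqrt(1.0 - rho * rho) * e_ind
    out = []
    for n_t, beta_t, noise in (
        (spec.n_study1, v["beta1"].to_numpy(), e1),
        (spec.n_study2, v["beta2"].to_numpy(), e2),
    ):
        z = np.sqrt(n_t) * beta_t * spec.sumstats_scale + noise
        p_allele = v["eaf"].to_numpy()
        se = 1.0 / np.sqrt(2.0 * n_t * p_allele * (1.0 - p_allele))
        pval = 2.0 * stats.norm.sf(np.abs(z))
        pval = np.clip(pval, np.nextafter(0, 1), 1.0)
        out.append(
            SummaryStatsTable(
                pd.DataFrame(
                    {
                        "id": v["id"], "chrom": v["chrom"], "pos": v["pos"],
                        "ea": v["ea"], "nea": v["nea"], "eaf": p_allele,
                        "beta": z * se, "se": se, "p": pval,
                        "n": float(n_t),
                    }
                )
            )
        )
    return out[0], out[1]


def simulate_study(spec: SimulationSpec) -> StudyData:
    """Full study build: pool genotypes, phenotype groups, cohort subset and
    the paired base-study summary statistics."""
    pool, blocks = simulate_genotypes(spec)
    pheno, truth = simulate_phenotypes(pool, spec)
    cohort = pool.subset(samples=pheno.samples)
    ss1, ss2 = simulate_base_sumstats(truth, spec)
    return StudyData(cohort, blocks, pheno, truth, ss1, ss2)


def write_study(study: StudyData, out_dir: str, prefix: str = "study") -> dict:
    """Write every artifact of a study as the plain-text exchange formats."""
    import os

    from . import io_formats as io

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, f"{prefix}.vcf"),
        "sumstats1": os.path.join(out_dir, f"{prefix}.base1.tsv"),
        "sumstats2": os.path.join(out_dir, f"{prefix}.base2.tsv"),
        "blocks": os.path.join(out_dir, f"{prefix}.blocks.bed"),
        "pheno": os.path.join(out_dir, f"{prefix}.pheno.tsv"),
        "truth_variants": os.path.join(out_dir, f"{prefix}.truth_variants.tsv"),
        "truth_samples": os.path.join(out_dir, f"{prefix}.truth_samples.tsv"),
    }
    io.write_vcf(study.genotypes, paths["vcf"])
    io.write_sumstats(study.sumstats1, paths["sumstats1"])
    io.write_sumstats(study.sumstats2, paths["sumstats2"])
    io.write_ld_blocks(study.blocks, paths["blocks"])
    io.write_pheno(study.phenotypes, paths["pheno"])
    study.truth.variants.to_csv(paths["truth_variants"], sep="\t", index=False)
    study.truth.samples.to_csv(paths["truth_samples"], sep="\t", index=False)
    return paths
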