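"""In-memory containers shared by every analysis module.

The pipeline moves genotype dosages, phenotype/covariate tables, GWAS
summary statistics and LD-block definitions between stages as the typed
objects defined here; file parsing/writing lives in :mod:`comorbigen.io_formats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np
import pandas as pd

GROUP_LABELS = ("SCZ", "T2D", "SCZplusT2D", "OTHER", "CONTROL")

#: canonical variant-metadata columns, in order
VARIANT_COLUMNS = ["id", "chrom", "pos", "ea", "nea", "eaf", "info"]

#: canonical summary-statistics columns, in order
SUMSTATS_COLUMNS = ["id", "chrom", "pos", "ea", "nea", "eaf", "beta", "se", "p", "n"]

_VALID_BASES = frozenset("ACGT")


class ValidationError(ValueError):
    """Raised when an input object or file violates a format contract."""


@dataclass(frozen=True)
class VariantRecord:
    """A single biallelic variant: identifier, position and alleles.

    ``ea`` is the effect allele (the allele whose copies a dosage counts,
    or the allele an effect size refers to); ``nea`` the other allele.
    """

    id: str
    chrom: str
    pos: int
    ea: str
    nea: str
    eaf: float | None = None
    info: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if self.ea == self.nea:
            raise ValidationError(f"variant {self.id}: ea == nea ({self.ea})")
        for name in ("eaf", "info"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError(f"variant {self.id}: {name}={v} outside [0, 1]")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G pairs, whose strand is unresolvable."""
        return {self.ea, self.nea} in ({"A", "T"}, {"C", "G"})


def variants_frame(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Stack :class:`VariantRecord` objects into the canonical DataFrame."""
    return pd.DataFrame(
        [[getattr(r, c) for c in VARIANT_COLUMNS] for r in records],
        columns=VARIANT_COLUMNS,
    ).astype({"pos": np.int64})


@dataclass
class GenotypeDataset:
    """Sample-by-variant dosage matrix with variant metadata.

    ``dosages`` holds expected effect-allele counts in ``[0, 2]``; missing
    genotypes are ``NaN`` (never silently zero).  Rows follow ``samples``,
    columns follow rows of ``variants`` (canonical columns, see
    :data:`VARIANT_COLUMNS`).
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float32)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValidationError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample ids")
        if self.variants["id"].duplicated().any():
            dup = self.variants["id"][self.variants["id"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate variant id {dup!r}")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            raise ValidationError("dosages outside [0, 2]")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_call_rate(self) -> np.ndarray:
        """Per-sample fraction of non-missing genotypes."""
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def variant_call_rate(self) -> np.ndarray:
        """Per-variant fraction of non-missing genotypes."""
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def eaf_observed(self) -> np.ndarray:
        """In-sample effect-allele frequency (mean dosage / 2)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf_observed(self) -> np.ndarray:
        eaf = self.eaf_observed()
        return np.minimum(eaf, 1.0 - eaf)

    def imputed_dosages(self) -> np.ndarray:
        """Dosages with missing entries replaced by the variant mean."""
        d = np.array(self.dosages, dtype=np.float64)
        mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
        mean = np.where(np.isnan(mean), 0.0, mean)
        idx = np.where(np.isnan(d))
        d[idx] = mean[idx[1]]
        return d

    def hard_genotypes(self) -> np.ndarray:
        """Rounded genotypes in {0, 1, 2}; missing encoded as -1 (int8)."""
        g = np.rint(self.dosages)
        g = np.where(np.isnan(self.dosages), -1, g)
        return g.astype(np.int8)

    def subset(
        self,
        samples: Sequence[str] | None = None,
        variant_mask: np.ndarray | None = None,
    ) -> "GenotypeDataset":
        """Restrict to the given samples and/or a boolean variant mask."""
        ds = self
        if samples is not None:
            pos = {s: i for i, s in enumerate(ds.samples)}
            missing = [s for s in samples if s not in pos]
            if missing:
                raise KeyError(f"unknown samples: {missing[:5]}")
            rows = [pos[s] for s in samples]
            ds = GenotypeDataset(list(samples), ds.variants.copy(), ds.dosages[rows])
        if variant_mask is not None:
            variant_mask = np.asarray(variant_mask, dtype=bool)
            ds = GenotypeDataset(
                list(ds.samples),
                ds.variants.loc[variant_mask].reset_index(drop=True),
                ds.dosages[:, variant_mask],
            )
        return ds


@dataclass
class PhenotypeTable:
    """Sample group labels plus ancestry covariates (MDS components).

    ``table`` is indexed by sample id with a ``GROUP`` column taking values
    in :data:`GROUP_LABELS` and optional covariate columns ``C1..Ck``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "GROUP" not in self.table.columns:
            raise ValidationError("phenotype table lacks GROUP column")
        bad = set(self.table["GROUP"].unique()) - set(GROUP_LABELS)
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        if self.table.index.duplicated().any():
            raise ValidationError("duplicate sample ids in phenotype table")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    def group(self, label: str) -> list[str]:
        """Sample ids carrying one group label."""
        return list(self.table.index[self.table["GROUP"] == label])

    def covariate_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("C") and c[1:].isdigit()]

    def covariates(self, samples: Sequence[str], k: int | None = None) -> pd.DataFrame:
        cols = self.covariate_columns()
        if k is not None:
            want = [f"C{i}" for i in range(1, k + 1)]
            missing = [c for c in want if c not in cols]
            if missing:
                raise ValidationError(f"missing covariate columns: {missing}")
            cols = want
        return self.table.loc[list(samples), cols].astype(float)

    def with_covariates(self, comps: pd.DataFrame) -> "PhenotypeTable":
        """Return a copy whose C1..Ck columns are replaced by ``comps``."""
        base = self.table.drop(columns=self.covariate_columns())
        return PhenotypeTable(base.join(comps, how="left"))


@dataclass
class SummaryStatsTable:
    """Per-variant GWAS effect estimates for one trait.

    ``table`` has the canonical columns (:data:`SUMSTATS_COLUMNS`):
    ``beta`` is the log odds ratio for ``ea``, ``se`` its standard error,
    ``p`` the association p-value and ``n`` the effective sample count.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTATS_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"summary stats lack columns: {missing}")
        t = self.table
        if t["id"].duplicated().any():
            dup = t["id"][t["id"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate variant id {dup!r} in summary stats")
        if len(t) and not (t["se"] > 0).all():
            raise ValidationError("se must be > 0")
        if len(t) and not ((t["p"] > 0) & (t["p"] <= 1)).all():
            raise ValidationError("p must lie in (0, 1]")
        if len(t) and not np.isfinite(t["beta"]).all():
            raise ValidationError("beta must be finite")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def z(self) -> np.ndarray:
        """Z-scores beta / se."""
        return (self.table["beta"] / self.table["se"]).to_numpy(dtype=float)


@dataclass
class LDBlockSet:
    """Approximately independent LD blocks, BED convention (0-based half-open)."""

    table: pd.DataFrame  # columns chrom, start, end

    def __post_init__(self) -> None:
        t = self.table[["chrom", "start", "end"]].copy()
        t["start"] = t["start"].astype(np.int64)
        t["end"] = t["end"].astype(np.int64)
        if len(t) and not (t["start"] < t["end"]).all():
            raise ValidationError("LD block with start >= end")
        t = t.sort_values(["chrom", "start"]).reset_index(drop=True)
        for chrom, sub in t.groupby("chrom", sort=False):
            if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                raise ValidationError(f"overlapping LD blocks on chromosome {chrom}")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    def assign(self, variants: pd.DataFrame) -> np.ndarray:
        """Block index for each variant row, or -1 if unassigned.

        A variant at 1-based ``pos`` belongs to block (chrom, start, end)
        iff its 0-based coordinate ``pos - 1`` lies in ``[start, end)``.
        """
        out = np.full(len(variants), -1, dtype=np.int64)
        for b, (chrom, start, end) in enumerate(
            self.table[["chrom", "start", "end"]].itertuples(index=False)
        ):
            pos0 = variants["pos"].to_numpy() - 1
            hit = (variants["chrom"].to_numpy() == chrom) & (pos0 >= start) & (pos0 < end)
            out[hit] = b
        return out


@dataclass
class RunConfig:
    """All tunable constants of a pipeline run, with study defaults.

    Threshold lists, clumping parameters, permutation count, colocalisation
    priors and QC cut-offs; a single integer ``seed`` fans out to per-stage
    random streams.
    """

    seed: int = 0
    # PRS threshold sweep (cumulative base-study p-value cut-offs)
    prs_thresholds: tuple = (5e-8, 0.001, 0.005, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 1.0)
    # shared-signal overlap test thresholds
    overlap_thresholds: tuple = (0.5, 0.1, 0.05, 0.04, 0.03, 0.02, 0.01, 0.005, 0.001, 5e-4)
    clump_r2: float = 0.1
    clump_window_kb: float = 250.0
    permutations: int = 1_000_000
    # colocalisation priors: per-SNP causal for trait 1 / trait 2 / both
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    coloc_w1: float = 0.04
    coloc_w2: float = 0.04
    coloc_pp_threshold: float = 0.9
    # QC cut-offs
    sample_call_rate_min: float = 0.90
    het_sd: float = 3.0
    pihat_max: float = 0.2
    variant_call_rate_min: float = 0.98
    hwe_p_min: float = 1e-4
    info_min: float = 0.4
    maf_min: float = 0.01
    mds_k: int = 10
    mds_outlier_sd: float = 3.0
    # LDSC
    ldsc_window_kb: float = 1000.0
    ldsc_jackknife_blocks: int = 200

    def __post_init__(self) -> None:
        for name in ("prs_thresholds", "overlap_thresholds"):
            vals = tuple(float(v) for v in getattr(self, name))
            if any(not (0 < v <= 1) for v in vals):
                raise ValidationError(f"{name} must lie in (0, 1]")
            object.__setattr__(self, name, vals)
        if not (0 < self.clump_r2 < 1):
            raise ValidationError("clump_r2 must lie in (0, 1)")
        if self.permutations < 1:
            raise ValidationError("permutations must be >= 1")

    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            d[f.name] = list(v) if isinstance(v, tuple) else v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        kw = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**kw)
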