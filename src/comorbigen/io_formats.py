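"""Readers and writers for every external artifact.

VCF genotypes (via pysam), GWAS summary-statistics TSV, risk-variant TSV,
phenotype/covariate TSV, BED3 LD blocks and the flat key-value run config.
Every reader validates strictly and returns the typed containers from
:mod:`comorbigen.datatypes`; rejected records are reported, never silently
dropped.

Coordinate conventions: VCF and TSV positions are 1-based; BED blocks are
0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
import yaml

from .datatypes import (
    SUMSTATS_COLUMNS,
    GenotypeDataset,
    LDBlockSet,
    PhenotypeTable,
    RunConfig,
    SummaryStatsTable,
    ValidationError,
)

SUMSTATS_HEADER = ["SNP", "CHR", "BP", "EA", "NEA", "EAF", "BETA", "SE", "P", "N"]
RISKSET_HEADER = ["SNP", "EA", "NEA", "LOG_OR"]
PHENO_BASE_HEADER = ["IID", "GROUP"]


@dataclass
class ValidationReport:
    """Machine-readable record of every rejected row, one entry each."""

    rejected: list = field(default_factory=list)  # (record id, reason code)

    def add(self, record_id: str, reason: str) -> None:
        self.rejected.append((record_id, reason))

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def counts(self) -> dict:
        out: dict = {}
        for _, reason in self.rejected:
            out[reason] = out.get(reason, 0) + 1
        return out


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str, info_field_name: str = "INFO_SCORE") -> GenotypeDataset:
    """Read an uncompressed biallelic-SNP VCF into a dosage dataset.

    Dosage is the ``DS`` FORMAT value when present, otherwise the number of
    ALT-allele copies in ``GT``; a missing ``GT`` yields a missing dosage.
    The effect allele is ALT.  Multi-allelic sites and indels raise an
    error naming the offending record (they must be split/removed upstream).
    """
    vf = pysam.VariantFile(path)
    samples = list(vf.header.samples)
    ids, chroms, poss, eas, neas, eafs, infos = [], [], [], [], [], [], []
    rows = []
    for k, rec in enumerate(vf):
        if rec.alts is None or len(rec.alts) != 1:
            raise ValidationError(
                f"{path}: record {k + 1} ({rec.chrom}:{rec.pos}) is not biallelic"
            )
        ref, alt = rec.ref, rec.alts[0]
        if len(ref) != 1 or len(alt) != 1:
            raise ValidationError(
                f"{path}: record {k + 1} ({rec.chrom}:{rec.pos}) is not a SNP"
            )
        vid = rec.id if rec.id else f"{rec.chrom}:{rec.pos}"
        dos = np.full(len(samples), np.nan)
        for i, s in enumerate(samples):
            call = rec.samples[s]
            ds = call.get("DS")
            if ds is not None and not (isinstance(ds, float) and math.isnan(ds)):
                dos[i] = float(ds)
            else:
                gt = call.get("GT")
                if gt is not None and None not in gt:
                    dos[i] = float(sum(gt))
        if np.nanmin(dos, initial=0.0) < 0 or np.nanmax(dos, initial=0.0) > 2:
            raise ValidationError(f"{path}: record {k + 1}: dosage outside [0, 2]")
        ids.append(vid)
        chroms.append(str(rec.chrom))
        poss.append(int(rec.pos))
        eas.append(alt)
        neas.append(ref)
        eafs.append(float(rec.info["EAF"]) if "EAF" in rec.info else np.nan)
        infos.append(
            float(rec.info[info_field_name]) if info_field_name in rec.info else np.nan
        )
        rows.append(dos)
    variants = pd.DataFrame(
        {"id": ids, "chrom": chroms, "pos": poss, "ea": eas, "nea": neas,
         "eaf": eafs, "info": infos}
    )
    dosages = (
        np.array(rows, dtype=np.float32).T
        if rows
        else np.zeros((len(samples), 0), dtype=np.float32)
    )
    return GenotypeDataset(samples, variants, dosages)


def write_vcf(ds: GenotypeDataset, path: str, info_field_name: str = "INFO_SCORE") -> None:
    """Write a dosage dataset as VCF 4.2 with GT (rounded) and DS (exact).

    Reading the file back recovers the dosage matrix exactly because DS
    carries the full value; GT is the nearest hard genotype.
    """
    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
                                     ("Description", "Genotype")])
    header.add_meta("FORMAT", items=[("ID", "DS"), ("Number", "1"), ("Type", "Float"),
                                     ("Description", "Effect allele dosage")])
    header.add_meta("INFO", items=[("ID", "EAF"), ("Number", "1"), ("Type", "Float"),
                                   ("Description", "Effect allele frequency")])
    header.add_meta("INFO", items=[("ID", info_field_name), ("Number", "1"),
                                   ("Type", "Float"),
                                   ("Description", "Imputation info score")])
    for chrom in pd.unique(ds.variants["chrom"]):
        sub = ds.variants[ds.variants["chrom"] == chrom]
        header.contigs.add(str(chrom), length=int(sub["pos"].max()) + 1)
    for s in ds.samples:
        header.add_sample(s)
    out = pysam.VariantFile(path, "w", header=header)
    for j, v in enumerate(ds.variants.itertuples(index=False)):
        rec = out.new_record(
            contig=str(v.chrom), start=int(v.pos) - 1, stop=int(v.pos),
            alleles=(v.nea, v.ea), id=str(v.id),
        )
        if v.eaf is not None and not pd.isna(v.eaf):
            rec.info["EAF"] = float(v.eaf)
        if v.info is not None and not pd.isna(v.info):
            rec.info[info_field_name] = float(v.info)
        col = ds.dosages[:, j]
        for i, s in enumerate(ds.samples):
            d = col[i]
            if np.isnan(d):
                rec.samples[s]["GT"] = (None, None)
            else:
                hard = int(round(float(d)))
                rec.samples[s]["GT"] = ((0, 0), (0, 1), (1, 1))[hard]
                rec.samples[s]["DS"] = float(d)
        out.write(rec)
    out.close()


# ---------------------------------------------------------------------------
# Summary statistics


def read_sumstats(path: str) -> tuple[SummaryStatsTable, ValidationReport]:
    """Read a GWAS summary-statistics TSV.

    Mandatory columns are ``SNP CHR BP EA NEA EAF SE P N`` plus either
    ``BETA`` (log OR) or ``OR`` (converted via the natural log).  Rows with
    ``se <= 0`` or ``p`` outside (0, 1] are rejected and reported; a missing
    mandatory column or duplicate SNP id is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str})
    has_or = "OR" in df.columns and "BETA" not in df.columns
    required = [c for c in SUMSTATS_HEADER if c != "BETA"] + (["OR"] if has_or else ["BETA"])
    for col in required:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing mandatory column {col!r}")
    if df["SNP"].duplicated().any():
        dup = df["SNP"][df["SNP"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate SNP id {dup!r}")
    report = ValidationReport()
    if has_or:
        with np.errstate(divide="ignore", invalid="ignore"):
            df["BETA"] = np.log(df["OR"].astype(float))
    keep = np.ones(len(df), dtype=bool)
    se = df["SE"].astype(float).to_numpy()
    p = df["P"].astype(float).to_numpy()
    beta = df["BETA"].astype(float).to_numpy()
    for i in range(len(df)):
        reasons = []
        if not (se[i] > 0):
            reasons.append("nonpositive_se")
        if not (0 < p[i] <= 1):
            reasons.append("p_out_of_range")
        if not np.isfinite(beta[i]):
            reasons.append("nonfinite_beta")
        if reasons:
            keep[i] = False
            report.add(str(df["SNP"].iloc[i]), "+".join(reasons))
    df = df[keep]
    table = pd.DataFrame(
        {
            "id": df["SNP"].astype(str).to_numpy(),
            "chrom": df["CHR"].astype(str).to_numpy(),
            "pos": df["BP"].astype(np.int64).to_numpy() if len(df) else np.array([], dtype=np.int64),
            "ea": df["EA"].astype(str).to_numpy(),
            "nea": df["NEA"].astype(str).to_numpy(),
            "eaf": df["EAF"].astype(float).to_numpy(),
            "beta": df["BETA"].astype(float).to_numpy(),
            "se": df["SE"].astype(float).to_numpy(),
            "p": df["P"].astype(float).to_numpy(),
            "n": df["N"].astype(float).to_numpy(),
        }
    )
    return SummaryStatsTable(table), report


def write_sumstats(ss: SummaryStatsTable, path: str) -> None:
    t = ss.table
    out = pd.DataFrame(
        {
            "SNP": t["id"], "CHR": t["chrom"], "BP": t["pos"], "EA": t["ea"],
            "NEA": t["nea"], "EAF": t["eaf"], "BETA": t["beta"], "SE": t["se"],
            "P": t["p"], "N": t["n"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Risk-variant sets (base-study weights)


def read_riskset(path: str) -> pd.DataFrame:
    """Read a risk-variant TSV: ``SNP EA NEA LOG_OR`` (+ optional ``P``).

    Returns the canonical weight frame with columns id, ea, nea, weight, p.
    """
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str})
    for col in RISKSET_HEADER:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing mandatory column {col!r}")
    if df["SNP"].duplicated().any():
        raise ValidationError(f"{path}: duplicate SNP ids")
    if not np.isfinite(df["LOG_OR"].astype(float)).all():
        raise ValidationError(f"{path}: non-finite LOG_OR")
    out = pd.DataFrame(
        {
            "id": df["SNP"].astype(str),
            "ea": df["EA"].astype(str),
            "nea": df["NEA"].astype(str),
            "weight": df["LOG_OR"].astype(float),
            "p": df["P"].astype(float) if "P" in df.columns else np.nan,
        }
    )
    return out


def write_riskset(rs: pd.DataFrame, path: str) -> None:
    out = pd.DataFrame(
        {"SNP": rs["id"], "EA": rs["ea"], "NEA": rs["nea"], "LOG_OR": rs["weight"],
         "P": rs["p"] if "p" in rs.columns else np.nan}
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# LD blocks (BED3)


def read_ld_blocks(path: str) -> LDBlockSet:
    """Read 3-column BED; output is sorted and validated (no overlaps)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end"], dtype={"chrom": str})
    return LDBlockSet(df)


def write_ld_blocks(blocks: LDBlockSet, path: str) -> None:
    blocks.table.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Phenotypes


def read_pheno(path: str) -> PhenotypeTable:
    """Read phenotype TSV with header IID, GROUP and optional C1..Ck."""
    df = pd.read_csv(path, sep="\t", dtype={"IID": str})
    for col in PHENO_BASE_HEADER:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing mandatory column {col!r}")
    return PhenotypeTable(df.set_index("IID"))


def write_pheno(pheno: PhenotypeTable, path: str) -> None:
    pheno.table.rename_axis("IID").reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Run config (flat key-value file)


def read_config(path: str) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    if not isinstance(d, dict):
        raise ValidationError(f"{path}: config must be a flat key-value mapping")
    return RunConfig.from_dict(d)


def write_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Validation entry point (CLI `comorbigen validate`)

_READERS = {
    "vcf": read_vcf,
    "sumstats": read_sumstats,
    "bed": read_ld_blocks,
    "pheno": read_pheno,
    "config": read_config,
}


def validate_file(path: str, kind: str) -> str:
    """Parse ``path`` as ``kind`` and return a one-line summary; raises on error."""
    if kind not in _READERS:
        raise ValidationError(f"unknown kind {kind!r}; choose from {sorted(_READERS)}")
    obj = _READERS[kind](path)
    if kind == "vcf":
        return f"OK vcf: {obj.n_samples} samples x {obj.n_variants} variants"
    if kind == "sumstats":
        table, report = obj
        return f"OK sumstats: {len(table)} variants kept, {report.n_rejected} rejected"
    if kind == "bed":
        return f"OK bed: {len(obj)} LD blocks"
    if kind == "pheno":
        return f"OK pheno: {len(obj.table)} samples"
    return "OK config"
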