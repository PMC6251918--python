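"""End-to-end orchestration of the study replica.

Stages (in order): simulate -> qc -> gwas -> prs -> overlap -> coloc ->
ldsc.  Each stage reads its inputs from and writes its outputs to one run
directory, so any suffix of the stage list can be re-run against existing
upstream outputs.  A manifest records the config hash, per-stage output
digests and wall-clock, and re-running with the same config and seed
reproduces identical digests.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__
from . import assoc, coloc, io_formats, ldsc, overlap, prs, qc
from .datatypes import RunConfig, ValidationError
from .synthetic_data import SimulationSpec, simulate_study, write_study

STAGES = ("simulate", "qc", "gwas", "prs", "overlap", "coloc", "ldsc")

_STAGE_INPUTS = {
    "simulate": (),
    "qc": ("study.vcf", "study.pheno.tsv"),
    "gwas": ("clean.vcf", "pheno_mds.tsv"),
    "prs": ("clean.vcf", "pheno_mds.tsv", "study.base1.tsv", "study.base2.tsv"),
    "overlap": ("clean.vcf", "study.base1.tsv", "study.base2.tsv"),
    "coloc": ("study.base1.tsv", "study.base2.tsv", "study.blocks.bed"),
    "ldsc": ("clean.vcf", "study.base1.tsv", "study.base2.tsv"),
}


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str = __version__
    stages: dict = field(default_factory=dict)  # name -> {files: {path: sha}, seconds}

    def to_json(self) -> str:
        return json.dumps(
            {"config_hash": self.config_hash, "seed": self.seed,
             "version": self.version, "stages": self.stages},
            indent=2, sort_keys=True,
        )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(cfg: RunConfig, spec: SimulationSpec) -> str:
    payload = json.dumps(
        {"config": cfg.to_dict(), "spec": vars(spec)}, sort_keys=True, default=str
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from one global seed."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _require(out_dir: str, stage: str) -> None:
    for fname in _STAGE_INPUTS[stage]:
        if not os.path.exists(os.path.join(out_dir, fname)):
            raise ValidationError(
                f"stage {stage!r}: missing upstream output {fname!r} in {out_dir}"
            )


def run_pipeline(
    cfg: RunConfig,
    out_dir: str,
    spec: SimulationSpec | None = None,
    stages: tuple = STAGES,
) -> RunManifest:
    """Execute the requested stages in order, halting on failure."""
    os.makedirs(out_dir, exist_ok=True)
    spec = spec if spec is not None else SimulationSpec(seed=stage_seed(cfg.seed, "simulate"))
    manifest = RunManifest(_config_hash(cfg, spec), cfg.seed)
    for stage in STAGES:
        if stage not in stages:
            continue
        _require(out_dir, stage)
        t0 = time.perf_counter()
        written = _STAGE_FUNCS[stage](cfg, spec, out_dir)
        manifest.stages[stage] = {
            "files": {os.path.basename(p): _sha256(p) for p in written},
            "seconds": round(time.perf_counter() - t0, 3),
        }
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            fh.write(manifest.to_json())
    return manifest


# ---------------------------------------------------------------------------
# Stage implementations


def _stage_simulate(cfg: RunConfig, spec: SimulationSpec, out_dir: str) -> list:
    study = simulate_study(spec)
    paths = write_study(study, out_dir, prefix="study")
    return list(paths.values())


def _stage_qc(cfg: RunConfig, spec: SimulationSpec, out_dir: str) -> list:
    ds = io_formats.read_vcf(os.path.join(out_dir, "study.vcf"))
    pheno = io_formats.read_pheno(os.path.join(out_dir, "study.pheno.tsv"))
    k = min(cfg.mds_k, ds.n_samples - 1)
    clean, comps, report = qc.run_qc(ds, replace(cfg, mds_k=k))
    pheno_kept = io_formats.PhenotypeTable(
        pheno.table.loc[[s for s in pheno.samples if s in set(clean.samples)]]
    ).with_covariates(comps)
    p_vcf = os.path.join(out_dir, "clean.vcf")
    p_pheno = os.path.join(out_dir, "pheno_mds.tsv")
    p_rep = os.path.join(out_dir, "qc_report.tsv")
    io_formats.write_vcf(clean, p_vcf)
    io_formats.write_pheno(pheno_kept, p_pheno)
    rows = [("sample", s, r) for s, r in report.removed_samples] + [
        ("variant", v, "+".join(r)) for v, r in report.removed_variants
    ]
    pd.DataFrame(rows, columns=["kind", "id", "reason"]).to_csv(
        p_rep, sep="\t", index=False
    )
    return [p_vcf, p_pheno, p_rep]


def _stage_gwas(cfg: RunConfig, spec: SimulationSpec, out_dir: str) -> list:
    ds = io_formats.read_vcf(os.path.join(out_dir, "clean.vcf"))
    pheno = io_formats.read_pheno(os.path.join(out_dir, "pheno_mds.tsv"))
    written = []
    lambdas = []
    for name, res in assoc.run_all_gwas(ds, pheno).items():
        p = os.path.join(out_dir, f"gwas_{name}.tsv")
        io_formats.write_sumstats(res.to_sumstats(), p)
        written.append(p)
        try:
            lambdas.append((name, assoc.lambda_gc(res).lam))
        except ValidationError:
            lambdas.append((name, np.nan))
    p_lam = os.path.join(out_dir, "gwas_lambda.tsv")
    pd.DataFrame(lambdas, columns=["analysis", "lambda_gc"]).to_csv(
        p_lam, sep="\t", index=False
    )
    return written + [p_lam]


_PRS_PAIRS = (
    ("SCZ", "CONTROL"), ("T2D", "CONTROL"), ("SCZplusT2D", "CONTROL"),
    ("T2D", "SCZ"), ("SCZplusT2D", "SCZ"), ("SCZplusT2D", "T2D"),
)


def _stage_prs(cfg: RunConfig, spec: SimulationSpec, out_dir: str) -> list:
    ds = io_formats.read_vcf(os.path.join(out_dir, "clean.vcf"))
    pheno = io_formats.read_pheno(os.path.join(out_dir, "pheno_mds.tsv"))
    rows = []
    means = []
    for label, fname in (("trait1", "study.base1.tsv"), ("trait2", "study.base2.tsv")):
        base, _ = io_formats.read_sumstats(os.path.join(out_dir, fname))
        clumped = prs.clump(base, ds, r2_max=cfg.clump_r2,
                            window_kb=cfg.clump_window_kb)
        established = clumped[clumped["p"] < 5e-8]
        if len(established) == 0:
            continue
        matched, _ = prs.match_alleles(established, ds)
        scores = prs.score_samples(matched, ds)
        std = (scores - scores.mean()) / scores.std(ddof=0)
        for grp in ("CONTROL", "SCZ", "SCZplusT2D", "T2D"):
            members = [s for s in pheno.group(grp) if s in scores.index]
            means.append((label, grp, float(std.loc[members].mean()),
                          float(std.loc[members].std(ddof=1) / np.sqrt(len(members)))))
        for case, ctrl in _PRS_PAIRS:
            res = prs.prs_analysis(established, ds, pheno, case, ctrl)
            rows.append((label, f"{case}_vs_{ctrl}", res.n_variants_used,
                         res.r2_full, res.r2_null, res.r2_final, res.p_assoc))
    p_sum = os.path.join(out_dir, "prs_established.tsv")
    pd.DataFrame(rows, columns=["score", "comparison", "n_variants", "r2_full",
                                "r2_null", "r2_final", "p_assoc"]).to_csv(
        p_sum, sep="\t", index=False
    )
    p_means = os.path.join(out_dir, "prs_group_means.tsv")
    pd.DataFrame(means, columns=["score", "group", "mean_std_score", "sem"]).to_csv(
        p_means, sep="\t", index=False
    )
    return [p_sum, p_means]


def _stage_overlap(cfg: RunConfig, spec: SimulationSpec, out_dir: str) -> list:
    ds = io_formats.read_vcf(os.path.join(out_dir, "clean.vcf"))
    ss1, _ = io_formats.read_sumstats(os.path.join(out_dir, "study.base1.tsv"))
    ss2, _ = io_formats.read_sumstats(os.path.join(out_dir, "study.base2.tsv"))
    results = overlap.overlap_analysis(
        ss1, ss2, ds, thresholds=cfg.overlap_thresholds, r2_max=cfg.clump_r2,
        window_kb=cfg.clump_window_kb, B=cfg.permutations,
        seed=stage_seed(cfg.seed, "overlap"),
    )
    p = os.path.join(out_dir, "overlap.tsv")
    overlap.overlap_results_frame(results).to_csv(p, sep="\t", index=False)
    return [p]


def _stage_coloc(cfg: RunConfig, spec: SimulationSpec, out_dir: str) -> list:
    ss1, _ = io_formats.read_sumstats(os.path.join(out_dir, "study.base1.tsv"))
    ss2, _ = io_formats.read_sumstats(os.path.join(out_dir, "study.base2.tsv"))
    blocks = io_formats.read_ld_blocks(os.path.join(out_dir, "study.blocks.bed"))
    priors = coloc.ColocPriors(cfg.coloc_p1, cfg.coloc_p2, cfg.coloc_p12,
                               cfg.coloc_w1, cfg.coloc_w2)
    results, _flagged = coloc.scan_genome(ss1, ss2, blocks, priors,
                                          pp_threshold=cfg.coloc_pp_threshold)
    p = os.path.join(out_dir, "coloc.tsv")
    coloc.coloc_results_frame(results).to_csv(p, sep="\t", index=False)
    return [p]


def _stage_ldsc(cfg: RunConfig, spec: SimulationSpec, out_dir: str) -> list:
    ds = io_formats.read_vcf(os.path.join(out_dir, "clean.vcf"))
    ss1, _ = io_formats.read_sumstats(os.path.join(out_dir, "study.base1.tsv"))
    ss2, _ = io_formats.read_sumstats(os.path.join(out_dir, "study.base2.tsv"))
    scores = ldsc.ld_scores(ds, window_kb=cfg.ldsc_window_kb)
    shared = len(
        set(scores.table["id"]) & set(ss1.table["id"]) & set(ss2.table["id"])
    )
    n_blocks = max(2, min(cfg.ldsc_jackknife_blocks, shared // 10))
    est = ldsc.rg_regression(ss1, ss2, scores, n_blocks=n_blocks)
    p = os.path.join(out_dir, "ldsc.tsv")
    pd.DataFrame([vars(est)]).to_csv(p, sep="\t", index=False)
    return [p]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "gwas": _stage_gwas,
    "prs": _stage_prs,
    "overlap": _stage_overlap,
    "coloc": _stage_coloc,
    "ldsc": _stage_ldsc,
}
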