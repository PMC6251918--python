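"""Shared setup for the numbered analysis scripts.

Each script re-derives the synthetic study deterministically from one seed,
so they can be run independently and in any order.
"""

from __future__ import annotations

import os
from functools import lru_cache

from comorbigen.datatypes import PhenotypeTable, RunConfig
from comorbigen.qc import run_qc
from comorbigen.synthetic_data import SimulationSpec, simulate_study

SEED = 1
RESULTS_DIR = os.path.join(os.path.dirname(__file__), "..", "results", "analysis")


def outpath(name: str) -> str:
    os.makedirs(RESULTS_DIR, exist_ok=True)
    return os.path.join(RESULTS_DIR, name)


@lru_cache(maxsize=1)
def study():
    return simulate_study(SimulationSpec(seed=SEED))


@lru_cache(maxsize=1)
def clean_study():
    """(post-QC genotypes, phenotypes with MDS covariates, QC report)."""
    st = study()
    clean, comps, report = run_qc(st.genotypes, RunConfig(seed=SEED))
    pheno = PhenotypeTable(
        st.phenotypes.table.loc[clean.samples]
    ).with_covariates(comps)
    return clean, pheno, report
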