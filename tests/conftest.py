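"""Shared fixtures: simulated cohorts and an on-disk fixture directory.

The expensive session fixtures encode the study conditions used by the
property-based checks: forward Wright-Fisher cohorts at population-scaled
selection strengths matching the recovery design (2Ns = 20 on private
genes, 2Ns*r on cooperative ones), and a small written fixture exercising
every file format, strand, missingness and spiked-variant path.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kinsig.popgen import compute_stats_table
from kinsig.synthetic_data import (
    SimulationConfig,
    generate_expression,
    simulate_outgroup,
    simulate_population,
    write_fixture,
)

settings.register_profile(
    "kinsig",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("kinsig")

RECOVERY_R = (0.25, 0.5, 1.0)
N_COHORTS = 20

# Diffusion-matched scaling of the recovery design: N=250 with s=0.04 keeps
# 2Ns identical to N=1000 with s=0.01 while staying desk-fast; u is chosen so
# that theta = 2Nu = 0.01/site and pi_N at balance ~ 2u/s = 1e-3/site.
RECOVERY_BASE = SimulationConfig(
    population_size=250,
    sample_size=31,
    gene_length_bp=600,
    per_site_mutation_rate=2e-5,
    selection_coefficient=0.04,
    true_relatedness=0.5,
    num_genes_per_class={"cooperative": 40, "private": 40, "background": 0},
    missingness_rate=0.0,
    seed=0,
)


def simulate_cohort_table(config: SimulationConfig):
    """Stats table (with category column) for one simulated cohort."""
    sim = simulate_population(config)
    table = compute_stats_table(sim.alignments)
    table["category"] = table["gene_id"].map(
        dict(zip(sim.truth["gene_id"], sim.truth["category"]))
    )
    return table


@pytest.fixture(scope="session")
def recovery_cohorts():
    """20 independent cohorts at each true r in {0.25, 0.5, 1.0}."""
    out = {}
    for r_idx, r in enumerate(RECOVERY_R):
        tables = []
        for rep in range(N_COHORTS):
            cfg = replace(
                RECOVERY_BASE, true_relatedness=r, seed=100_000 * (r_idx + 1) + rep
            )
            tables.append(simulate_cohort_table(cfg))
        out[r] = tables
    return out


SMALL_CONFIG = SimulationConfig(
    population_size=120,
    sample_size=20,
    gene_length_bp=300,
    per_site_mutation_rate=5e-5,
    selection_coefficient=0.02,
    true_relatedness=0.5,
    num_genes_per_class={"cooperative": 3, "private": 3, "background": 2},
    missingness_rate=0.1,
    outgroup_expected_Ks=0.2,
    seed=42,
)


@pytest.fixture(scope="session")
def small_sim():
    """One small cohort kept in memory, with outgroup rows attached."""
    sim = simulate_population(SMALL_CONFIG)
    refs = {a.gene_id: a.ref_seq for a in sim.alignments}
    cats = dict(zip(sim.truth["gene_id"], sim.truth["category"]))
    outgroup = simulate_outgroup(SMALL_CONFIG, refs, cats)
    for a in sim.alignments:
        a.outgroup_seq = outgroup[a.gene_id]
    return sim


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The small cohort written to disk with missingness and spiked variants."""
    sim = simulate_population(SMALL_CONFIG)
    refs = {a.gene_id: a.ref_seq for a in sim.alignments}
    cats = dict(zip(sim.truth["gene_id"], sim.truth["category"]))
    outgroup = simulate_outgroup(SMALL_CONFIG, refs, cats)
    expr = generate_expression(
        list(cats), num_timepoints=11,
        coexpressed_sets=[[g for g, c in cats.items() if c != "background"]],
        target_rho=0.4, seed=SMALL_CONFIG.seed + 1,
    )
    outdir = tmp_path_factory.mktemp("fixture")
    paths = write_fixture(
        outdir, sim.alignments, sim.truth, expr,
        outgroup_seqs=outgroup,
        missingness_rate=SMALL_CONFIG.missingness_rate,
        seed=SMALL_CONFIG.seed,
        spike_stop_gain=["coop_0001", "priv_0002"],
        spike_frameshift=["coop_0002"],
        force=True,
    )
    return {"paths": paths, "sim": sim, "outgroup": outgroup}
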