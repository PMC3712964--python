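"""Shared fixtures: simulated truth sets and cross-validation tables.

The reference-configuration cross-validation runs are session-scoped
because several analyses (headline MAF pattern, drift contrast, global-MAF
stratification) read the same five-seed experiment.
"""

from __future__ import annotations

import numpy as np
import pytest

import localpanel as lp

REFERENCE_SEEDS = (1, 2, 3, 4, 5)


def crossval_table(seed: int, drift_generations: int = 10):
    cfg = lp.SimConfig(seed=seed, drift_generations=drift_generations)
    truth = lp.simulate_populations(cfg)
    return lp.run_crossval(truth)


@pytest.fixture(scope="session")
def reference_tables():
    """Accuracy tables for the reference config, seeds 1-5."""
    return {s: crossval_table(s) for s in REFERENCE_SEEDS}


@pytest.fixture(scope="session")
def strong_drift_tables():
    """Same seeds with drift doubled (stronger divergence)."""
    return {s: crossval_table(s, drift_generations=20) for s in REFERENCE_SEEDS}


@pytest.fixture(scope="session")
def tiny_truth():
    """Small but structurally complete simulation for cheap tests."""
    cfg = lp.SimConfig(n_founders=30, n_sites=150, region_length=200_000,
                       map_length=0.2, n_global_haps=60, n_local_subjects=12,
                       drift_generations=3, seed=7)
    return lp.simulate_populations(cfg)


def make_genotype_matrix(calls, gq=None, site_qual=None, pos=None,
                         is_multimapping=None, alt=None):
    """Hand-build a GenotypeMatrix from a (N, L) call array."""
    calls = np.asarray(calls, dtype=np.int8)
    n, l = calls.shape
    if gq is None:
        gq = np.full((n, l), 60.0)
    if site_qual is None:
        site_qual = np.full(l, 100.0)
    if pos is None:
        pos = np.arange(1, l + 1) * 100
    refs = np.array(["A"] * l, dtype=object)
    alts = np.array(["C"] * l, dtype=object) if alt is None else np.asarray(alt, dtype=object)
    sites = lp.SiteMap(
        chrom=np.full(l, "1", dtype=object), pos=np.asarray(pos),
        ids=np.array([f"s{i}" for i in range(l)], dtype=object),
        ref=refs, alt=alts, cm=np.linspace(0, 0.1, l),
        is_exomic=np.ones(l, dtype=bool), is_array=np.zeros(l, dtype=bool),
        is_multimapping=(np.zeros(l, dtype=bool) if is_multimapping is None
                         else np.asarray(is_multimapping, dtype=bool)))
    subjects = np.array([f"S{i:03d}" for i in range(n)], dtype=object)
    return lp.GenotypeMatrix(subjects, sites, calls, np.asarray(gq, float),
                             np.asarray(site_qual, float))
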