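"""Reproducibility experiments: calibration, power, and cross-cohort
integration studies run entirely on synthetic cohorts.

Each experiment regenerates its data from a base seed, runs the full
pipeline (filter -> TMM -> log2 -> quantile -> permutation DE -> enrichment
-> integration), and reports summary statistics.  Problem sizes default to
desk scale: 2000 genes, 5 vs 5 samples, 300 permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .de_permutation import DeConfig, run_de
from .enrichment import enrich
from .integration import CohortResult, shared_enriched_terms
from .preprocess import preprocess_pipeline
from .synthetic_data import SimulationConfig, simulate_cohort, simulate_multi_cohort


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic sub-seeds (< 2**31) derived from one base seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) % 2**31 for s in state]


def _run_cohort(counts, fpkm, de_seed: int, n_permutations: int = 300):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        norm, _, kept = preprocess_pipeline(counts, fpkm)
        records, null, cutoff = run_de(
            norm, counts.groups,
            DeConfig(n_permutations=n_permutations, seed=de_seed),
        )
    return records, null, cutoff, kept


@dataclass
class NullCalibration:
    """Per-replicate type-I behaviour on cohorts with nothing planted."""

    t_rate: np.ndarray      # fraction of genes with empirical t p < 0.05
    deg_rate: np.ndarray    # fraction of genes passing all three DEG criteria
    ks_pvalue: np.ndarray   # KS uniformity p of the empirical t p-values


def null_calibration(
    n_replicates: int = 20,
    n_genes: int = 2000,
    n_per_group: int = 5,
    dispersion: float = 0.1,
    n_permutations: int = 300,
    seed: int = 0,
) -> NullCalibration:
    """Simulate null cohorts (no planted effects) and measure false-positive
    rates of the empirical t p-value and of the full three-criterion DEG call,
    plus KS uniformity of the empirical p-values."""
    sim_seeds = _child_seeds(seed, n_replicates)
    de_seeds = _child_seeds(seed + 1, n_replicates)
    t_rate, deg_rate, ks_p = [], [], []
    for r in range(n_replicates):
        cfg = SimulationConfig(
            n_genes=n_genes, n_per_group=n_per_group, de_fraction=0.0,
            dispersion=dispersion, seed=sim_seeds[r],
        )
        counts, fpkm, _ = simulate_cohort(cfg)
        records, _, _, _ = _run_cohort(counts, fpkm, de_seeds[r], n_permutations)
        t_rate.append((records["p_t_adj"] < 0.05).mean())
        deg_rate.append(records["is_deg"].mean())
        ks_p.append(stats.kstest(records["p_t_adj"], "uniform").pvalue)
    return NullCalibration(
        t_rate=np.array(t_rate), deg_rate=np.array(deg_rate),
        ks_pvalue=np.array(ks_p),
    )


@dataclass
class RecoveryResult:
    """Sensitivity and false-discovery proportion per planted effect size."""

    effects: tuple[float, ...]
    sensitivity: np.ndarray  # mean over replicates, one per effect
    fdp: np.ndarray


def effect_recovery(
    effects: Sequence[float] = (0.5, 1.0, 2.0),
    n_replicates: int = 5,
    n_genes: int = 2000,
    de_fraction: float = 0.10,
    dispersion: float = 0.1,
    n_permutations: int = 300,
    seed: int = 0,
) -> RecoveryResult:
    """Plant DE genes at each effect size and measure how many the
    three-criterion call recovers, and how many calls are false."""
    sens_by_effect, fdp_by_effect = [], []
    for e_idx, effect in enumerate(effects):
        sim_seeds = _child_seeds(seed + 100 + e_idx, n_replicates)
        de_seeds = _child_seeds(seed + 200 + e_idx, n_replicates)
        sens, fdp = [], []
        for r in range(n_replicates):
            cfg = SimulationConfig(
                n_genes=n_genes, de_fraction=de_fraction,
                effect_log2fc=effect, dispersion=dispersion, seed=sim_seeds[r],
            )
            counts, fpkm, truth = simulate_cohort(cfg)
            records, _, _, _ = _run_cohort(counts, fpkm, de_seeds[r], n_permutations)
            up = set(records.loc[records["direction"] == "up", "gene_id"])
            down = set(records.loc[records["direction"] == "down", "gene_id"])
            tp = len(up & truth.de_genes_up) + len(down & truth.de_genes_down)
            called = len(up) + len(down)
            planted = len(truth.de_genes_up) + len(truth.de_genes_down)
            sens.append(tp / planted)
            fdp.append(1.0 - tp / called if called else 0.0)
        sens_by_effect.append(np.mean(sens))
        fdp_by_effect.append(np.mean(fdp))
    return RecoveryResult(
        effects=tuple(effects),
        sensitivity=np.array(sens_by_effect),
        fdp=np.array(fdp_by_effect),
    )


@dataclass
class IntegrationRecovery:
    """Cross-cohort pathway-level integration on planted-term scenarios."""

    n_replicates: int
    recovered: int           # replicates where the planted term is shared
    spurious_shared: int     # replicates with any non-planted shared term
    max_pairwise_jaccard: float  # over up-DEG lists, all replicates


def multi_cohort_integration(
    n_replicates: int = 10,
    n_cohorts: int = 3,
    n_genes: int = 2000,
    de_fraction: float = 0.05,
    effect_log2fc: float = 1.0,
    shared_term_size: int = 200,
    overlap_fraction: float = 0.05,
    n_permutations: int = 300,
    seed: int = 0,
) -> IntegrationRecovery:
    """Simulate cohorts whose planted up-genes share one annotation term but
    little gene identity, run the full per-cohort pipeline, and check that
    pathway-level intersection recovers the planted term while gene-level
    overlap (Jaccard of up-DEG lists) stays small."""
    recovered = spurious = 0
    max_jac = 0.0
    for rep in range(n_replicates):
        cohort_seeds = _child_seeds(seed + 300 + rep, n_cohorts)
        de_seeds = _child_seeds(seed + 400 + rep, n_cohorts)
        cfgs = [
            SimulationConfig(
                n_genes=n_genes, de_fraction=de_fraction,
                effect_log2fc=effect_log2fc, seed=cohort_seeds[i],
            )
            for i in range(n_cohorts)
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            cohorts, annotation = simulate_multi_cohort(
                cfgs, shared_term_size, overlap_fraction
            )
        results = []
        for i, c in enumerate(cohorts):
            records, _, _, kept = _run_cohort(
                c.counts, c.fpkm, de_seeds[i], n_permutations
            )
            up = records.loc[records["direction"] == "up", "gene_id"].tolist()
            down = records.loc[records["direction"] == "down", "gene_id"].tolist()
            background = set(kept)
            results.append(
                CohortResult(
                    cohort_id=c.cohort_id, up=up, down=down,
                    enriched_up=enrich(set(up) & background, background, annotation),
                    enriched_down=enrich(set(down) & background, background, annotation),
                )
            )
        shared = shared_enriched_terms(results, "up")
        planted = cohorts[0].truth.planted_term
        if planted in shared:
            recovered += 1
        if shared - {planted}:
            spurious += 1
        for a, b in combinations(results, 2):
            union = set(a.up) | set(b.up)
            if union:
                max_jac = max(max_jac, len(set(a.up) & set(b.up)) / len(union))
    return IntegrationRecovery(
        n_replicates=n_replicates, recovered=recovered,
        spurious_shared=spurious, max_pairwise_jaccard=max_jac,
    )
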