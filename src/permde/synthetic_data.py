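"""Synthetic whole-blood-style RNA-seq cohorts, gene-set annotations, and
qPCR plates with the statistical structure the downstream analysis assumes.

The generator emulates a small two-group sequencing study (typically 5 case
vs 5 control samples): negative-binomial gene counts over a log-normal
baseline abundance profile, a planted fraction of differentially expressed
genes at a fixed |log2 fold-change|, and FPKM derived from the counts via
simulated gene lengths.  Multi-cohort scenarios plant largely disjoint DE
gene sets that are nevertheless drawn from one shared annotation term, so
that gene-level overlap is low while pathway-level integration can recover
the shared term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    CASE,
    CONTROL,
    CountMatrix,
    FpkmMatrix,
    GeneSetCollection,
    QpcrPlate,
    ValidationError,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated two-group cohort.

    ``dispersion`` is the negative-binomial dispersion phi in
    Var = mu + phi * mu^2, held constant across genes.  ``effect_log2fc`` is
    the planted |log2 fold-change|, split symmetrically between the groups
    (+-effect/2) so library-size totals stay balanced.
    """

    n_genes: int
    n_per_group: int = 5
    de_fraction: float = 0.0
    effect_log2fc: float = 0.0
    dispersion: float = 0.1
    mean_library_size: float = 1e6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_per_group <= 0:
            raise ValidationError("n_genes and n_per_group must be positive")
        if not (0 <= self.de_fraction < 1):
            raise ValidationError("de_fraction must be in [0, 1)")
        if self.effect_log2fc < 0:
            raise ValidationError("effect_log2fc must be non-negative")
        if self.dispersion <= 0 or self.mean_library_size <= 0:
            raise ValidationError("dispersion and mean_library_size must be positive")

    @property
    def n_de(self) -> int:
        return int(round(self.de_fraction * self.n_genes))


@dataclass
class GroundTruth:
    """Identities of the planted DE genes and, in multi-cohort scenarios,
    the shared annotation term they were drawn from."""

    de_genes_up: frozenset[str] = frozenset()
    de_genes_down: frozenset[str] = frozenset()
    planted_term: str | None = None

    def __post_init__(self) -> None:
        if self.de_genes_up & self.de_genes_down:
            raise ValidationError("up and down planted sets must be disjoint")


@dataclass
class SimulatedCohort:
    cohort_id: str
    counts: CountMatrix
    fpkm: FpkmMatrix
    truth: GroundTruth


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    # Gamma-Poisson mixture: lambda ~ Gamma(1/phi, scale=mu*phi) gives
    # marginal NB with Var = mu + phi*mu^2.
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    return rng.poisson(lam)


def _generate_cohort(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    genes: list[str],
    up: frozenset[str],
    down: frozenset[str],
    planted_term: str | None = None,
    cohort_id: str = "cohort",
) -> SimulatedCohort:
    n_genes, n = cfg.n_genes, cfg.n_per_group
    # Baseline relative abundances: log-normal so that dynamic range is wide
    # enough for the FPKM expressed-gene filter to have bite.
    q = rng.lognormal(mean=0.0, sigma=1.5, size=n_genes)
    q /= q.sum()
    lengths_kb = rng.uniform(0.5, 10.0, size=n_genes)
    lib = rng.lognormal(
        mean=np.log(cfg.mean_library_size) - 0.15**2 / 2, sigma=0.15, size=2 * n
    )

    gene_index = {g: i for i, g in enumerate(genes)}
    shift = np.zeros(n_genes)
    for g in up:
        shift[gene_index[g]] = cfg.effect_log2fc / 2
    for g in down:
        shift[gene_index[g]] = -cfg.effect_log2fc / 2

    # columns 0..n-1 = case, n..2n-1 = control
    mu = np.empty((n_genes, 2 * n))
    mu[:, :n] = np.outer(q * 2.0**shift, lib[:n])
    mu[:, n:] = np.outer(q * 2.0**-shift, lib[n:])
    counts = _nb_counts(rng, mu, cfg.dispersion)

    sample_ids = [f"{cohort_id}_case{i + 1}" for i in range(n)] + [
        f"{cohort_id}_ctrl{i + 1}" for i in range(n)
    ]
    groups = {s: (CASE if i < n else CONTROL) for i, s in enumerate(sample_ids)}
    cm = CountMatrix(
        gene_ids=list(genes), sample_ids=sample_ids, counts=counts, groups=groups
    )

    mapped_millions = counts.sum(axis=0) / 1e6
    fpkm = counts / (lengths_kb[:, None] * mapped_millions[None, :])
    fm = FpkmMatrix(
        gene_ids=list(genes),
        sample_ids=sample_ids,
        fpkm=fpkm,
        gene_lengths_kb=lengths_kb,
    )
    truth = GroundTruth(
        de_genes_up=up, de_genes_down=down, planted_term=planted_term
    )
    return SimulatedCohort(cohort_id=cohort_id, counts=cm, fpkm=fm, truth=truth)


def simulate_cohort(
    cfg: SimulationConfig, cohort_id: str = "cohort"
) -> tuple[CountMatrix, FpkmMatrix, GroundTruth]:
    """Simulate one two-group cohort; identical configs give identical output.

    Planted up-regulated genes have case-group mean ``2**effect_log2fc``
    times their control-group mean (and symmetrically for down-regulated
    genes).  FPKM = count / (gene_length_kb * mapped_reads_millions).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.n_genes)
    n_de = cfg.n_de
    if cfg.de_fraction > 0 and cfg.effect_log2fc > 0 and n_de < 1:
        warnings.warn(
            "de_fraction * n_genes rounds to zero planted genes; "
            "ground truth is empty",
            stacklevel=2,
        )
    if n_de > 0 and cfg.effect_log2fc > 0:
        chosen = rng.choice(cfg.n_genes, size=n_de, replace=False)
        half = n_de - n_de // 2
        up = frozenset(genes[i] for i in chosen[:half])
        down = frozenset(genes[i] for i in chosen[half:])
    else:
        up = down = frozenset()
    cohort = _generate_cohort(cfg, rng, genes, up, down, cohort_id=cohort_id)
    return cohort.counts, cohort.fpkm, cohort.truth


def simulate_go_annotation(
    n_terms: int,
    size_range: tuple[int, int],
    universe: list[str],
    seed: int | np.random.Generator = 0,
    prefix: str = "TERM",
) -> GeneSetCollection:
    """Random decoy terms: member genes sampled from ``universe`` without
    regard to DE status, sizes uniform in ``size_range`` (inclusive)."""
    if len(universe) == 0:
        raise ValidationError("universe must be non-empty")
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValidationError("size_range must satisfy 1 <= lo <= hi")
    if hi > len(universe):
        raise ValidationError("term sizes cannot exceed the universe size")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for i in range(1, n_terms + 1):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(universe, size=size, replace=False))
        tid = f"{prefix}{i:04d}"
        terms[tid] = (f"decoy term {i}", members)
    return GeneSetCollection(terms=terms)


def simulate_multi_cohort(
    cfgs: list[SimulationConfig],
    shared_term_size: int,
    overlap_fraction: float,
    n_decoy_terms: int = 20,
) -> tuple[list[SimulatedCohort], GeneSetCollection]:
    """Simulate >= 2 cohorts whose planted up-genes come from one shared
    annotation term but are otherwise largely distinct.

    Each pair of cohorts shares roughly ``overlap_fraction`` of its planted
    up-genes (a common core of size round(overlap_fraction * m) planted in
    every cohort; the remainder drawn disjointly from the term where
    capacity allows).  The returned annotation holds the shared term plus
    ``n_decoy_terms`` decoys of the same size, sampled without regard to DE
    status.  Down-regulated genes are planted by the same scheme from the
    non-term part of the universe.
    """
    if len(cfgs) < 2:
        raise ValidationError("need at least two cohorts")
    if not (0 <= overlap_fraction <= 1):
        raise ValidationError("overlap_fraction must be in [0, 1]")
    n_genes = cfgs[0].n_genes
    if any(c.n_genes != n_genes for c in cfgs):
        raise ValidationError("all cohorts must share one gene universe")
    if shared_term_size < max(c.n_de for c in cfgs):
        raise ValidationError(
            "shared_term_size smaller than the largest per-cohort DE count"
        )

    genes = _gene_ids(n_genes)
    rng = np.random.default_rng([abs(c.seed) % 2**31 for c in cfgs])
    term_idx = rng.choice(n_genes, size=shared_term_size, replace=False)
    term_genes = [genes[i] for i in term_idx]
    non_term = [g for g in genes if g not in set(term_genes)]

    n_up = [c.n_de - c.n_de // 2 for c in cfgs]
    n_down = [c.n_de // 2 for c in cfgs]

    def plant(pool: list[str], sizes: list[int]) -> list[frozenset[str]]:
        core_size = int(round(overlap_fraction * min(sizes))) if sizes else 0
        pool = list(pool)
        rng.shuffle(pool)
        core = pool[:core_size]
        available = pool[core_size:]
        sets = []
        used_from_available = 0
        for m in sizes:
            extra = m - core_size
            fresh = available[used_from_available : used_from_available + extra]
            if len(fresh) < extra:
                # capacity exhausted: reuse already-planted genes (overlap
                # rises above the requested fraction)
                warnings.warn(
                    "pool too small for fully disjoint planting; reusing genes",
                    stacklevel=3,
                )
                reuse = rng.choice(
                    pool[: core_size + used_from_available],
                    size=extra - len(fresh),
                    replace=False,
                )
                fresh = fresh + list(reuse)
            used_from_available += min(extra, len(fresh))
            sets.append(frozenset(core) | frozenset(fresh))
        return sets

    up_sets = plant(term_genes, n_up)
    down_sets = plant(non_term, n_down)

    term_id = "TERM_SHARED"
    terms: dict[str, tuple[str, frozenset[str]]] = {
        term_id: ("shared planted term", frozenset(term_genes))
    }
    decoys = simulate_go_annotation(
        n_decoy_terms,
        (shared_term_size, shared_term_size),
        genes,
        seed=rng,
        prefix="TERM_DECOY",
    )
    terms.update(decoys.terms)
    annotation = GeneSetCollection(terms=terms)

    cohorts = []
    for i, cfg in enumerate(cfgs):
        cohort = _generate_cohort(
            cfg,
            np.random.default_rng(cfg.seed),
            genes,
            up_sets[i],
            down_sets[i],
            planted_term=term_id,
            cohort_id=f"cohort{i + 1}",
        )
        cohorts.append(cohort)
    return cohorts, annotation


def simulate_qpcr_plate(
    n_per_group: int,
    group_delta_ct: float,
    noise_sd: float,
    seed: int = 0,
    base_ct_target: float = 24.0,
    base_ct_reference: float = 18.0,
) -> QpcrPlate:
    """Simulate a qPCR plate for one target gene.

    The case group's target CT is lowered by ``group_delta_ct`` cycles
    (lower CT means higher expression, so a positive ``group_delta_ct``
    plants case-group up-regulation by a factor ``2**group_delta_ct``).
    Independent Gaussian noise with sd ``noise_sd`` is added to each CT
    channel.
    """
    if n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n = n_per_group
    rows = []
    for grp, tgt_base in ((CASE, base_ct_target - group_delta_ct), (CONTROL, base_ct_target)):
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{grp}{i + 1}",
                    "group": grp,
                    "ct_target": tgt_base + rng.normal(0.0, noise_sd),
                    "ct_reference": base_ct_reference + rng.normal(0.0, noise_sd),
                }
            )
    return QpcrPlate(samples=pd.DataFrame(rows))
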