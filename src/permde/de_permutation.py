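"""Per-gene differential-expression testing against permutation empirical
nulls, with Stouffer combination and three-criterion DEG calling.

For each gene the observed two-sample t-statistic and log2 fold-change
(case minus control on the log2 matrix) are referred to empirical null
distributions obtained by recomputing both statistics under random
relabelings of the samples and pooling the draws across genes.  The two
empirical ("adjusted") p-values are combined with Stouffer's method, and a
gene is called a DEG when the combined p, the t-test p, and the absolute
log2 fold-change all pass their thresholds.  For datasets whose null
fold-change spread differs, the fold-change cutoff can be derived
adaptively from percentiles of the null fold-change distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm, t as t_dist

from .io_formats import CASE, CONTROL, ValidationError
from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)

P_CLIP = 1e-15


@dataclass(frozen=True)
class DeConfig:
    """Thresholds and permutation settings for DEG calling.

    ``fc_cutoff`` is either a positive absolute-log2FC cutoff (0.58, i.e.
    1.5-fold, by default) or the string ``"adaptive"``, in which case the
    cutoff is the mean of the absolute values of a symmetric percentile
    pair of the null fold-change distribution.
    """

    n_permutations: int = 300
    seed: int = 0
    alpha_combined: float = 0.05
    alpha_t: float = 0.05
    fc_cutoff: float | str = 0.58
    percentile_pair: tuple[float, float] = (10.0, 90.0)
    t_flavor: str = "pooled"  # or "welch"
    variance_floor_quantile: float = 0.01

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        for a in (self.alpha_combined, self.alpha_t):
            if not (0 < a < 1):
                raise ValidationError("alpha thresholds must be in (0, 1)")
        if isinstance(self.fc_cutoff, str):
            if self.fc_cutoff != "adaptive":
                raise ValidationError("fc_cutoff must be positive or 'adaptive'")
        elif self.fc_cutoff <= 0:
            raise ValidationError("fc_cutoff must be positive or 'adaptive'")
        lo, hi = self.percentile_pair
        if abs((lo + hi) / 2 - 50.0) > 1e-9:
            raise ValidationError("percentile_pair must be symmetric about 50")
        if self.t_flavor not in ("pooled", "welch"):
            raise ValidationError("t_flavor must be 'pooled' or 'welch'")


@dataclass
class NullDistributions:
    """Permutation draws of the t-statistic and log2FC, genes x permutations."""

    null_t: np.ndarray
    null_fc: np.ndarray

    def __post_init__(self) -> None:
        if self.null_t.shape != self.null_fc.shape:
            raise ValidationError("null_t and null_fc must have the same shape")
        if not (np.all(np.isfinite(self.null_t)) and np.all(np.isfinite(self.null_fc))):
            raise ValidationError("null draws must be finite")

    @property
    def pooled_t(self) -> np.ndarray:
        return self.null_t.ravel()

    @property
    def pooled_fc(self) -> np.ndarray:
        return self.null_fc.ravel()


def _group_indices(
    sample_ids: list[str], groups: Mapping[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    case = np.array([i for i, s in enumerate(sample_ids) if groups[s] == CASE])
    ctrl = np.array([i for i, s in enumerate(sample_ids) if groups[s] == CONTROL])
    if case.size < 2 or ctrl.size < 2:
        raise ValidationError("each group needs at least 2 samples")
    return case, ctrl


def _stats_for_split(
    x: np.ndarray,
    case_idx: np.ndarray,
    ctrl_idx: np.ndarray,
    flavor: str,
    floor_quantile: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-gene (t, log2fc) for one assignment of samples.

    A variance floor (the ``floor_quantile`` quantile of the per-gene scale
    estimates across genes) keeps t finite for genes with zero within-group
    variance.
    """
    a = x[:, case_idx]
    b = x[:, ctrl_idx]
    na, nb = a.shape[1], b.shape[1]
    fc = a.mean(axis=1) - b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    if flavor == "pooled":
        sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
        floor = np.quantile(sp, floor_quantile)
        sp = np.maximum(sp, max(floor, np.finfo(float).tiny))
        se = sp * np.sqrt(1.0 / na + 1.0 / nb)
    else:
        se = np.sqrt(va / na + vb / nb)
        floor = np.quantile(se, floor_quantile)
        se = np.maximum(se, max(floor, np.finfo(float).tiny))
    return fc / se, fc


def gene_statistics(
    m: NormalizedMatrix,
    groups: Mapping[str, str],
    t_flavor: str = "pooled",
    variance_floor_quantile: float = 0.01,
) -> pd.DataFrame:
    """Observed per-gene t-statistic and log2FC (case minus control).

    The default t is the Student pooled-variance two-sample statistic;
    Welch is available via ``t_flavor="welch"``.
    """
    case_idx, ctrl_idx = _group_indices(m.sample_ids, groups)
    t, fc = _stats_for_split(
        m.values, case_idx, ctrl_idx, t_flavor, variance_floor_quantile
    )
    return pd.DataFrame({"gene_id": m.gene_ids, "t_stat": t, "log2fc": fc})


def permutation_null(
    m: NormalizedMatrix,
    groups: Mapping[str, str],
    cfg: DeConfig,
    exhaustive: bool = False,
) -> NullDistributions:
    """Empirical null by random relabeling of the samples.

    Each permutation reassigns the case/control labels uniformly at random
    over all samples with group sizes preserved (assignments are sampled
    with replacement, since the requested number of permutations may exceed
    the number of distinct assignments; the identity assignment is
    allowed).  With ``exhaustive=True`` every distinct assignment is used
    exactly once instead.
    """
    case_idx, ctrl_idx = _group_indices(m.sample_ids, groups)
    n = len(m.sample_ids)
    n_case = case_idx.size
    all_idx = np.arange(n)

    if exhaustive:
        assignments = [np.array(c) for c in combinations(range(n), n_case)]
    else:
        n_distinct = comb(n, n_case)
        if cfg.n_permutations > n_distinct:
            warnings.warn(
                f"{cfg.n_permutations} permutations requested but only "
                f"{n_distinct} distinct assignments exist; sampling with "
                "replacement",
                stacklevel=2,
            )
        rng = np.random.default_rng(cfg.seed)
        assignments = [
            rng.permutation(n)[:n_case] for _ in range(cfg.n_permutations)
        ]

    null_t = np.empty((len(m.gene_ids), len(assignments)))
    null_fc = np.empty_like(null_t)
    for j, case_perm in enumerate(assignments):
        ctrl_perm = np.setdiff1d(all_idx, case_perm)
        t, fc = _stats_for_split(
            m.values, case_perm, ctrl_perm, cfg.t_flavor, cfg.variance_floor_quantile
        )
        null_t[:, j] = t
        null_fc[:, j] = fc
    return NullDistributions(null_t=null_t, null_fc=null_fc)


def empirical_pvalue(
    stat: float | np.ndarray, pooled_null: np.ndarray
) -> float | np.ndarray:
    """Two-tailed empirical p-value against a pooled null.

    p = (#{|null| >= |stat|} + 1) / (N + 1), so p is always in (0, 1].
    """
    null_abs = np.sort(np.abs(np.asarray(pooled_null).ravel()))
    n = null_abs.size
    if n == 0:
        raise ValidationError("pooled null is empty")
    stat_arr = np.abs(np.atleast_1d(np.asarray(stat, dtype=float)))
    if not np.all(np.isfinite(stat_arr)):
        raise ValidationError("statistic must be finite")
    count_ge = n - np.searchsorted(null_abs, stat_arr, side="left")
    p = (count_ge + 1.0) / (n + 1.0)
    return float(p[0]) if np.isscalar(stat) or np.asarray(stat).ndim == 0 else p


def stouffer_combine(
    p_t: float | np.ndarray, p_fc: float | np.ndarray
) -> float | np.ndarray:
    """Stouffer combination of two one-sided-coded p-values.

    z_i = Phi^-1(1 - p_i); combined z = (z_t + z_fc) / sqrt(2);
    p = 1 - Phi(z).  Inputs are clipped to [1e-15, 1 - 1e-15] first (the
    clip is logged when it triggers).
    """
    pt = np.atleast_1d(np.asarray(p_t, dtype=float))
    pf = np.atleast_1d(np.asarray(p_fc, dtype=float))
    bad = (pt <= 0) | (pt > 1) | (pf <= 0) | (pf > 1)
    if np.any(bad):
        raise ValidationError(f"{int(bad.sum())} p-value(s) outside (0, 1]")
    clipped = (pt < P_CLIP) | (pt > 1 - P_CLIP) | (pf < P_CLIP) | (pf > 1 - P_CLIP)
    if np.any(clipped):
        logger.info("clipped %d p-value pair(s) to [%g, 1-%g]", clipped.sum(), P_CLIP, P_CLIP)
    pt = np.clip(pt, P_CLIP, 1 - P_CLIP)
    pf = np.clip(pf, P_CLIP, 1 - P_CLIP)
    z = (norm.isf(pt) + norm.isf(pf)) / np.sqrt(2.0)
    p = norm.sf(z)
    if np.isscalar(p_t) and np.isscalar(p_fc):
        return float(p[0])
    return p


def adaptive_fc_cutoff(
    pooled_null_fc: np.ndarray, percentile_pair: tuple[float, float] = (10.0, 90.0)
) -> float:
    """Fold-change cutoff from the null: mean of the absolute values of the
    two percentiles of the pooled null log2FC distribution."""
    x = np.asarray(pooled_null_fc).ravel()
    if x.size == 0:
        raise ValidationError("pooled null is empty")
    lo, hi = np.percentile(x, list(percentile_pair))
    return float((abs(lo) + abs(hi)) / 2.0)


def call_degs(
    records: pd.DataFrame, cfg: DeConfig, fc_cutoff: float | None = None
) -> tuple[list[str], list[str]]:
    """Three-criterion DEG call, applied in place on ``records``.

    A gene is a DEG iff p_combined < alpha_combined, p_t_adj < alpha_t, and
    |log2fc| > the fold-change cutoff; direction follows the log2FC sign.
    Returns the up- and down-regulated gene lists.
    """
    if fc_cutoff is None:
        if isinstance(cfg.fc_cutoff, str):
            raise ValidationError(
                "adaptive fc_cutoff must be resolved against a null first "
                "(see adaptive_fc_cutoff / run_de)"
            )
        fc_cutoff = float(cfg.fc_cutoff)
    is_deg = (
        (records["p_combined"] < cfg.alpha_combined)
        & (records["p_t_adj"] < cfg.alpha_t)
        & (records["log2fc"].abs() > fc_cutoff)
    )
    direction = np.where(
        ~is_deg, "none", np.where(records["log2fc"] > 0, "up", "down")
    )
    records["is_deg"] = is_deg.to_numpy()
    records["direction"] = direction
    up = records.loc[records["direction"] == "up", "gene_id"].tolist()
    down = records.loc[records["direction"] == "down", "gene_id"].tolist()
    return up, down


def run_de(
    m: NormalizedMatrix,
    groups: Mapping[str, str],
    cfg: DeConfig,
    exhaustive: bool = False,
) -> tuple[pd.DataFrame, NullDistributions, float]:
    """Full DE test on a normalized matrix.

    Returns a per-gene record table (log2fc, t_stat, the two empirical
    adjusted p-values, parametric t-test p for reference, Stouffer-combined
    p, DEG flag and direction), the null distributions, and the fold-change
    cutoff actually used.
    """
    obs = gene_statistics(m, groups, cfg.t_flavor, cfg.variance_floor_quantile)
    null = permutation_null(m, groups, cfg, exhaustive=exhaustive)
    p_t = empirical_pvalue(obs["t_stat"].to_numpy(), null.pooled_t)
    p_fc = empirical_pvalue(obs["log2fc"].to_numpy(), null.pooled_fc)
    p_comb = stouffer_combine(p_t, p_fc)

    case_idx, ctrl_idx = _group_indices(m.sample_ids, groups)
    df_param = case_idx.size + ctrl_idx.size - 2
    p_t_param = 2.0 * t_dist.sf(np.abs(obs["t_stat"].to_numpy()), df_param)

    records = obs.assign(
        p_t_adj=p_t, p_fc_adj=p_fc, p_combined=p_comb, p_t_param=p_t_param
    )
    if cfg.fc_cutoff == "adaptive":
        cutoff = adaptive_fc_cutoff(null.pooled_fc, cfg.percentile_pair)
    else:
        cutoff = float(cfg.fc_cutoff)
    call_degs(records, cfg, fc_cutoff=cutoff)
    return records, null, cutoff
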