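"""Expressed-gene filtering and the normalization cascade.

The pipeline order is fixed: filter on the FPKM matrix, then TMM scaling
factors on the counts of the retained genes, then log2(count + 1), then
quantile normalization.  Permuting the order changes results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.stats import rankdata

from .io_formats import (
    CASE,
    CONTROL,
    CountMatrix,
    FpkmMatrix,
    ValidationError,
)


@dataclass
class NormalizationFactors:
    """Per-sample library sizes and TMM scale factors.

    The TMM factors are rescaled to geometric mean 1.  ``scaling`` is the
    relative effective library size (library_size * tmm_factor divided by
    its geometric mean); dividing counts by it puts all samples on a common
    depth while staying on the raw-count scale.
    """

    sample_ids: list[str]
    library_size: np.ndarray
    tmm_factor: np.ndarray
    reference_sample: str

    def __post_init__(self) -> None:
        self.library_size = np.asarray(self.library_size)
        self.tmm_factor = np.asarray(self.tmm_factor, dtype=float)
        if np.any(self.tmm_factor <= 0) or not np.all(np.isfinite(self.tmm_factor)):
            raise ValidationError("TMM factors must be positive and finite")
        log_gm = np.mean(np.log(self.tmm_factor))
        if abs(log_gm) > 1e-9:
            raise ValidationError("TMM factors must have geometric mean 1")

    @property
    def effective_size(self) -> np.ndarray:
        return self.library_size * self.tmm_factor

    @property
    def scaling(self) -> np.ndarray:
        eff = self.effective_size
        return eff / np.exp(np.mean(np.log(eff)))


@dataclass
class NormalizedMatrix:
    """Log2-scale expression matrix (genes x samples)."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("values shape does not match gene/sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("normalized values must be finite")


def filter_expressed(
    fpkm: FpkmMatrix,
    groups: Mapping[str, str],
    min_nonzero_fraction: float = 0.5,
    max_fpkm_cutoff: float = 1.0,
) -> list[str]:
    """Expressed-gene filter on the FPKM matrix.

    A gene is kept iff it has a nonzero FPKM in at least
    ceil(min_nonzero_fraction * group size) samples of the case OR the
    control group, AND the maximum of its nonzero FPKM values exceeds
    ``max_fpkm_cutoff``.  Input gene order is preserved.
    """
    case_idx = [i for i, s in enumerate(fpkm.sample_ids) if groups.get(s) == CASE]
    ctrl_idx = [i for i, s in enumerate(fpkm.sample_ids) if groups.get(s) == CONTROL]
    if not case_idx or not ctrl_idx:
        raise ValidationError("both case and control groups must be non-empty")
    need_case = math.ceil(min_nonzero_fraction * len(case_idx))
    need_ctrl = math.ceil(min_nonzero_fraction * len(ctrl_idx))
    x = fpkm.fpkm
    nz = x > 0
    enough = (nz[:, case_idx].sum(axis=1) >= need_case) | (
        nz[:, ctrl_idx].sum(axis=1) >= need_ctrl
    )
    max_nonzero = np.where(nz, x, 0.0).max(axis=1)
    keep = enough & (max_nonzero > max_fpkm_cutoff)
    return [g for g, k in zip(fpkm.gene_ids, keep) if k]


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Trimmed mean of M-values of one sample against the reference.

    M = log2 ratio of library-size-scaled proportions, A = mean log2
    abundance; genes with a zero count in either sample are excluded, both
    tails of M (trim_m) and A (trim_a) are trimmed, and the retained
    M-values are averaged with inverse asymptotic-variance weights.
    """
    mask = (obs > 0) & (ref > 0)
    o, r = obs[mask].astype(float), ref[mask].astype(float)
    if o.size == 0:
        raise ValidationError("no genes jointly nonzero with the reference")
    log_r = np.log2((o / n_obs) / (r / n_ref))
    abs_e = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = math.floor(n * trim_m) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * trim_a) + 1
    hi_s = n + 1 - lo_s
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not np.any(keep):
        return 1.0
    w = 1.0 / v[keep]
    return float(2.0 ** (np.sum(w * log_r[keep]) / np.sum(w)))


def tmm_factors(
    counts: CountMatrix | np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference_sample: str | None = None,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scale factors.

    ``counts`` may be a :class:`CountMatrix` or a plain genes-x-samples
    integer array (normalization needs no group labels).  The reference
    sample is the one whose upper-quartile count fraction is closest to the
    mean upper-quartile fraction (configurable).  Factors are rescaled to
    geometric mean 1.
    """
    if isinstance(counts, CountMatrix):
        x = counts.counts.astype(float)
        sample_ids = list(counts.sample_ids)
    else:
        x = np.asarray(counts, dtype=float)
        if x.ndim != 2 or x.shape[1] < 2:
            raise ValidationError("need a genes-x-samples matrix with >= 2 samples")
        sample_ids = [f"sample{j + 1}" for j in range(x.shape[1])]
    lib = x.sum(axis=0)
    if np.any(lib == 0):
        bad = sample_ids[int(np.argmax(lib == 0))]
        raise ValidationError(f"sample {bad!r} has all-zero counts")
    f75 = np.percentile(x, 75, axis=0) / lib
    if reference_sample is None:
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        if reference_sample not in sample_ids:
            raise ValidationError(f"unknown reference sample {reference_sample!r}")
        ref_idx = sample_ids.index(reference_sample)
    factors = np.array(
        [
            _tmm_pair(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
            for j in range(x.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(
        sample_ids=sample_ids,
        library_size=lib.astype(np.int64),
        tmm_factor=factors,
        reference_sample=sample_ids[ref_idx],
    )


def log_transform(
    counts: CountMatrix, factors: NormalizationFactors
) -> NormalizedMatrix:
    """log2(normalized count + 1): each sample's counts are divided by its
    relative effective library size (TMM factor x library size, rescaled to
    geometric mean 1) before the +1 log transform."""
    if list(counts.sample_ids) != list(factors.sample_ids):
        raise ValidationError("factors were computed for a different sample set")
    scaled = counts.counts / factors.scaling[None, :]
    return NormalizedMatrix(
        gene_ids=list(counts.gene_ids),
        sample_ids=list(counts.sample_ids),
        values=np.log2(scaled + 1.0),
    )


def quantile_normalize(m: NormalizedMatrix) -> NormalizedMatrix:
    """Force all samples onto one empirical distribution.

    Each sample's sorted values are replaced by the across-sample means of
    the sorted values (rank means); tied values within a sample receive the
    mean of their tied positions' rank means, so the result is deterministic.
    """
    x = m.values
    n_genes, n_samples = x.shape
    order = np.argsort(x, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(x, order, axis=0)
    rank_means = sorted_vals.mean(axis=1)
    out = np.empty_like(x)
    for j in range(n_samples):
        col_sorted = sorted_vals[:, j]
        assigned = rank_means.copy()
        # average rank-means over runs of tied values
        start = 0
        for i in range(1, n_genes + 1):
            if i == n_genes or col_sorted[i] != col_sorted[start]:
                if i - start > 1:
                    assigned[start:i] = rank_means[start:i].mean()
                start = i
        out[order[:, j], j] = assigned
    return NormalizedMatrix(
        gene_ids=list(m.gene_ids), sample_ids=list(m.sample_ids), values=out
    )


def preprocess_pipeline(
    counts: CountMatrix,
    fpkm: FpkmMatrix,
    min_nonzero_fraction: float = 0.5,
    max_fpkm_cutoff: float = 1.0,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> tuple[NormalizedMatrix, NormalizationFactors, list[str]]:
    """Filter -> TMM -> log2(count+1) -> quantile normalization.

    The filter is computed on the FPKM matrix and applied to the count
    matrix by gene id; genes present in only one of the two matrices raise
    an error rather than being dropped silently.
    """
    count_genes = set(counts.gene_ids)
    fpkm_genes = set(fpkm.gene_ids)
    if count_genes != fpkm_genes:
        only = sorted((count_genes ^ fpkm_genes))[:10]
        raise ValidationError(
            f"count and FPKM matrices disagree on the gene universe "
            f"(e.g. {only})"
        )
    kept = filter_expressed(
        fpkm, counts.groups, min_nonzero_fraction, max_fpkm_cutoff
    )
    kept_set = set(kept)
    row_idx = [i for i, g in enumerate(counts.gene_ids) if g in kept_set]
    sub = CountMatrix(
        gene_ids=[counts.gene_ids[i] for i in row_idx],
        sample_ids=list(counts.sample_ids),
        counts=counts.counts[row_idx, :],
        groups=dict(counts.groups),
    )
    factors = tmm_factors(sub, trim_m=trim_m, trim_a=trim_a)
    logm = log_transform(sub, factors)
    return quantile_normalize(logm), factors, kept
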