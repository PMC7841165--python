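"""Validation-cohort statistics: ΔΔCT qPCR quantification, Welch and
Student t-tests, χ² tests, and clinical-characteristics table summaries.

ΔΔCT assumes a doubling per PCR cycle (amplification efficiency 2) and a
single housekeeping reference gene; technical replicates sharing a sample
id are averaged before ΔCT.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CONTROL, QpcrPlate, ValidationError


@dataclass
class DdctResult:
    """Relative quantification of one target gene.

    ``per_sample`` columns: sample_id, group, delta_ct (target minus
    reference, cycles), delta_delta_ct (relative to the control-group mean
    ΔCT, cycles), rq = 2^(−ΔΔCT) (fold, dimensionless).  ``group_stats``
    holds each group's mean rq and SEM; ``welch`` is the Welch t comparison
    of the rq values between groups.
    """

    per_sample: pd.DataFrame
    group_stats: pd.DataFrame
    welch: tuple[float, float, float]  # (t, df, p)

    def __post_init__(self) -> None:
        ctrl = self.per_sample[self.per_sample["group"] == self._control]
        if abs(ctrl["delta_delta_ct"].mean()) > 1e-12:
            raise ValidationError("control-group mean ΔΔCT must be 0")
        if (self.per_sample["rq"] <= 0).any():
            raise ValidationError("relative quantities must be positive")

    _control: str = CONTROL


def ddct_quantify(plate: QpcrPlate, control_group: str = CONTROL) -> DdctResult:
    """ΔΔCT relative quantification against the plate's reference gene.

    ΔCT = CT_target − CT_reference per sample; ΔΔCT = ΔCT minus the
    control group's mean ΔCT; RQ = 2^(−ΔΔCT).  Groups are compared with a
    Welch t-test on the RQ values.
    """
    df = plate.samples.copy()
    if df[["ct_target", "ct_reference"]].isna().any().any():
        raise ValidationError("missing CT value on plate")
    # technical replicates: average CTs per sample id
    df = (
        df.groupby(["sample_id", "group"], as_index=False, sort=False)[
            ["ct_target", "ct_reference"]
        ].mean()
    )
    if control_group not in set(df["group"]):
        raise ValidationError(f"control group {control_group!r} not on plate")
    df["delta_ct"] = df["ct_target"] - df["ct_reference"]
    ctrl_mean = df.loc[df["group"] == control_group, "delta_ct"].mean()
    df["delta_delta_ct"] = df["delta_ct"] - ctrl_mean
    df["rq"] = 2.0 ** (-df["delta_delta_ct"])

    group_stats = (
        df.groupby("group")["rq"]
        .agg(mean_rq="mean", sem_rq=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
        .reset_index()
    )
    groups = [g for g in df["group"].unique() if g != control_group]
    welch = (float("nan"),) * 3
    if groups:
        a = df.loc[df["group"] == groups[0], "rq"].to_numpy()
        b = df.loc[df["group"] == control_group, "rq"].to_numpy()
        try:
            welch = welch_t(a, b)
        except ValidationError:
            # degenerate plate (singleton group or both groups constant):
            # quantification is still valid, only the comparison is undefined
            pass
    return DdctResult(
        per_sample=df, group_stats=group_stats, welch=welch, _control=control_group
    )


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Unpaired t-test with Welch's correction: (t, Welch–Satterthwaite df,
    two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs >= 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValidationError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def student_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Student pooled-variance two-sample t-test: (t, df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs >= 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValidationError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(a.size + b.size - 2), float(res.pvalue)


def chi2_test(
    table: Sequence[Sequence[float]],
    correction: bool = False,
    fisher: bool = False,
) -> tuple[float, float, float]:
    """Pearson χ² test of independence on a 2 x k count table.

    Continuity (Yates) correction is off by default; for 2 x 2 tables with
    small cells a Fisher exact test is available via ``fisher=True`` (the
    returned statistic is then the odds ratio and df is 0).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] != 2:
        raise ValidationError("table must be 2 x k")
    if np.any(obs < 0):
        raise ValidationError("counts must be non-negative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValidationError("degenerate margins: zero row or column sum")
    if fisher:
        if obs.shape != (2, 2):
            raise ValidationError("Fisher exact requires a 2 x 2 table")
        odds, p = stats.fisher_exact(obs)
        return float(odds), 0.0, float(p)
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=correction)
    return float(chi2), float(df), float(p)


def percentage(count: int, group_n: int) -> float:
    """Percent of a group, rounded to one decimal (Table-style summary)."""
    if group_n <= 0:
        raise ValidationError("group n must be positive")
    return round(100.0 * count / group_n, 1)


@dataclass
class ClinicalTable:
    """Two-group clinical characteristics.

    ``continuous`` maps variable -> {group: per-subject values};
    ``categorical`` maps variable -> {group: {level: count}} with counts
    summing to the group's n.
    """

    continuous: dict[str, dict[str, np.ndarray]]
    categorical: dict[str, dict[str, dict[str, int]]]
    group_n: dict[str, int]

    def __post_init__(self) -> None:
        for var, by_group in self.categorical.items():
            for grp, levels in by_group.items():
                total = sum(levels.values())
                if total != self.group_n[grp]:
                    raise ValidationError(
                        f"{var!r}: counts for group {grp!r} sum to {total}, "
                        f"expected n={self.group_n[grp]}"
                    )


def summarize_clinical(table: ClinicalTable) -> pd.DataFrame:
    """Per-variable summary in the clinical-table idiom.

    Continuous variables: mean ± SE (SE = sd/√n) per group and a Student
    t-test p.  Categorical variables: 'count (percent)' per level and a χ²
    p over the 2 x k level table.
    """
    groups = list(table.group_n)
    rows = []
    for var, by_group in table.continuous.items():
        entry: dict[str, object] = {"variable": var, "level": ""}
        for grp in groups:
            v = np.asarray(by_group[grp], dtype=float)
            se = v.std(ddof=1) / np.sqrt(v.size)
            entry[grp] = f"{v.mean():.1f} ± {se:.1f}"
        _, _, p = student_t(by_group[groups[0]], by_group[groups[1]])
        entry["p_value"] = p
        entry["test"] = "student_t"
        rows.append(entry)
    for var, by_group in table.categorical.items():
        levels = sorted({lvl for d in by_group.values() for lvl in d})
        counts = [[by_group[g].get(lvl, 0) for lvl in levels] for g in groups]
        try:
            _, _, p = chi2_test(counts)
        except ValidationError:
            p = float("nan")
        for i, lvl in enumerate(levels):
            entry = {"variable": var, "level": lvl}
            for g in groups:
                c = by_group[g].get(lvl, 0)
                entry[g] = f"{c} ({percentage(c, table.group_n[g]):.1f})"
            entry["p_value"] = p if i == 0 else float("nan")
            entry["test"] = "chi2" if i == 0 else ""
            rows.append(entry)
    return pd.DataFrame(rows)
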