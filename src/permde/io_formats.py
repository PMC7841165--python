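"""Readers, writers and validated in-memory containers for every artifact the
pipeline touches.

All on-disk formats are plain TSV (matrices, two-column sample sheets,
results tables) or GMT (gene sets).  Gene identity is the string id as given;
no symbol or alias resolution is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"


class FormatError(ValueError):
    """A file or table violates the format contract."""


class ValidationError(ValueError):
    """An in-memory container violates its invariants."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what}: {i!r}")
        seen.add(i)


@dataclass
class CountMatrix:
    """Raw gene-level integer counts (genes x samples) with two-group labels.

    ``groups`` maps every sample id to ``"case"`` or ``"control"``; each group
    must contain at least two samples so that within-group variances exist.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.asarray(self.counts)
            if not np.all(np.isfinite(as_int.astype(float))) or np.any(
                as_int.astype(float) != np.floor(as_int.astype(float))
            ):
                bad = np.argwhere(as_int.astype(float) != np.floor(as_int.astype(float)))
                g, s = bad[0]
                raise ValidationError(
                    f"non-integer count {as_int[g, s]!r} for gene "
                    f"{self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
                )
            self.counts = as_int.astype(np.int64)
        if np.any(self.counts < 0):
            g, s = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count for gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        missing = [s for s in self.sample_ids if s not in self.groups]
        if missing:
            raise ValidationError(f"samples missing from sample sheet: {missing}")
        bad_labels = sorted({v for v in self.groups.values()} - {CASE, CONTROL})
        if bad_labels:
            raise ValidationError(
                f"group labels must be {{'case', 'control'}}, got extras {bad_labels}"
            )
        for grp in (CASE, CONTROL):
            n = sum(1 for s in self.sample_ids if self.groups[s] == grp)
            if n < 2:
                raise ValidationError(
                    f"group {grp!r} has {n} sample(s); at least 2 required"
                )

    @property
    def case_indices(self) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.sample_ids) if self.groups[s] == CASE]
        )

    @property
    def control_indices(self) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.sample_ids) if self.groups[s] == CONTROL]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class FpkmMatrix:
    """Length- and depth-normalised expression (FPKM), genes x samples.

    Used only for the expressed-gene filter.  ``gene_lengths_kb`` is carried
    along when the matrix was simulated, so counts -> FPKM round-trips.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    fpkm: np.ndarray
    gene_lengths_kb: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fpkm = np.asarray(self.fpkm, dtype=float)
        if self.fpkm.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"fpkm shape {self.fpkm.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if not np.all(np.isfinite(self.fpkm)):
            raise ValidationError("FPKM values must be finite")
        if np.any(self.fpkm < 0):
            raise ValidationError("FPKM values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fpkm, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GeneSetCollection:
    """Annotation terms: term id -> (human-readable name, member gene set)."""

    terms: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, (_name, members) in self.terms.items():
            if len(members) == 0:
                raise ValidationError(f"term {tid!r} has no member genes")

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def members(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]

    def name(self, term_id: str) -> str:
        return self.terms[term_id][0]


@dataclass
class QpcrPlate:
    """Per-sample cycle-threshold readings for one target gene and the
    reference gene (GAPDH-style housekeeping normaliser)."""

    samples: pd.DataFrame  # columns: sample_id, group, ct_target, ct_reference

    REQUIRED = ("sample_id", "group", "ct_target", "ct_reference")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.samples.columns]
        if missing:
            raise ValidationError(f"qPCR plate missing columns: {missing}")
        ct = self.samples[["ct_target", "ct_reference"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(ct)):
            raise ValidationError("CT values must be finite")
        if np.any(ct < 10) or np.any(ct > 40):
            warnings.warn(
                "CT values outside the typical 10-40 cycle range", stacklevel=2
            )


# ---------------------------------------------------------------------------
# TSV matrices and sample sheets
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample id, group) -> mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"sample sheet {path} needs >= 2 columns")
    sample_col, group_col = df.columns[:2]
    return dict(zip(df[sample_col], df[group_col]))


def write_sample_sheet(groups: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(groups), "group": [groups[s] for s in groups]}
    ).to_csv(path, sep="\t", index=False)


def _read_matrix_frame(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate gene id {dup!r} in {path}")
    return df

def read_count_matrix(path: str | Path, sample_sheet_path: str | Path) -> CountMatrix:
    """Read a genes-x-samples count TSV plus a sample sheet.

    Raises :class:`FormatError` / :class:`ValidationError` naming the
    offending row or column for duplicate gene ids, samples absent from the
    sheet, and negative or non-integer counts.
    """
    df = _read_matrix_frame(path)
    groups = read_sample_sheet(sample_sheet_path)
    missing = [s for s in df.columns if s not in groups]
    if missing:
        raise FormatError(
            f"sample(s) {missing} in {path} missing from sample sheet "
            f"{sample_sheet_path}"
        )
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"non-numeric counts in {path}")
    frac = values.astype(float) - np.floor(values.astype(float))
    if np.any(frac != 0):
        g, s = np.argwhere(frac != 0)[0]
        raise FormatError(
            f"non-integer count {values[g, s]!r} for gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r}"
        )
    if np.any(values < 0):
        g, s = np.argwhere(values < 0)[0]
        raise FormatError(
            f"negative count for gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    relevant = {s: groups[s] for s in df.columns}
    return CountMatrix(
        gene_ids=list(df.index.astype(str)),
        sample_ids=list(df.columns.astype(str)),
        counts=values.astype(np.int64),
        groups=relevant,
    )


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    cm.to_frame().rename_axis("gene_id").to_csv(path, sep="\t")


def read_fpkm_matrix(path: str | Path) -> FpkmMatrix:
    df = _read_matrix_frame(path)
    return FpkmMatrix(
        gene_ids=list(df.index.astype(str)),
        sample_ids=list(df.columns.astype(str)),
        fpkm=df.to_numpy(dtype=float),
    )


def write_fpkm_matrix(fm: FpkmMatrix, path: str | Path) -> None:
    fm.to_frame().rename_axis("gene_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Standard GMT: term <tab> description <tab> member genes...

    Duplicate member genes within a term are de-duplicated; duplicate term
    ids are an error.
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            tid, desc = fields[0], fields[1]
            if tid in terms:
                raise FormatError(f"{path}:{lineno}: duplicate term id {tid!r}")
            members = frozenset(g for g in fields[2:] if g)
            terms[tid] = (desc, members)
    return GeneSetCollection(terms=terms)


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tid, (name, members) in gsc.terms.items():
            fh.write("\t".join([tid, name, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------

def read_qpcr_plate(path: str | Path) -> QpcrPlate:
    df = pd.read_csv(path, sep="\t")
    return QpcrPlate(samples=df)


def write_qpcr_plate(plate: QpcrPlate, path: str | Path) -> None:
    plate.samples.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Results tables with a header comment recording provenance
# ---------------------------------------------------------------------------

def write_results(
    df: pd.DataFrame, path: str | Path, meta: Mapping[str, object] | None = None
) -> None:
    """Write a results table as TSV, preceded by ``# key=value`` comment lines
    recording configuration and seed."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in (meta or {}).items():
            if "=" in str(key) or "\n" in str(key) or "\n" in str(val):
                raise FormatError(f"illegal metadata entry {key!r}")
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_results(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Inverse of :func:`write_results`; returns (table, metadata)."""
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    raise FormatError(f"malformed header line in {path}: {line!r}")
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, sep="\t")
    return df, meta
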