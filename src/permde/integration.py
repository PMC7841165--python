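"""Cross-cohort comparison at the gene level (Venn region counts) and at
the pathway level (terms enriched in every cohort).

The pathway-level intersection is the step that tolerates gene-level
heterogeneity between cohorts: DE gene identities can be nearly disjoint
across studies while still pointing at one shared biological process.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .enrichment import EnrichedTerm
from .io_formats import ValidationError


@dataclass
class CohortResult:
    """One cohort's DEG lists plus direction-stratified enrichment."""

    cohort_id: str
    up: list[str]
    down: list[str]
    enriched_up: list[EnrichedTerm] = field(default_factory=list)
    enriched_down: list[EnrichedTerm] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValidationError("up and down DEG lists must be disjoint")


def venn_overlap(
    lists: list[list[str]], names: list[str] | None = None
) -> dict[str, int]:
    """Exact set arithmetic over >= 2 gene lists.

    Returns counts for all 2^m - 1 non-empty membership regions, keyed by
    '&'-joined list names (e.g. ``"A&B"`` is the genes in exactly A and B).
    Region counts sum to the union size.
    """
    if len(lists) < 2:
        raise ValidationError("need at least two lists")
    if names is None:
        names = [f"set{i + 1}" for i in range(len(lists))]
    if len(names) != len(lists):
        raise ValidationError("names must match lists")
    sets = [set(l) for l in lists]
    universe = set().union(*sets)
    counts: dict[str, int] = {}
    for r in range(1, len(sets) + 1):
        for idx in combinations(range(len(sets)), r):
            inside = set(universe)
            for i in idx:
                inside &= sets[i]
            for i in range(len(sets)):
                if i not in idx:
                    inside -= sets[i]
            counts["&".join(names[i] for i in idx)] = len(inside)
    return counts


def shared_enriched_terms(
    results: list[CohortResult], direction: str
) -> set[str]:
    """Terms whose ``enriched`` flag is true in every cohort for the given
    direction ('up' or 'down')."""
    if len(results) < 2:
        raise ValidationError("need at least two cohorts")
    if direction not in ("up", "down"):
        raise ValidationError("direction must be 'up' or 'down'")
    shared: set[str] | None = None
    for res in results:
        terms = res.enriched_up if direction == "up" else res.enriched_down
        if not terms:
            raise ValidationError(
                f"cohort {res.cohort_id!r} has no enrichment results for "
                f"direction {direction!r}"
            )
        flagged = {t.term_id for t in terms if t.enriched}
        shared = flagged if shared is None else shared & flagged
    return shared or set()


def shared_term_report(
    results: list[CohortResult], direction: str
) -> pd.DataFrame:
    """Presence matrix: one row per term seen in any cohort, one p_ease and
    one enriched column per cohort."""
    frames = {}
    for res in results:
        terms = res.enriched_up if direction == "up" else res.enriched_down
        frames[res.cohort_id] = {
            t.term_id: (t.p_ease, t.enriched) for t in terms
        }
    all_terms = sorted({tid for d in frames.values() for tid in d})
    data: dict[str, list] = {"term_id": all_terms}
    for cid, d in frames.items():
        data[f"p_ease_{cid}"] = [d.get(t, (float("nan"), False))[0] for t in all_terms]
        data[f"enriched_{cid}"] = [d.get(t, (float("nan"), False))[1] for t in all_terms]
    return pd.DataFrame(data)


def overlap_with_reference(
    up: list[str], down: list[str], reference_panel: set[str]
) -> tuple[set[str], dict[str, int]]:
    """Intersection of a DEG list with an external reference gene panel,
    split by direction."""
    if not reference_panel:
        raise ValidationError("reference panel must be non-empty")
    up_hit = set(up) & set(reference_panel)
    down_hit = set(down) & set(reference_panel)
    return up_hit | down_hit, {"up": len(up_hit), "down": len(down_hit)}
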