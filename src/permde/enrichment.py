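"""Gene-set over-representation with the EASE-score variant of the
one-sided Fisher exact test.

The EASE score is a conservative variant used by the DAVID tool: one gene
is removed from the overlap before taking the hypergeometric upper tail, so
single-gene overlaps can never look significant.  Following the original
analysis style, no multiple-testing correction enters the enrichment flag;
a Benjamini-Hochberg column is emitted for information only.  Up- and
down-regulated gene lists are meant to be tested separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection, ValidationError


@dataclass
class EnrichedTerm:
    """One term's over-representation result.

    k of the n query genes fall in the term, which has K members among the
    N background genes.  ``enriched`` requires p_ease < alpha and
    k >= min_count.
    """

    term_id: str
    name: str
    overlap_genes: frozenset[str]
    k: int
    K: int
    n: int
    N: int
    p_ease: float
    p_fisher: float
    p_bh: float
    enriched: bool

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n) <= self.N):
            raise ValidationError(
                f"inconsistent contingency margins for term {self.term_id!r}"
            )
        if self.p_ease < self.p_fisher - 1e-12:
            raise ValidationError("p_ease must be >= p_fisher")


def ease_test_batch(
    k: np.ndarray, K: int, n: int, N: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`ease_test` over overlap counts ``k`` for one fixed
    set of margins.  Returns (p_ease, p_fisher) arrays."""
    k = np.asarray(k, dtype=int)
    if not (0 <= min(K, n) <= N) or K > N or n > N:
        raise ValidationError(f"inconsistent margins: K={K}, n={n}, N={N}")
    if np.any(k < np.maximum(0, K + n - N)) or np.any(k > min(K, n)):
        raise ValidationError(f"overlap k outside support for K={K}, n={n}, N={N}")
    p_fisher = hypergeom.sf(k - 1, N, K, n)
    p_ease = hypergeom.sf(np.maximum(k - 1, 0) - 1, N, K, n)
    return np.minimum(p_ease, 1.0), np.minimum(p_fisher, 1.0)


def ease_test(k: int, K: int, n: int, N: int) -> tuple[float, float]:
    """EASE and Fisher upper-tail p for a k/K/n/N overlap.

    p_fisher = P(X >= k) under Hypergeom(N, K, n); p_ease is the same tail
    with the overlap reduced by one success (max(k-1, 0)).
    """
    p_ease, p_fisher = ease_test_batch(np.array([k]), K, n, N)
    return float(p_ease[0]), float(p_fisher[0])


def enrich(
    query: set[str],
    background: set[str],
    sets: GeneSetCollection,
    alpha: float = 0.05,
    min_count: int = 5,
) -> list[EnrichedTerm]:
    """Over-representation of ``query`` against every term in ``sets``.

    Term memberships are intersected with ``background`` before testing.
    Results are sorted by p_ease ascending, ties broken by term id.
    """
    query = set(query)
    background = set(background)
    offenders = sorted(query - background)
    if offenders:
        raise ValidationError(
            f"query genes absent from background: {offenders[:10]}"
        )
    N = len(background)
    n = len(query)
    rows = []
    for tid in sorted(sets.terms):
        name, members = sets.terms[tid]
        members_bg = members & background
        K = len(members_bg)
        if K == 0:
            continue
        overlap = frozenset(query & members_bg)
        k = len(overlap)
        p_ease, p_fisher = ease_test(k, K, n, N)
        rows.append((tid, name, overlap, k, K, p_ease, p_fisher))
    if not rows:
        return []
    p_bh = multipletests([r[5] for r in rows], method="fdr_bh")[1]
    out = [
        EnrichedTerm(
            term_id=tid,
            name=name,
            overlap_genes=overlap,
            k=k,
            K=K,
            n=n,
            N=N,
            p_ease=p_ease,
            p_fisher=p_fisher,
            p_bh=float(bh),
            enriched=bool(p_ease < alpha and k >= min_count),
        )
        for (tid, name, overlap, k, K, p_ease, p_fisher), bh in zip(rows, p_bh)
    ]
    out.sort(key=lambda t: (t.p_ease, t.term_id))
    return out


def terms_to_frame(terms: list[EnrichedTerm]) -> pd.DataFrame:
    """Flatten enrichment results for TSV output."""
    return pd.DataFrame(
        {
            "term_id": [t.term_id for t in terms],
            "name": [t.name for t in terms],
            "k": [t.k for t in terms],
            "K": [t.K for t in terms],
            "n": [t.n for t in terms],
            "N": [t.N for t in terms],
            "p_ease": [t.p_ease for t in terms],
            "p_fisher": [t.p_fisher for t in terms],
            "p_bh": [t.p_bh for t in terms],
            "enriched": [t.enriched for t in terms],
            "overlap_genes": ["|".join(sorted(t.overlap_genes)) for t in terms],
        }
    )
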