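"""Promoter-level motif co-occurrence enrichment.

Presence/absence per promoter (>= 1 hit).  Under independence the expected
number of promoters carrying both motifs is n_a * n_b / n; the enrichment
ratio is observed/expected and significance is the hypergeometric upper
tail (>= n_both promoters with both, drawing n_b promoters from n of which
n_a are marked).  A seeded label-permutation p-value is provided as a
cross-check mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


@dataclass(frozen=True)
class CooccurrenceResult:
    motif_a: str
    motif_b: str
    n: int
    n_a: int
    n_b: int
    n_both: int
    expected_both: float
    ratio: float
    p_value: float


def cooccurrence(
    promoter_hits_a: Iterable[str],
    promoter_hits_b: Iterable[str],
    n: int,
    motif_a: str = "A",
    motif_b: str = "B",
) -> CooccurrenceResult:
    """Co-occurrence statistics for two promoter-id hit sets out of ``n`` tested."""
    set_a, set_b = set(promoter_hits_a), set(promoter_hits_b)
    n_a, n_b = len(set_a), len(set_b)
    if n <= 0:
        raise ValueError("n must be positive")
    if n < max(n_a, n_b):
        raise ValueError("n smaller than a hit set")
    n_both = len(set_a & set_b)
    expected = n_a * n_b / n
    if expected > 0:
        ratio = n_both / expected
    else:
        ratio = math.inf if n_both > 0 else 0.0
    p = float(hypergeom.sf(n_both - 1, n, n_a, n_b))
    return CooccurrenceResult(
        motif_a=motif_a,
        motif_b=motif_b,
        n=n,
        n_a=n_a,
        n_b=n_b,
        n_both=n_both,
        expected_both=expected,
        ratio=ratio,
        p_value=min(p, 1.0),
    )


def randomized_pvalue(result: CooccurrenceResult, rng: np.random.Generator) -> float:
    """Randomized p-value, exactly Uniform(0,1) under the null.

    The exact hypergeometric p-value is discrete and therefore conservative
    (stochastically larger than uniform); for calibration checks the
    standard randomization p = P(X > k) + U * P(X = k) restores exact
    uniformity.
    """
    k = result.n_both
    tail_above = float(hypergeom.sf(k, result.n, result.n_a, result.n_b))
    pmf = float(hypergeom.pmf(k, result.n, result.n_a, result.n_b))
    return min(tail_above + rng.random() * pmf, 1.0)


def permutation_pvalue(
    result: CooccurrenceResult, n_permutations: int = 10_000, seed: int = 0
) -> float:
    """Cross-check p-value: permute which promoters carry motif B."""
    rng = np.random.default_rng(seed)
    marked = np.zeros(result.n, dtype=bool)
    marked[: result.n_a] = True
    exceed = 0
    for _ in range(n_permutations):
        draw = rng.choice(result.n, size=result.n_b, replace=False)
        if int(marked[draw].sum()) >= result.n_both:
            exceed += 1
    return (exceed + 1) / (n_permutations + 1)


def pairwise_table(
    hit_sets: dict[str, set[str]], n: int, pairs: Sequence[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Co-occurrence results for all (or the given) motif pairs as a table."""
    names = sorted(hit_sets)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    rows = [
        vars(cooccurrence(hit_sets[a], hit_sets[b], n, a, b)) for a, b in pairs
    ]
    return pd.DataFrame(rows)
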