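"""Over-representation of binding-site-positive miRs among downregulated miRs.

Given a universe of miR promoters (or genes), of which K carry at least one
TF binding site, and a selected set of n downregulated miRs of which k are
binding-positive, the analytic upper-tail hypergeometric probability
P(X >= k) measures whether binding and downregulation co-occur more often
than chance.  A seeded permutation test provides an independent empirical
cross-check of the same tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "EnrichmentInput",
    "hypergeom_tail",
    "permutation_enrichment",
    "bound_fraction",
]


@dataclass(frozen=True)
class EnrichmentInput:
    """The 2x2 overlap counts feeding the tail test.

    n_universe: all items considered (e.g. 781 promoters);
    n_bound: items with >= 1 binding site (e.g. 160);
    n_selected: items in the selection, e.g. downregulated genes (e.g. 63);
    n_selected_bound: selected items that are also bound (e.g. 38).
    """

    n_universe: int
    n_bound: int
    n_selected: int
    n_selected_bound: int

    def __post_init__(self) -> None:
        n, K, s, k = (
            self.n_universe,
            self.n_bound,
            self.n_selected,
            self.n_selected_bound,
        )
        if min(n, K, s, k) < 0 or n == 0:
            raise ValueError("counts must be non-negative with a non-empty universe")
        if K > n or s > n:
            raise ValueError("bound and selected counts cannot exceed the universe")
        if k > min(K, s):
            raise ValueError("overlap cannot exceed either margin")


def hypergeom_tail(inp: EnrichmentInput) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Evaluated through the survival function in log-stable form, so counts up
    to ~1e6 do not overflow.
    """
    k = inp.n_selected_bound
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy computes the sum with log-gamma terms
    p = stats.hypergeom.sf(k - 1, inp.n_universe, inp.n_bound, inp.n_selected)
    return float(min(1.0, max(0.0, p)))


def permutation_enrichment(
    inp: EnrichmentInput,
    iters: int = 100_000,
    seed: int = 0,
    chunk: int = 20_000,
) -> float:
    """Empirical tail probability by repeated random selection.

    Each iteration draws ``n_selected`` distinct items uniformly from the
    universe (items 0..n_bound-1 are the bound ones) and counts how many are
    bound; the draw is realized by ranking i.i.d. random keys, so it does not
    reuse any hypergeometric machinery.  Returns the add-one-smoothed
    empirical p-value (1 + #{draws with >= k bound}) / (1 + iters).
    """
    if iters < 1:
        raise ValueError("iters must be >= 1")
    rng = np.random.default_rng(seed)
    N, K, n, k = inp.n_universe, inp.n_bound, inp.n_selected, inp.n_selected_bound
    hits = 0
    done = 0
    while done < iters:
        b = min(chunk, iters - done)
        keys = rng.random((b, N))
        # the n smallest keys per row form a uniform n-subset of the universe
        sel = np.argpartition(keys, n - 1, axis=1)[:, :n]
        marked = (sel < K).sum(axis=1)
        hits += int((marked >= k).sum())
        done += b
    return (1 + hits) / (1 + iters)


def bound_fraction(inp: EnrichmentInput) -> tuple[float, int]:
    """Percentage of selected items that are bound: (full precision, rounded)."""
    if inp.n_selected == 0:
        raise ValueError("bound fraction undefined for an empty selection")
    pct = 100.0 * inp.n_selected_bound / inp.n_selected
    return pct, int(round(pct))
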