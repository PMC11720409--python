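"""Top-K ranking overlap across phenotype screens and its bootstrap null.

The observed statistic is the size of the intersection of the top-K
(default 500) reagent sets from several phenotype association rankings.
The null distribution is simulated by drawing, per iteration, the same
number of multisets of K uniform with-replacement draws from the reagent
universe, reducing each to its unique elements and intersecting; the
empirical p-value uses the add-one convention so it is never zero.  The
analytic expectation of the null intersection size is

    E[|∩|] = N · (1 − (1 − 1/N)^K)^m

which serves as an independent cross-check of the simulation.

A 2×2 enrichment comparison (hits vs non-hits × reagent set A vs B)
reports the odds ratio with a log-OR normal-approximation 95% CI and a
Pearson chi-square p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("crossprot")


def top_k(ranked: pd.DataFrame, k: int = 500,
          id_column: str = "reagent_id") -> set[str]:
    """First k reagent ids of a deterministically ranked association table."""
    if ranked.empty:
        raise ValueError("empty ranking")
    if k > len(ranked):
        logger.warning("top_k: k=%d exceeds ranking size %d; taking all",
                       k, len(ranked))
        k = len(ranked)
    return set(ranked[id_column].iloc[:k])


def multi_overlap(sets: Sequence[Iterable[str]],
                  annotations: Mapping[str, frozenset[str]] | None = None
                  ) -> tuple[set[str], set[frozenset[str]] | None]:
    """Intersection of ≥ 2 identifier sets, plus the unique-protein collapse
    (distinct UniProt ID sets) when an annotation mapping is given."""
    sets = [set(s) for s in sets]
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    inter = set.intersection(*sets)
    collapsed = None
    if annotations is not None:
        collapsed = {annotations[r] for r in inter if r in annotations}
    return inter, collapsed


@dataclass
class OverlapNull:
    universe_size: int
    set_size: int
    n_sets: int
    iterations: int
    seed: int
    sim_mean: float
    sim_sd: float
    sizes: np.ndarray
    observed: int | None = None
    empirical_p: float | None = None

    @property
    def expected_closed_form(self) -> float:
        N, k, m = self.universe_size, self.set_size, self.n_sets
        return N * (1.0 - (1.0 - 1.0 / N) ** k) ** m


def bootstrap_overlap_null(N: int, k: int = 500, m: int = 3,
                           B: int = 10000, seed: int = 0) -> OverlapNull:
    """Simulate the null distribution of the m-way top-k overlap.

    Per iteration: draw m multisets of k uniform with-replacement draws
    from {0..N−1}, reduce each to its unique elements, record the size of
    the m-way intersection.  Mean and SD (n−1) are taken across the B
    iterations; reproducible under ``seed``.
    """
    if N < 1 or k < 1 or m < 1 or B < 1:
        raise ValueError("N, k, m and B must all be >= 1")
    rng = np.random.default_rng(seed)
    sizes = np.empty(B, dtype=np.int64)
    hit = np.empty((m, N), dtype=bool)
    for it in range(B):
        draws = rng.integers(0, N, size=(m, k))
        hit[:] = False
        for j in range(m):
            hit[j, draws[j]] = True
        sizes[it] = int(hit.all(axis=0).sum())
    return OverlapNull(
        universe_size=N, set_size=k, n_sets=m, iterations=B, seed=seed,
        sim_mean=float(sizes.mean()),
        sim_sd=float(sizes.std(ddof=1)) if B > 1 else 0.0,
        sizes=sizes)


def empirical_p(observed: int, simulated: Sequence[int] | np.ndarray) -> float:
    """Add-one empirical p-value: (#{sim ≥ observed} + 1) / (B + 1)."""
    sim = np.asarray(simulated)
    if sim.size == 0:
        raise ValueError("empty simulation list")
    return float((np.sum(sim >= observed) + 1) / (sim.size + 1))


def attach_observed(null: OverlapNull, observed: int) -> OverlapNull:
    """Record the observed overlap and its empirical p on a null object."""
    null.observed = int(observed)
    null.empirical_p = empirical_p(observed, null.sizes)
    return null


@dataclass(frozen=True)
class EnrichmentStats:
    table: tuple[tuple[float, float], tuple[float, float]]
    odds_ratio: float
    ci95: tuple[float, float]
    chi2_p: float
    corrected: bool  # Haldane–Anscombe +0.5 applied (a zero cell occurred)


def enrichment_stats(hits_a: int, n_a: int, hits_b: int, n_b: int
                     ) -> EnrichmentStats:
    """2×2 enrichment of hits in reagent set A versus set B.

    OR = (hits_a·(n_b−hits_b)) / (hits_b·(n_a−hits_a)); 95% CI from the
    normal approximation on log OR; Pearson chi-square without continuity
    correction.  If any cell is zero the Haldane–Anscombe +0.5 correction
    is applied to all cells and flagged.
    """
    if not (n_a >= hits_a >= 0 and n_b >= hits_b >= 0):
        raise ValueError("need n >= hits >= 0 for both sets")
    cells = np.array([[hits_a, n_a - hits_a],
                      [hits_b, n_b - hits_b]], dtype=float)
    if cells.sum() == 0:
        raise ValueError("empty contingency table")
    corrected = bool((cells == 0).any())
    work = cells + 0.5 if corrected else cells
    orat = (work[0, 0] * work[1, 1]) / (work[0, 1] * work[1, 0])
    se = np.sqrt((1.0 / work).sum())
    lo = float(np.exp(np.log(orat) - 1.959963984540054 * se))
    hi = float(np.exp(np.log(orat) + 1.959963984540054 * se))
    chi2_p = float(stats.chi2_contingency(work, correction=False)[1])
    return EnrichmentStats(
        table=((float(cells[0, 0]), float(cells[0, 1])),
               (float(cells[1, 0]), float(cells[1, 1]))),
        odds_ratio=float(orat), ci95=(lo, hi), chi2_p=chi2_p,
        corrected=corrected)
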