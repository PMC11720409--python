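"""Reproducibility and reliability scoring of aptamer measurements.

Intra-platform reproducibility is the Spearman correlation of the same
aptamer across the two independent aptamer runs on overlapping samples;
inter-platform reliability is the Spearman correlation of UniProt-matched
aptamer/antibody reagent pairs.  Correlations fall into three categories —
good (ρ ≥ 0.5), moderate (0.3 ≤ ρ < 0.5), poor (ρ < 0.3, negative values
included) — and the intra × best-inter category combination maps to a
single 12-level score:

    intra \\ inter   good  moderate  poor   (no antibody match)
    good              1       2       3          A
    moderate          4       5       6          B
    poor              7       8       9          C

When an aptamer has inter-platform correlations against both aptamer runs
(or several antibody subpanel assays), the record with the highest ρ decides
the inter category.  Scores 1–3 plus A form the "reproducible set" used to
filter downstream association screens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    ExpressionMatrix,
    Platform,
    ReagentAnnotation,
    ReagentPair,
    align_overlap,
    pair_reagents,
)

logger = logging.getLogger("crossprot")


class Category(str, Enum):
    GOOD = "GOOD"
    MODERATE = "MODERATE"
    POOR = "POOR"


class Comparison(str, Enum):
    INTRA_AB = "INTRA_AB"
    INTER_A_OLINK = "INTER_A_OLINK"
    INTER_B_OLINK = "INTER_B_OLINK"


#: intra category × inter category → score (1–9); A–C when no antibody match
SCORE_TABLE: dict[tuple[Category, Category], str] = {
    (Category.GOOD, Category.GOOD): "1",
    (Category.GOOD, Category.MODERATE): "2",
    (Category.GOOD, Category.POOR): "3",
    (Category.MODERATE, Category.GOOD): "4",
    (Category.MODERATE, Category.MODERATE): "5",
    (Category.MODERATE, Category.POOR): "6",
    (Category.POOR, Category.GOOD): "7",
    (Category.POOR, Category.MODERATE): "8",
    (Category.POOR, Category.POOR): "9",
}

UNMATCHED_SCORES: dict[Category, str] = {
    Category.GOOD: "A", Category.MODERATE: "B", Category.POOR: "C",
}

ALL_SCORES = ("1", "2", "3", "4", "5", "6", "7", "8", "9", "A", "B", "C")
REPRODUCIBLE_SCORES = frozenset({"1", "2", "3", "A"})


def classify_rho(rho: float) -> Category:
    """Correlation category of a Spearman ρ: good at ρ ≥ 0.5 (boundary
    inclusive), moderate on [0.3, 0.5), poor below — negative values are
    poor."""
    if not -1.0 - 1e-12 <= rho <= 1.0 + 1e-12:
        raise ValueError(f"rho {rho} outside [-1, 1]")
    if rho >= 0.5:
        return Category.GOOD
    if rho >= 0.3:
        return Category.MODERATE
    return Category.POOR


@dataclass(frozen=True)
class CorrelationRecord:
    reagent_a: str
    reagent_b: str
    comparison: Comparison
    rho: float
    n: int

    @property
    def category(self) -> Category:
        return classify_rho(self.rho)


def _spearman_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise Spearman ρ between paired rows of A and B (no NaNs),
    average ranks for ties."""
    ra = stats.rankdata(A, axis=1)
    rb = stats.rankdata(B, axis=1)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    num = (ra * rb).sum(axis=1)
    den = np.sqrt((ra ** 2).sum(axis=1) * (rb ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def correlate_pairs(a: ExpressionMatrix, b: ExpressionMatrix,
                    pairs: Sequence[ReagentPair | tuple[str, str]],
                    comparison: Comparison,
                    min_n: int = 10) -> list[CorrelationRecord]:
    """Spearman ρ for each reagent pair on the overlapping samples.

    Observations are pairwise-complete per pair; pairs with fewer than
    ``min_n`` complete observations are omitted with a logged reason.
    """
    aligned = align_overlap(a, b)
    if aligned.n_overlap < min_n:
        raise ValueError(
            f"only {aligned.n_overlap} overlapping samples (< min_n={min_n})")
    ids = []
    for p in pairs:
        if isinstance(p, ReagentPair):
            ids.append((p.reagent_a.reagent_id, p.reagent_b.reagent_id))
        else:
            ids.append((p[0], p[1]))
    valid = [(ra, rb) for ra, rb in ids
             if ra in aligned.a.values.index and rb in aligned.b.values.index]
    skipped = len(ids) - len(valid)
    if skipped:
        logger.warning("correlate_pairs: %d pair(s) reference absent "
                       "reagents; skipped", skipped)
    if not valid:
        logger.warning("correlate_pairs: no valid pairs")
        return []
    A = aligned.a.values.loc[[ra for ra, _ in valid]].to_numpy(dtype=float)
    B = aligned.b.values.loc[[rb for _, rb in valid]].to_numpy(dtype=float)
    records: list[CorrelationRecord] = []
    clean = ~(np.isnan(A).any() or np.isnan(B).any())
    if clean:
        rhos = _spearman_rows(A, B)
        for (ra, rb), rho in zip(valid, rhos):
            if np.isnan(rho):
                logger.warning("correlate_pairs: constant values for pair "
                               "(%s, %s); omitted", ra, rb)
                continue
            records.append(CorrelationRecord(ra, rb, comparison, float(rho),
                                             aligned.n_overlap))
    else:
        for i, (ra, rb) in enumerate(valid):
            mask = ~(np.isnan(A[i]) | np.isnan(B[i]))
            if mask.sum() < min_n:
                logger.warning("correlate_pairs: pair (%s, %s) has %d < %d "
                               "complete observations; omitted",
                               ra, rb, int(mask.sum()), min_n)
                continue
            rho = stats.spearmanr(A[i, mask], B[i, mask]).statistic
            if np.isnan(rho):
                continue
            records.append(CorrelationRecord(ra, rb, comparison, float(rho),
                                             int(mask.sum())))
    return records


@dataclass(frozen=True)
class ReproducibilityScore:
    reagent_id: str
    intra_category: Category
    best_inter_category: Category | None
    best_inter_rho: float | None
    score: str


def assign_score(intra: CorrelationRecord,
                 inters: Sequence[CorrelationRecord] = ()
                 ) -> ReproducibilityScore:
    """Combine an intra-platform record with up to two inter-platform
    records (one per aptamer run vs the antibody panel) into the 12-level
    score.  With several inter records the one with the highest ρ decides;
    with none the A–C branch applies."""
    if len(inters) > 2:
        raise ValueError("at most two inter-platform records expected")
    if not inters:
        cat = intra.category
        return ReproducibilityScore(intra.reagent_a, cat, None, None,
                                    UNMATCHED_SCORES[cat])
    best = max(inters, key=lambda r: r.rho)
    score = SCORE_TABLE[(intra.category, best.category)]
    return ReproducibilityScore(intra.reagent_a, intra.category,
                                best.category, best.rho, score)


def summarize_scores(scores: Sequence[ReproducibilityScore | str],
                     annotations: Mapping[str, frozenset[str]] | None = None
                     ) -> dict:
    """Count/percentage table over the 12 score levels.

    Percentages are over the grand total of scored reagents.  Also reports
    the 1–9 vs A–C branch totals, the reproducible set (scores 1–3 and A),
    and — when a reagent→UniProt-set mapping is provided — unique-protein
    counts collapsed over set-identical annotations.
    """
    if len(scores) == 0:
        raise ValueError("empty score list")
    labels = [s if isinstance(s, str) else s.score for s in scores]
    for s in labels:
        if s not in ALL_SCORES:
            raise ValueError(f"unknown score label {s!r}")
    counts = pd.Series(labels).value_counts()
    total = int(counts.sum())
    table = pd.DataFrame({
        "score": list(ALL_SCORES),
        "count": [int(counts.get(s, 0)) for s in ALL_SCORES],
    })
    table["percentage"] = 100.0 * table["count"] / total
    out = {
        "table": table,
        "total": total,
        "total_matched": int(table.loc[table["score"].isin(list("123456789")),
                                       "count"].sum()),
        "total_unmatched": int(table.loc[table["score"].isin(list("ABC")),
                                         "count"].sum()),
    }
    ids = [s.reagent_id for s in scores
           if isinstance(s, ReproducibilityScore)]
    if ids:
        repro = [s.reagent_id for s in scores
                 if isinstance(s, ReproducibilityScore)
                 and s.score in REPRODUCIBLE_SCORES]
        out["reproducible_set"] = sorted(repro)
        if annotations is not None:
            out["unique_proteins_total"] = len(
                {annotations[r] for r in ids if r in annotations})
            out["unique_proteins_reproducible"] = len(
                {annotations[r] for r in repro if r in annotations})
    return out


# ---------------------------------------------------------------------------
# Pipeline: three harmonized matrices + annotations -> per-aptamer scores
# ---------------------------------------------------------------------------


def score_reagents(soma_a: ExpressionMatrix, soma_b: ExpressionMatrix,
                   olink: ExpressionMatrix,
                   annotations: Mapping[Platform,
                                        Sequence[ReagentAnnotation]],
                   min_n: int = 10) -> pd.DataFrame:
    """Full scoring pipeline for every aptamer present in both aptamer runs.

    The intra record correlates the aptamer with itself across the two
    runs; inter records come from UniProt-set pairing against the antibody
    panel, collapsed to the max-ρ record per comparison.  Returns one row
    per aptamer with rhos, categories and the final score.
    """
    shared = [r for r in soma_a.reagent_ids if r in set(soma_b.reagent_ids)]
    intra_records = {
        r.reagent_a: r
        for r in correlate_pairs(soma_a, soma_b, [(r, r) for r in shared],
                                 Comparison.INTRA_AB, min_n=min_n)
    }
    inter_best: dict[Comparison, dict[str, CorrelationRecord]] = {}
    for comp, mat, plat in ((Comparison.INTER_A_OLINK, soma_a, Platform.SOMA_A),
                            (Comparison.INTER_B_OLINK, soma_b, Platform.SOMA_B)):
        pairs = pair_reagents(annotations[plat], annotations[Platform.OLINK])
        best: dict[str, CorrelationRecord] = {}
        for rec in correlate_pairs(mat, olink, pairs, comp, min_n=min_n):
            cur = best.get(rec.reagent_a)
            if cur is None or rec.rho > cur.rho:
                best[rec.reagent_a] = rec
        inter_best[comp] = best

    ann_map = {a.reagent_id: a for a in annotations[Platform.SOMA_A]}
    rows = []
    for rid, intra in intra_records.items():
        inters = [inter_best[c][rid] for c in (Comparison.INTER_A_OLINK,
                                               Comparison.INTER_B_OLINK)
                  if rid in inter_best[c]]
        sc = assign_score(intra, inters)
        ann = ann_map.get(rid)
        rows.append({
            "reagent_id": rid,
            "uniprot_ids": "|".join(sorted(ann.uniprot_ids)) if ann else "",
            "intra_rho": intra.rho,
            "intra_category": intra.category.value,
            "inter_rho_a": next((r.rho for r in inters
                                 if r.comparison is Comparison.INTER_A_OLINK),
                                np.nan),
            "inter_rho_b": next((r.rho for r in inters
                                 if r.comparison is Comparison.INTER_B_OLINK),
                                np.nan),
            "best_inter_category": (sc.best_inter_category.value
                                    if sc.best_inter_category else ""),
            "score": sc.score,
        })
    return pd.DataFrame(rows).set_index("reagent_id").sort_index()
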