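"""Platform quality control: PCA structure checks and calibrator CVs.

PCA runs on harmonized (log2 + z-scored) matrices with samples as
observations; the module reports explained-variance fractions, the number
of components needed to reach a variance target, top absolute loadings,
PC–phenotype screens (marginal Pearson and joint linear models) and
1.5×IQR score-based outlier samples.

Coefficients of variation are computed on the *raw* (pre-harmonization)
matrices from calibrator replicates: per-plate (intra-assay) and pooled
across plates (inter-assay).  The formula depends on the readout scale —
σ/μ for the linear RFU scale, and the log-normal identity
sqrt(exp((ln2·σ_NPX)²) − 1) for the log2 NPX scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, PhenotypeTable, PlateMap, Scale

logger = logging.getLogger("crossprot")

# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    explained_variance_fraction: np.ndarray   # per component
    scores: pd.DataFrame                      # samples × components
    loadings: pd.DataFrame                    # reagents × components

    @property
    def cumulative_fraction(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_fraction)


def run_pca(m: ExpressionMatrix, n_components: int | None = None) -> PCAResult:
    """PCA of a z-scored matrix with samples as observations.

    Components are ordered by decreasing explained variance.  Per-component
    sign is fixed by requiring the largest-magnitude loading to be positive,
    making results deterministic across SVD implementations.
    """
    if m.scale is not Scale.ZSCORED:
        raise ValueError("run_pca expects a z-scored matrix")
    if m.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = m.values.to_numpy(dtype=float).T          # samples × reagents
    X = X - X.mean(axis=0, keepdims=True)
    max_rank = min(X.shape)
    k = max_rank if n_components is None else min(n_components, max_rank)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total_var = (s ** 2).sum()
    frac = (s ** 2) / total_var if total_var > 0 else np.zeros_like(s)
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(len(s)):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U[:, :k] * s[:k]
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        explained_variance_fraction=frac[:k],
        scores=pd.DataFrame(scores, index=m.sample_ids, columns=comp_names),
        loadings=pd.DataFrame(Vt[:k].T, index=m.reagent_ids,
                              columns=comp_names),
    )


def pcs_for_variance(p: PCAResult, target: float = 0.95) -> int:
    """Smallest number of leading components whose cumulative explained
    variance reaches ``target``."""
    if not 0 < target <= 1:
        raise ValueError("target must lie in (0, 1]")
    cum = p.cumulative_fraction
    idx = np.searchsorted(cum, target - 1e-12)
    if idx >= len(cum):
        return len(cum)
    return int(idx) + 1


def top_loadings(p: PCAResult, component: int = 1, k: int = 15) -> pd.DataFrame:
    """Reagents ranked by absolute loading on one component (1-based index);
    ties broken by reagent id."""
    name = f"PC{component}"
    if name not in p.loadings.columns:
        raise ValueError(f"component {component} not available")
    col = p.loadings[name]
    order = sorted(col.index, key=lambda r: (-abs(col[r]), r))
    k = min(k, len(order))
    sel = order[:k]
    return pd.DataFrame({"reagent_id": sel,
                         "loading": col.loc[sel].to_numpy()})


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pc_phenotype_screen(scores: pd.DataFrame, phenotypes: PhenotypeTable,
                        top_k: int = 5, mode: str = "UNADJUSTED"
                        ) -> pd.DataFrame:
    """Screen leading PC scores against clinical variables.

    UNADJUSTED: per (PC, variable) Pearson r with its p-value on complete
    cases.  JOINT: per PC, one linear model of the score on all variables
    simultaneously; each variable's coefficient and Wald p.  Zero-variance
    variables are dropped with a warning.  p-values carry the conventional
    0.05/0.01/0.001 star labels.
    """
    import statsmodels.api as sm

    if top_k > scores.shape[1]:
        raise ValueError("top_k exceeds available components")
    pheno = phenotypes.numeric_frame()
    common = [s for s in scores.index if s in pheno.index]
    pheno = pheno.loc[common]
    sc = scores.loc[common, scores.columns[:top_k]]
    keep = []
    for v in pheno.columns:
        x = pheno[v].dropna()
        if len(x) < 3 or x.std(ddof=1) == 0:
            logger.warning("pc_phenotype_screen: dropping variable %r "
                           "(constant or too few observations)", v)
            continue
        keep.append(v)
    rows = []
    if mode.upper() == "UNADJUSTED":
        for pc in sc.columns:
            for v in keep:
                mask = pheno[v].notna()
                r, p = stats.pearsonr(sc.loc[mask, pc], pheno.loc[mask, v])
                rows.append({"pc": pc, "variable": v, "estimate": r,
                             "p": p, "stars": _stars(p)})
    elif mode.upper() == "JOINT":
        mask = pheno[keep].notna().all(axis=1)
        X = sm.add_constant(pheno.loc[mask, keep])
        for pc in sc.columns:
            fit = sm.OLS(sc.loc[mask, pc], X).fit()
            for v in keep:
                rows.append({"pc": pc, "variable": v,
                             "estimate": fit.params[v],
                             "p": fit.pvalues[v],
                             "stars": _stars(fit.pvalues[v])})
    else:
        raise ValueError("mode must be UNADJUSTED or JOINT")
    return pd.DataFrame(rows)


def iqr_outlier_samples(scores: pd.DataFrame, components: set[int] = {1, 2},
                        fold: float = 1.5) -> list[str]:
    """Samples whose score on any listed component lies outside
    [Q1 − fold·IQR, Q3 + fold·IQR]."""
    if fold <= 0:
        raise ValueError("fold must be positive")
    excluded: set[str] = set()
    for c in sorted(components):
        name = f"PC{c}"
        if name not in scores.columns:
            raise ValueError(f"component {c} not in scores")
        col = scores[name]
        q1, q3 = col.quantile(0.25), col.quantile(0.75)
        iqr = q3 - q1
        lo, hi = q1 - fold * iqr, q3 + fold * iqr
        out = col.index[(col < lo) | (col > hi)]
        excluded.update(out)
    result = sorted(excluded)
    if result:
        logger.info("iqr_outlier_samples: excluding %d sample(s): %s",
                    len(result), result[:10])
    return result


# ---------------------------------------------------------------------------
# Coefficients of variation
# ---------------------------------------------------------------------------


def _cv_from_values(vals: np.ndarray, scale: Scale) -> np.ndarray:
    """Per-reagent CV of calibrator readouts, by readout scale.

    Linear RFU: σ/μ with the n−1 SD.  Log2 NPX: sqrt(exp((ln2·σ_NPX)²) − 1),
    the log-normal CV identity with the log-SD converted from base 2 to
    natural log.
    """
    if scale is Scale.LINEAR_RFU:
        mu = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=1)
        return sd / mu
    if scale is Scale.NPX_LOG2:
        sd = vals.std(axis=1, ddof=1)
        return np.sqrt(np.expm1((np.log(2.0) * sd) ** 2))
    raise ValueError(f"CV undefined for scale {scale}")


def intra_assay_cv(m: ExpressionMatrix, plates: PlateMap) -> pd.Series:
    """Intra-assay CV per reagent: CV over each plate's calibrators,
    averaged (unweighted) across plates.  Plates with fewer than two
    calibrators are skipped with a warning."""
    per_plate = []
    for plate in plates.plates:
        cals = [c for c in plates.calibrators(plate) if c in m.values.columns]
        if len(cals) < 2:
            logger.warning("intra_assay_cv: plate %r has < 2 calibrators; "
                           "skipped", plate)
            continue
        vals = m.values[cals].to_numpy(dtype=float)
        per_plate.append(_cv_from_values(vals, m.scale))
    if not per_plate:
        raise ValueError("no plate has >= 2 calibrator samples")
    return pd.Series(np.mean(per_plate, axis=0), index=m.reagent_ids,
                     name="cv_intra")


def inter_assay_cv(m: ExpressionMatrix, plates: PlateMap) -> pd.Series:
    """Inter-assay CV per reagent: one CV over all calibrator samples pooled
    across plates."""
    cals = [c for c in plates.calibrators() if c in m.values.columns]
    if len(cals) < 2:
        raise ValueError("need >= 2 calibrator samples in total")
    vals = m.values[cals].to_numpy(dtype=float)
    return pd.Series(_cv_from_values(vals, m.scale), index=m.reagent_ids,
                     name="cv_inter")


def cv_summary(cvs: pd.Series | list[float],
               other: pd.Series | list[float] | None = None,
               trim_fold: float = 1.5) -> dict:
    """Percentile summary of a CV distribution, optionally compared to a
    second one.

    Reports the 10/25/50/75/90th percentiles (linear interpolation) and the
    fraction of reagents with CV < 0.20.  When ``other`` is given, both
    lists are trimmed of outliers beyond ``trim_fold``×IQR and compared by
    a two-sided Mann-Whitney U test.
    """
    cvs = pd.Series(cvs).dropna()
    if cvs.empty:
        raise ValueError("empty CV list")
    qs = [10, 25, 50, 75, 90]
    out = {
        "percentiles": {q: float(np.percentile(cvs, q)) for q in qs},
        "fraction_below_20pct": float((cvs < 0.20).mean()),
        "n": int(len(cvs)),
    }
    if other is not None:
        other = pd.Series(other).dropna()
        if other.empty:
            raise ValueError("empty comparison CV list")
        a = _trim_iqr(cvs, trim_fold)
        b = _trim_iqr(other, trim_fold)
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        out["mannwhitney"] = {"U": float(u), "p": float(p),
                              "n_a": int(len(a)), "n_b": int(len(b))}
    return out


def _trim_iqr(x: pd.Series, fold: float) -> pd.Series:
    q1, q3 = x.quantile(0.25), x.quantile(0.75)
    iqr = q3 - q1
    return x[(x >= q1 - fold * iqr) & (x <= q3 + fold * iqr)]
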