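"""Per-reagent association screens against clinical traits and CSF
biomarkers, with covariate adjustment, Bonferroni control and a penalized
regression variance-explained evaluation.

For continuous traits the model is linear with the z-scored protein level
as the outcome and the phenotype plus covariates (sex, age, CSF total
protein, and biomarker technique when the phenotype is a CSF biomarker) as
predictors; for sex the model is logistic with sex as the outcome.  A
covariate identical to the tested phenotype is dropped from the adjustment
set.  Total tau is never screened (it is nearly collinear with p-tau).

The LASSO evaluation trains an L1-penalized model on a random 80% of
samples with 5-fold cross-validation repeated 5 times over a log-spaced
penalty grid, and reports held-out performance on the remaining 20% —
R² for continuous phenotypes, AUC/sensitivity/specificity for binary ones.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .core import CSF_BIOMARKERS, ExpressionMatrix, PhenotypeTable, Scale

logger = logging.getLogger("crossprot")

DEFAULT_COVARIATES = ("sex", "age", "csf_total_protein")

#: phenotypes screened by default; t-tau deliberately absent
DEFAULT_PHENOTYPES = ("age", "sex", "csf_albumin", "csf_globulins",
                      "csf_rbc", "qalb", "mmse", "csf_ab42", "csf_ptau")


class ModelFamily(str, Enum):
    LINEAR = "LINEAR"
    LOGISTIC = "LOGISTIC"


@dataclass(frozen=True)
class AssociationResult:
    reagent_id: str
    phenotype: str
    family: ModelFamily
    beta: float
    se: float
    p: float
    n_used: int
    covariates: tuple[str, ...]
    converged: bool = True


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Familywise significance threshold alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = []
        for col in X.columns:
            sub = X.drop(columns=[col]).to_numpy(dtype=float)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(col)
        raise ValueError(f"design matrix is rank-deficient; collinear "
                         f"columns: {bad or list(X.columns)}")


def fit_association(protein: pd.Series, phenotype: pd.Series,
                    covariates: pd.DataFrame, family: ModelFamily,
                    reagent_id: str = "", phenotype_name: str = ""
                    ) -> AssociationResult:
    """Single covariate-adjusted association fit.

    LINEAR: protein ~ phenotype + covariates, two-sided Wald p on the
    phenotype coefficient.  LOGISTIC: phenotype (binary, e.g. sex) ~
    protein + covariates, Wald p on the protein coefficient.  Perfect
    separation yields a flagged non-converged result with missing p.
    """
    family = ModelFamily(family)
    df = pd.concat([protein.rename("__protein"),
                    phenotype.rename("__phenotype"), covariates], axis=1)
    df = df.dropna()
    if len(df) < covariates.shape[1] + 3:
        raise ValueError("too few complete cases for the requested model")
    cov_cols = list(covariates.columns)
    if family is ModelFamily.LINEAR:
        X = sm.add_constant(df[["__phenotype"] + cov_cols],
                            has_constant="add")
        _check_rank(X)
        fit = sm.OLS(df["__protein"], X).fit()
        term = "__phenotype"
        est, se, p, converged = (fit.params[term], fit.bse[term],
                                 fit.pvalues[term], True)
    else:
        y = df["__phenotype"]
        if y.nunique() < 2:
            raise ValueError("logistic outcome has a single class")
        X = sm.add_constant(df[["__protein"] + cov_cols],
                            has_constant="add")
        _check_rank(X)
        term = "__protein"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0)
            converged = bool(fit.mle_retvals.get("converged", True))
            est, se, p = fit.params[term], fit.bse[term], fit.pvalues[term]
            if not converged or not np.isfinite(se) or se > 1e3:
                converged, p = False, np.nan
        except (PerfectSeparationError, np.linalg.LinAlgError):
            logger.warning("fit_association: perfect separation for %r vs %r",
                           reagent_id, phenotype_name)
            est, se, p, converged = np.nan, np.nan, np.nan, False
    return AssociationResult(reagent_id, phenotype_name, family,
                             float(est), float(se), float(p), len(df),
                             tuple(cov_cols), converged)


def covariates_for(phenotype: str,
                   base: tuple[str, ...] = DEFAULT_COVARIATES) -> list[str]:
    """Adjustment set for one phenotype: the base covariates minus the
    phenotype itself, plus biomarker technique when the phenotype is a CSF
    biomarker."""
    covs = [c for c in base if c != phenotype]
    if phenotype in CSF_BIOMARKERS:
        covs.append("technique")
    return covs


def association_screen(matrix: ExpressionMatrix, phenotypes: PhenotypeTable,
                       phenotype_list: tuple[str, ...] = DEFAULT_PHENOTYPES,
                       covariates: tuple[str, ...] = DEFAULT_COVARIATES,
                       alpha: float = 0.05,
                       scores: pd.Series | None = None
                       ) -> dict[str, pd.DataFrame]:
    """Screen every reagent against each phenotype.

    Returns, per phenotype, a table ranked by ascending p (ties broken by
    descending |beta| then reagent id), with the Bonferroni significance
    flag at alpha / n_reagents_tested and the reliability score joined on
    when provided.
    """
    if matrix.scale is not Scale.ZSCORED:
        raise ValueError("association_screen expects a z-scored matrix")
    pheno = phenotypes.numeric_frame()
    shared = [s for s in matrix.sample_ids if s in pheno.index]
    if not shared:
        raise ValueError("no samples shared between matrix and phenotypes")
    pheno = pheno.loc[shared]
    vals = matrix.values[shared]
    out: dict[str, pd.DataFrame] = {}
    for ph in phenotype_list:
        if ph not in pheno.columns:
            logger.warning("association_screen: phenotype %r absent; skipped",
                           ph)
            continue
        family = ModelFamily.LOGISTIC if ph == "sex" else ModelFamily.LINEAR
        covs = covariates_for(ph, covariates)
        covs = [c for c in covs if c in pheno.columns]
        cov_df = pheno[covs]
        y = pheno[ph]
        rows = []
        for rid in vals.index:
            res = fit_association(vals.loc[rid], y, cov_df, family,
                                  reagent_id=rid, phenotype_name=ph)
            rows.append({"reagent_id": res.reagent_id, "beta": res.beta,
                         "se": res.se, "p": res.p, "n_used": res.n_used,
                         "converged": res.converged})
        tab = pd.DataFrame(rows)
        thr = bonferroni_threshold(alpha, len(tab))
        tab["significant"] = tab["p"] < thr
        tab["neg_log10_p"] = -np.log10(tab["p"])
        tab["abs_beta"] = tab["beta"].abs()
        tab = tab.sort_values(["p", "abs_beta", "reagent_id"],
                              ascending=[True, False, True],
                              na_position="last").drop(columns="abs_beta")
        tab = tab.reset_index(drop=True)
        if scores is not None:
            tab["score"] = tab["reagent_id"].map(scores)
        out[ph] = tab
    return out


@dataclass(frozen=True)
class LassoReport:
    phenotype: str
    feature_set: str
    family: ModelFamily
    r2: float | None
    auc: float | None
    sensitivity: float | None
    specificity: float | None
    n_train: int
    n_test: int
    n_features: int
    best_penalty: float
    fold_scheme: str
    seed: int


def lasso_performance(matrix: ExpressionMatrix, phenotype: pd.Series,
                      feature_ids: list[str] | None = None,
                      feature_set: str = "complete",
                      n_lambdas: int = 100, seed: int = 0) -> LassoReport:
    """Held-out performance of an L1-penalized model of one phenotype.

    Single 80/20 split (stratified for binary phenotypes); the penalty is
    tuned on the training portion by 5-fold cross-validation repeated 5
    times over a 100-point log-spaced grid spanning four decades below the
    data-derived maximal penalty, selecting by AUC (binary) or RMSE
    (continuous).  Deterministic under ``seed``.
    """
    from sklearn.linear_model import LassoCV, LogisticRegressionCV
    from sklearn.metrics import r2_score, roc_auc_score
    from sklearn.model_selection import (RepeatedKFold,
                                         RepeatedStratifiedKFold,
                                         train_test_split)

    if feature_ids is None:
        feature_ids = matrix.reagent_ids
    if len(feature_ids) < 2:
        raise ValueError("need at least 2 features")
    shared = [s for s in matrix.sample_ids if s in phenotype.index
              and not pd.isna(phenotype[s])]
    if len(shared) < 50:
        raise ValueError("need at least 50 complete samples")
    X = matrix.values.loc[feature_ids, shared].to_numpy(dtype=float).T
    y = phenotype.loc[shared].to_numpy(dtype=float)
    binary = set(np.unique(y)) <= {0.0, 1.0}
    if binary and len(np.unique(y)) < 2:
        raise ValueError("binary phenotype has a single class")
    strat = y if binary else None
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.2, random_state=seed, stratify=strat)
    fold_scheme = "5-fold CV repeated 5 times on an 80% training split"
    if binary:
        cv = RepeatedStratifiedKFold(n_splits=5, n_repeats=5,
                                     random_state=seed)
        # grid in C = 1/lambda; lambda_max from the score equation at beta=0
        lam_max = np.abs(X_tr.T @ (y_tr - y_tr.mean())).max() / len(y_tr)
        Cs = 1.0 / (len(y_tr) * np.logspace(np.log10(lam_max) - 4,
                                            np.log10(lam_max), n_lambdas))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            model = LogisticRegressionCV(
                Cs=Cs, cv=cv, penalty="l1", solver="liblinear",
                scoring="roc_auc", random_state=seed, max_iter=2000)
            model.fit(X_tr, y_tr)
        prob = model.predict_proba(X_te)[:, 1]
        pred = (prob >= 0.5).astype(float)
        tp = float(((pred == 1) & (y_te == 1)).sum())
        tn = float(((pred == 0) & (y_te == 0)).sum())
        fn = float(((pred == 0) & (y_te == 1)).sum())
        fp = float(((pred == 1) & (y_te == 0)).sum())
        return LassoReport(
            phenotype=str(phenotype.name), feature_set=feature_set,
            family=ModelFamily.LOGISTIC, r2=None,
            auc=float(roc_auc_score(y_te, prob)),
            sensitivity=tp / (tp + fn) if tp + fn else np.nan,
            specificity=tn / (tn + fp) if tn + fp else np.nan,
            n_train=len(y_tr), n_test=len(y_te),
            n_features=len(feature_ids),
            best_penalty=float(1.0 / (model.C_[0] * len(y_tr))),
            fold_scheme=fold_scheme, seed=seed)
    cv = RepeatedKFold(n_splits=5, n_repeats=5, random_state=seed)
    lam_max = np.abs(X_tr.T @ (y_tr - y_tr.mean())).max() / len(y_tr)
    alphas = np.logspace(np.log10(lam_max) - 4, np.log10(lam_max), n_lambdas)
    model = LassoCV(alphas=alphas, cv=cv, max_iter=50000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X_tr, y_tr)
    pred = model.predict(X_te)
    return LassoReport(
        phenotype=str(phenotype.name), feature_set=feature_set,
        family=ModelFamily.LINEAR, r2=float(r2_score(y_te, pred)),
        auc=None, sensitivity=None, specificity=None,
        n_train=len(y_tr), n_test=len(y_te), n_features=len(feature_ids),
        best_penalty=float(model.alpha_), fold_scheme=fold_scheme, seed=seed)
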