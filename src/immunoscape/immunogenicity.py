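"""Lasso model of tumor immunogenicity.

The response is a per-patient cytotoxicity score — the mean of the
CD8, NK and Tgd metagene expression summaries — regressed on a wide
block of tumor-intrinsic and -extrinsic features (neo-antigen
frequencies, immunomodulators, HLA class I molecules, chemokines,
cytokines, immunosuppressive TIL abundances, cancer-germline antigen
counts).  Lasso regularization (lambda by inner cross-validation on
MSE) shrinks the feature set; the surviving coefficients are refit by
ordinary least squares and only features with BH-adjusted refit
p-values below the threshold (default 0.005) enter the final model.
This naive post-selection inference ignores the selection event — a
documented caveat.  Outer k-fold cross-validation reports mean R^2
and MSE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FeatureMatrix",
    "LassoFit",
    "cytotoxicity_score",
    "assemble_features",
    "fit_lasso_model",
]

CYTOTOXIC_COMPONENTS = ("CD8", "NK", "Tgd")


@dataclass
class FeatureMatrix:
    """Standardized patients x features design with provenance."""

    values: pd.DataFrame  # standardized (mean 0, sd 1 per column)
    means: pd.Series
    sds: pd.Series
    provenance: dict[str, str] = field(default_factory=dict)
    dropped: list[str] = field(default_factory=list)


@dataclass
class LassoFit:
    alphas: np.ndarray
    chosen_alpha: float
    coefficients: pd.Series  # lasso coefficients (standardized scale)
    refit_p: pd.Series  # BH-adjusted OLS refit p for nonzero features
    selected: list[str]  # nonzero features surviving the p filter
    final_coefficients: pd.Series  # OLS refit coefficients of `selected`
    cv_r2: float
    cv_mse: float
    cv_fold_r2: list[float] = field(default_factory=list)


def cytotoxicity_score(
    components: pd.DataFrame, names: tuple[str, str, str] = CYTOTOXIC_COMPONENTS
) -> pd.Series:
    """Mean of the three cytotoxic metagene summaries per patient."""
    missing = [n for n in names if n not in components.columns]
    if missing:
        raise KeyError(f"missing cytotoxic components: {missing}")
    bad = components[list(names)].isna().any(axis=1)
    if bad.any():
        raise ValueError(
            f"patients with missing components: {list(components.index[bad])}"
        )
    return components[list(names)].mean(axis=1).rename("cytotoxicity")


def assemble_features(blocks: dict[str, pd.DataFrame]) -> FeatureMatrix:
    """Column-bind feature blocks, complete-case, standardized.

    Patients absent from any block are excluded (complete-case
    analysis); zero-variance columns are dropped with a warning.
    Column provenance records which block each feature came from.
    """
    if not blocks:
        raise ValueError("no feature blocks supplied")
    shared = None
    for df in blocks.values():
        shared = set(df.index) if shared is None else shared & set(df.index)
    shared = sorted(shared)
    if not shared:
        raise ValueError("no patients shared by all feature blocks")
    pieces, provenance = [], {}
    for name, df in blocks.items():
        sub = df.loc[shared]
        dup = set(sub.columns) & set(provenance)
        if dup:
            sub = sub.rename(columns={c: f"{name}.{c}" for c in dup})
        for c in sub.columns:
            provenance[c] = name
        pieces.append(sub)
    x = pd.concat(pieces, axis=1).astype(float)
    if x.isna().any().any():
        bad = list(x.columns[x.isna().any()])
        raise ValueError(f"missing values after complete-case join: {bad}")
    sds = x.std(ddof=0)
    dropped = list(x.columns[sds == 0])
    if dropped:
        warnings.warn(f"dropping zero-variance features: {dropped}")
        x = x.drop(columns=dropped)
        sds = sds.drop(labels=dropped)
    means = x.mean()
    z = (x - means) / sds
    return FeatureMatrix(z, means, sds, provenance, dropped)


def _lasso_select(
    x: np.ndarray, y: np.ndarray, seed: int, inner_folds: int = 5
) -> tuple[LassoCV, np.ndarray]:
    cv = KFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    # a path floor of alpha_max/100 is ample: relevant features enter the
    # path early, and the OLS refit supplies the final coefficients
    model = LassoCV(cv=cv, alphas=60, eps=0.01, max_iter=20_000, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(x, y)
    return model, model.coef_


def fit_lasso_model(
    features: FeatureMatrix | pd.DataFrame,
    y: pd.Series,
    n_folds: int = 10,
    p_threshold: float = 0.005,
    seed: int = 0,
) -> LassoFit:
    """Lasso selection, OLS refit with BH-adjusted p filter, outer CV.

    ``y`` is centered internally.  Outer cross-validation repeats the
    full selection inside each training fold, so the reported R^2/MSE
    include the selection step.
    """
    x_df = features.values if isinstance(features, FeatureMatrix) else features
    patients = [p for p in x_df.index if p in y.index]
    x_df = x_df.loc[patients]
    yv = y.loc[patients].to_numpy(dtype=float)
    x = x_df.to_numpy(dtype=float)
    n = x.shape[0]
    if n_folds < 2 or n_folds > n:
        raise ValueError(f"n_folds={n_folds} outside [2, {n}]")
    model, coef = _lasso_select(x, yv, seed)
    coefficients = pd.Series(coef, index=x_df.columns, name="coef")
    nonzero = list(x_df.columns[coef != 0])
    refit_p = pd.Series(dtype=float)
    selected: list[str] = []
    final = pd.Series(dtype=float)
    if nonzero:
        design = sm.add_constant(x_df[nonzero].to_numpy())
        ols = sm.OLS(yv, design).fit()
        raw_p = ols.pvalues[1:]
        adj = multipletests(raw_p, method="fdr_bh")[1]
        refit_p = pd.Series(adj, index=nonzero, name="p_adj")
        selected = [f for f, p in refit_p.items() if p < p_threshold]
        if selected:
            design2 = sm.add_constant(x_df[selected].to_numpy())
            ols2 = sm.OLS(yv, design2).fit()
            final = pd.Series(ols2.params[1:], index=selected, name="coef")
    outer = KFold(n_splits=n_folds, shuffle=True, random_state=seed + 1)
    fold_r2, fold_mse = [], []
    for train, test in outer.split(x):
        m, _ = _lasso_select(x[train], yv[train], seed)
        pred = m.predict(x[test])
        resid = yv[test] - pred
        ss_tot = np.sum((yv[test] - yv[test].mean()) ** 2)
        fold_mse.append(float(np.mean(resid**2)))
        fold_r2.append(float(1 - np.sum(resid**2) / ss_tot) if ss_tot > 0 else 0.0)
    return LassoFit(
        alphas=model.alphas_,
        chosen_alpha=float(model.alpha_),
        coefficients=coefficients,
        refit_p=refit_p,
        selected=selected,
        final_coefficients=final,
        cv_r2=float(np.mean(fold_r2)),
        cv_mse=float(np.mean(fold_mse)),
        cv_fold_r2=fold_r2,
    )
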