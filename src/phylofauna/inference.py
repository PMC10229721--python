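"""Statistical layer: scaled-predictor OLS with a diversity × diversity
interaction, VIFs, studentized-residual outlier exclusion, Pearson
correlation screen, PCA vegetation factors, median splits, and report
formatting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .errors import DegenerateScalingError, RankDeficiencyError, ValidationError

__all__ = [
    "zscale",
    "ModelSpec",
    "ModelResult",
    "fit_interaction_model",
    "vif",
    "pearson_screen",
    "vegetation_factors",
    "median_split",
    "build_report",
]

OUTLIER_THRESHOLD = 3.0  # externally studentized residual
MAX_OUTLIERS = 3
T_CAP = 1e6  # reported in place of infinite t under a perfect fit


def zscale(x) -> np.ndarray:
    """Center to mean 0 and scale to SD 1 (n−1 denominator)."""
    arr = np.asarray(x, dtype=float)
    sd = arr.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DegenerateScalingError("cannot z-scale a constant vector")
    out = (arr - arr.mean()) / sd
    if isinstance(x, pd.Series):
        return pd.Series(out, index=x.index)
    return out


@dataclass(frozen=True)
class ModelSpec:
    """One Table-1-style model: a response regressed on the source factor,
    the community-weighted trait mean, phylogenetic diversity, single-trait
    functional diversity, and the diversity × diversity interaction."""

    response: str
    trait: str  # e.g. "sla" or "ldmc"; names the cwm_/rao_ columns
    phylodiv: str = "ses_mpd"
    funtraitdiv: str | None = None  # default: f"rao_{trait}"
    cwm: str | None = None  # default: f"cwm_{trait}"
    veg_factor: str | None = "veg_source"
    max_outliers: int = MAX_OUTLIERS
    outlier_threshold: float = OUTLIER_THRESHOLD
    scale_predictors: bool = True

    @property
    def funtraitdiv_col(self) -> str:
        return self.funtraitdiv or f"rao_{self.trait}"

    @property
    def cwm_col(self) -> str:
        return self.cwm or f"cwm_{self.trait}"

    @property
    def predictor_cols(self) -> list[str]:
        cols = [] if self.veg_factor is None else [self.veg_factor]
        return cols + [self.phylodiv, self.cwm_col, self.funtraitdiv_col]


@dataclass
class ModelResult:
    """Fitted interaction model: per-term statistics plus diagnostics."""

    response: str
    trait: str
    terms: list[str]
    coef: dict[str, float]
    se: dict[str, float]
    t: dict[str, float]
    p: dict[str, float]
    r2: float
    adj_r2: float
    vif: dict[str, float]
    excluded: list = field(default_factory=list)
    n_used: int = 0
    df_resid: float = 0.0
    perfect_fit: bool = False

    INTERACTION = "phylodiv:funtraitdiv"

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "trait": self.trait,
            "terms": self.terms,
            "coef": self.coef,
            "se": self.se,
            "t": self.t,
            "p": self.p,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "vif": self.vif,
            "excluded": list(self.excluded),
            "n_used": self.n_used,
            "df_resid": self.df_resid,
            "perfect_fit": self.perfect_fit,
        }


def _design(data: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, pd.Series]:
    cols = [spec.response] + spec.predictor_cols
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    sub = data[cols].dropna()
    y = sub[spec.response]
    X = pd.DataFrame(index=sub.index)
    for c in spec.predictor_cols:
        v = sub[c].astype(float)
        X[c] = zscale(v) if spec.scale_predictors else v
    # interaction always formed from the two (scaled) diversity terms
    X[ModelResult.INTERACTION] = X[spec.phylodiv] * X[spec.funtraitdiv_col]
    return X, y


def _ols(X: pd.DataFrame, y: pd.Series):
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        pairs = [
            f"{a}~{b}"
            for a in corr.index
            for b in corr.columns
            if a < b and corr.loc[a, b] > 1 - 1e-10
        ]
        raise RankDeficiencyError(
            f"singular design; collinear terms: {pairs or 'constant column present'}"
        )
    return sm.OLS(y, Xc).fit()


def fit_interaction_model(data: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Fit the interaction model with iterative outlier exclusion.

    Rows with any missing value are dropped listwise. Predictors are
    z-scaled on the rows actually used (re-scaled after each exclusion);
    the interaction is the product of the two scaled diversity terms.
    Outliers are removed one at a time — the largest externally
    studentized residual exceeding the threshold — up to ``max_outliers``.
    """
    X, y = _design(data, spec)
    excluded: list = []
    while True:
        if len(y) <= X.shape[1] + 2:
            warnings.warn("too few rows to keep excluding outliers", UserWarning, stacklevel=2)
            break
        fit = _ols(X, y)
        if len(excluded) >= spec.max_outliers:
            if spec.max_outliers > 0 and _worst_outlier(fit, spec.outlier_threshold) is not None:
                warnings.warn(
                    f"outlier cap ({spec.max_outliers}) reached with outliers remaining",
                    UserWarning,
                    stacklevel=2,
                )
            break
        worst = _worst_outlier(fit, spec.outlier_threshold)
        if worst is None:
            break
        label = y.index[worst]
        excluded.append(label)
        keep = data.drop(index=excluded)
        X, y = _design(keep, spec)

    fit = _ols(X, y)
    perfect = fit.ssr <= 1e-12 * max(1.0, float((y - y.mean()) @ (y - y.mean())))
    terms = list(X.columns)
    tvals, pvals = {}, {}
    for term in terms:
        t = float(fit.tvalues[term])
        if perfect or not np.isfinite(t):
            t = float(np.clip(t, -T_CAP, T_CAP)) if np.isfinite(t) else np.sign(fit.params[term]) * T_CAP
        tvals[term] = t
        pvals[term] = float(fit.pvalues[term]) if np.isfinite(fit.pvalues[term]) else 0.0
    return ModelResult(
        response=spec.response,
        trait=spec.trait,
        terms=terms,
        coef={t: float(fit.params[t]) for t in terms} | {"const": float(fit.params["const"])},
        se={t: float(fit.bse[t]) for t in terms},
        t=tvals,
        p=pvals,
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        vif=vif(X),
        excluded=excluded,
        n_used=int(fit.nobs),
        df_resid=float(fit.df_resid),
        perfect_fit=bool(perfect),
    )


def _worst_outlier(fit, threshold: float) -> int | None:
    resid = OLSInfluence(fit).resid_studentized_external
    resid = np.asarray(resid)
    resid = np.where(np.isfinite(resid), resid, 0.0)
    i = int(np.argmax(np.abs(resid)))
    return i if abs(resid[i]) > threshold else None


def vif(design: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factors: VIF_k = 1/(1 − R²_k) regressing column k
    on the remaining columns (with intercept). Infinite under perfect
    collinearity."""
    out = {}
    X = design.to_numpy(dtype=float)
    for k, name in enumerate(design.columns):
        others = np.delete(X, k, axis=1)
        if others.shape[1] == 0:
            out[name] = 1.0
            continue
        A = np.column_stack([np.ones(len(X)), others])
        yk = X[:, k]
        beta, *_ = np.linalg.lstsq(A, yk, rcond=None)
        resid = yk - A @ beta
        tss = ((yk - yk.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / tss if tss > 0 else 1.0
        out[name] = float("inf") if r2 >= 1 - 1e-12 else float(1.0 / (1.0 - r2))
    return out


def pearson_screen(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p with pairwise deletion.

    Cells with fewer than 3 complete pairs, or a constant column, are NaN.
    """
    cols = table.columns
    n = len(cols)
    r = pd.DataFrame(np.eye(n), index=cols, columns=cols)
    p = pd.DataFrame(np.full((n, n), np.nan), index=cols, columns=cols)
    for i in range(n):
        for j in range(i + 1, n):
            x, y = table.iloc[:, i], table.iloc[:, j]
            ok = x.notna() & y.notna()
            if ok.sum() < 3 or x[ok].nunique() < 2 or y[ok].nunique() < 2:
                r.iloc[i, j] = r.iloc[j, i] = np.nan
                continue
            rr, pp = scipy.stats.pearsonr(x[ok], y[ok])
            r.iloc[i, j] = r.iloc[j, i] = rr
            p.iloc[i, j] = p.iloc[j, i] = pp
    return r, p


def vegetation_factors(community: pd.DataFrame, n_factors: int = 2) -> pd.DataFrame:
    """Scores on the first principal components of the centred site ×
    species matrix. Sign convention: the species with the largest absolute
    loading on each component loads positively."""
    if community.shape[0] < 3 or community.shape[1] < 2:
        raise ValidationError("need at least 3 sites and 2 species for PCA")
    X = community.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    nonzero = int((s > 1e-12 * s.max()).sum()) if s.max() > 0 else 0
    k = min(n_factors, nonzero)
    if k < n_factors:
        warnings.warn(
            f"only {k} non-degenerate component(s) available", UserWarning, stacklevel=2
        )
    scores = U[:, :k] * s[:k]
    for c in range(k):
        lead = np.argmax(np.abs(Vt[c]))
        if Vt[c, lead] < 0:
            scores[:, c] *= -1
    return pd.DataFrame(
        scores, index=community.index, columns=[f"veg_pc{i + 1}" for i in range(k)]
    )


def median_split(values: pd.Series) -> tuple[pd.Series, float]:
    """Label sites 'below'/'above' the sample median; ties go to 'below'."""
    v = values.dropna()
    if len(v) < 2:
        raise ValidationError("need at least 2 values for a median split")
    threshold = float(v.median())
    labels = pd.Series(
        np.where(v <= threshold, "below", "above"), index=v.index, name="phylodiv_group"
    )
    if (labels == "below").all():
        warnings.warn("all values at or below the median", UserWarning, stacklevel=2)
    return labels, threshold


def _mark(p: float) -> str:
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "."
    return ""


def build_report(results: list[ModelResult]) -> pd.DataFrame:
    """Format fitted models into one row per (trait, response).

    Each term renders as "t (p)" with ** for p < 0.05 and . for
    0.05 ≤ p < 0.1. Two-sided p-values, no multiple-testing correction.
    """
    if not results:
        raise ValidationError("no model results to report")
    rows = []
    for res in results:
        row = {"trait": res.trait, "response": res.response, "n_sites": res.n_used}
        for term in res.terms:
            row[term] = f"{res.t[term]:.2f} ({res.p[term]:.2f}){_mark(res.p[term])}"
        row["r2"] = round(res.r2, 2)
        row["adj_r2"] = round(res.adj_r2, 2)
        rows.append(row)
    return pd.DataFrame(rows)
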