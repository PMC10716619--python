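"""Statistical layer: Kruskal-Wallis with Dunn/Holm post-hocs, the nested
log-linear mixed determinants model with percent-change reporting, VIF
collinearity diagnostics and single-term AIC screening."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy import stats

from .lmm import NestedLmmFit, SingularDesignError, fit_nested_lmm

ALPHA = 0.05


class CollinearityError(ValueError):
    """A design column is an exact linear combination of the others."""


# ---------------------------------------------------------------------------
# Rank tests


def _rank_setup(groups: Sequence[Sequence[float]]):
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be nonempty")
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)  # midranks
    sizes = np.array([len(g) for g in groups])
    split = np.split(ranks, np.cumsum(sizes)[:-1])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    return split, sizes, len(pooled), tie_term


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Tie-corrected H statistic with a chi-square reference (df = k - 1)."""
    split, sizes, n, tie_term = _rank_setup(groups)
    if n < 3:
        raise ValueError("need total N >= 3")
    rank_sums = np.array([r.sum() for r in split])
    h = 12.0 / (n * (n + 1)) * np.sum(rank_sums**2 / sizes) - 3.0 * (n + 1)
    correction = 1.0 - tie_term / (n**3 - n)
    if correction <= 0:  # all values identical
        return 0.0, len(sizes) - 1, 1.0
    h /= correction
    df = len(sizes) - 1
    return float(h), df, float(stats.chi2.sf(h, df))


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_holm: float


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment with monotonicity enforcement."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for k, idx in enumerate(order):
        running = max(running, (m - k) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
) -> list[PairwiseComparison]:
    """All pairwise Dunn z tests, Holm-adjusted within this one family.

    ``z = (mean rank a - mean rank b) / sqrt((N(N+1)/12 - T/(12(N-1))) *
    (1/n_a + 1/n_b))`` with ``T = sum(t^3 - t)`` over tie groups.
    """
    split, sizes, n, tie_term = _rank_setup(groups)
    k = len(sizes)
    labels = list(labels) if labels is not None else [str(i) for i in range(k)]
    mean_ranks = np.array([r.mean() for r in split])
    var_base = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    zs, praw = [], []
    for i, j in pairs:
        denom = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if denom == 0 else (mean_ranks[i] - mean_ranks[j]) / denom
        zs.append(float(z))
        praw.append(float(2 * stats.norm.sf(abs(z))))
    ph = holm_adjust(praw)
    return [
        PairwiseComparison(labels[i], labels[j], z, p, float(padj))
        for (i, j), z, p, padj in zip(pairs, zs, praw, ph)
    ]


@dataclass
class GroupTestResult:
    H: float
    df: int
    p: float
    pairwise: list[PairwiseComparison]


def group_test(
    groups: Sequence[Sequence[float]], labels: Optional[Sequence[str]] = None
) -> GroupTestResult:
    h, df, p = kruskal_wallis(groups)
    return GroupTestResult(h, df, p, dunn_posthoc(groups, labels))


# ---------------------------------------------------------------------------
# Percent change and VIF


def percent_change(
    beta: float, se: float = 0.0, df: float = np.inf
) -> tuple[float, float, float]:
    """``(exp(beta) - 1) * 100`` with a Wald CI transformed from the log scale."""
    if se < 0:
        raise ValueError("se must be >= 0")
    q = stats.t.ppf(0.975, df) if np.isfinite(df) else stats.norm.ppf(0.975)
    point = (np.exp(beta) - 1.0) * 100.0
    lo = (np.exp(beta - q * se) - 1.0) * 100.0
    hi = (np.exp(beta + q * se) - 1.0) * 100.0
    return float(point), float(lo), float(hi)


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column.

    Each column is regressed on all the others plus an intercept;
    ``VIF = 1/(1 - R^2)``.  Exact collinearity raises, naming the column.
    """
    if design.shape[1] < 2:
        raise ValueError("need at least 2 design columns")
    if design.shape[0] < design.shape[1] + 1:
        raise ValueError("need more rows than columns")
    out = {}
    X = design.to_numpy(float)
    n = X.shape[0]
    exact = []
    for j, col in enumerate(design.columns):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        sst = float(np.sum((yj - yj.mean()) ** 2))
        if sst == 0:
            out[col] = np.nan
            continue
        r2 = 1.0 - float(resid @ resid) / sst
        if 1.0 - r2 < 1e-10:
            exact.append(col)
            out[col] = np.inf
        else:
            out[col] = 1.0 / (1.0 - r2)
    if exact:
        raise CollinearityError(
            f"exactly collinear column(s) with infinite VIF: {exact}"
        )
    return pd.Series(out, name="vif")


# ---------------------------------------------------------------------------
# Determinants model


@dataclass
class FixedTerm:
    name: str
    reference: Optional[str] = None  # None -> numeric linear term

    def formula(self) -> str:
        if self.reference is None:
            return self.name
        return f"C(Q('{self.name}'), Treatment(reference={self.reference!r}))"


@dataclass
class ModelSpec:
    outcome: str  # column holding the (positive) daily mean to be logged
    fixed_terms: list[FixedTerm]
    city_col: str = "city_id"
    child_col: str = "child_id"


@dataclass
class LmmFit:
    """Determinants-model fit on the log scale plus the percent-change table."""

    alpha: float
    table: pd.DataFrame  # term, level, reference, beta, se, df, p, pct_change, ci
    sigma2_location: float
    sigma2_child: float
    sigma2_resid: float
    aic: float  # from the ML refit, for screening comparability
    loglik_reml: float
    df_method: str
    converged: bool
    n_obs: int
    raw: NestedLmmFit = field(repr=False, default=None)


def _design(spec: ModelSpec, data: pd.DataFrame):
    rhs = " + ".join([t.formula() for t in spec.fixed_terms]) or "1"
    mat = dmatrix("1 + " + rhs, data, return_type="dataframe")
    return mat


def _pretty_names(columns: Sequence[str], terms: Sequence[FixedTerm]):
    """Map patsy column names to (term, level, reference) triples."""
    rows = []
    for col in columns:
        if col == "Intercept":
            rows.append(("Intercept", "", ""))
            continue
        matched = False
        for t in terms:
            if t.reference is not None and f"Q('{t.name}')" in col:
                level = col.split("[T.", 1)[1].rstrip("]") if "[T." in col else col
                rows.append((t.name, level, t.reference))
                matched = True
                break
            if t.reference is None and col == t.name:
                rows.append((t.name, "", ""))
                matched = True
                break
        if not matched:
            rows.append((col, "", ""))
    return rows


def fit_lmm(
    spec: ModelSpec,
    data: pd.DataFrame,
    df_method: str = "satterthwaite",
) -> LmmFit:
    """REML fit of the log-outcome nested mixed model, ML refit for AIC.

    The outcome must be strictly positive; percent changes are
    ``(exp(beta) - 1) * 100`` with 95% Wald CIs on the log scale.
    """
    y_raw = data[spec.outcome].to_numpy(float)
    if np.any(~np.isfinite(y_raw)) or np.any(y_raw <= 0):
        raise ValueError("outcome must be finite and strictly positive")
    y = np.log(y_raw)
    mat = _design(spec, data)
    names = list(mat.columns)
    X = mat.to_numpy(float)
    city = data[spec.city_col].to_numpy()
    child = data[spec.child_col].to_numpy()

    fit = fit_nested_lmm(y, X, city, child, names=names, reml=True,
                         df_method=df_method)
    if fit.degenerate:
        aic = -np.inf
    else:
        aic = fit_nested_lmm(y, X, city, child, names=names, reml=False).aic

    triples = _pretty_names(names, spec.fixed_terms)
    rows = []
    for j, (term, level, ref) in enumerate(triples):
        if term == "Intercept":
            continue
        pct, lo, hi = percent_change(fit.beta[j], fit.se[j], fit.df[j])
        rows.append({
            "term": term, "level": level, "reference": ref,
            "beta": fit.beta[j], "se": fit.se[j], "df": fit.df[j],
            "p": fit.pvalues[j], "pct_change": pct,
            "ci_low": lo, "ci_high": hi,
        })
    return LmmFit(
        alpha=float(fit.beta[names.index("Intercept")]),
        table=pd.DataFrame(rows),
        sigma2_location=fit.sigma2_city,
        sigma2_child=fit.sigma2_child,
        sigma2_resid=fit.sigma2_resid,
        aic=float(aic),
        loglik_reml=fit.loglik,
        df_method=fit.df_method,
        converged=fit.converged,
        n_obs=fit.n,
        raw=fit,
    )


def model_vif(spec: ModelSpec, data: pd.DataFrame) -> pd.Series:
    """VIFs of the model's design columns (intercept excluded)."""
    mat = _design(spec, data)
    return vif(mat.drop(columns="Intercept"))


def aic_screen(
    base: ModelSpec,
    candidates: Sequence[FixedTerm],
    data: pd.DataFrame,
) -> pd.DataFrame:
    """Single-term screen: each candidate is added alone to the base model.

    A candidate is dropped iff its addition raises the ML AIC *and* it is
    not significant (likelihood-ratio p >= 0.05).  Returns a ledger with
    ``delta_aic`` and ``p`` for every candidate.
    """
    base_names = {t.name for t in base.fixed_terms}
    for c in candidates:
        if c.name in base_names:
            raise ValueError(f"candidate {c.name!r} already in base model")
        if c.name not in data.columns:
            raise ValueError(f"candidate {c.name!r} not present in data")

    y = np.log(data[base.outcome].to_numpy(float))
    city = data[base.city_col].to_numpy()
    child = data[base.child_col].to_numpy()

    def ml_fit(spec_: ModelSpec):
        mat = _design(spec_, data)
        return fit_nested_lmm(
            y, mat.to_numpy(float), city, child,
            names=list(mat.columns), reml=False, df_method="normal",
        )

    base_fit = ml_fit(base)
    rows = []
    for c in candidates:
        aug = ModelSpec(
            outcome=base.outcome, fixed_terms=base.fixed_terms + [c],
            city_col=base.city_col, child_col=base.child_col,
        )
        fit_c = ml_fit(aug)
        extra = fit_c.p - base_fit.p
        lr = 2.0 * (fit_c.loglik - base_fit.loglik)
        p = float(stats.chi2.sf(max(lr, 0.0), extra)) if extra > 0 else np.nan
        delta = fit_c.aic - base_fit.aic
        kept = not (delta > 0 and p >= ALPHA)
        rows.append({
            "candidate": c.name, "delta_aic": float(delta), "p": p,
            "decision": "kept" if kept else "dropped",
        })
    return pd.DataFrame(rows, columns=["candidate", "delta_aic", "p", "decision"])
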