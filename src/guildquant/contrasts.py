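"""Gaussian-identity GLM contrasts of δ across contexts.

Context effects on diversification are estimated with a generalized linear
model (Gaussian family, identity link, fitted by iteratively reweighted
least squares), treating contexts as categorical predictors.  Rather than a
joint dummy-coded model, effects are reported as *marginal one-vs-rest
contrasts*: for each focal category (a station class, or a depth layer) the
model is refit with a single focal indicator, and the indicator's
coefficient, standard error and normal-approximation p-value are extracted.
Station contrasts ignore layer and vice versa, and each guild class (uptake
vs redox) is modelled separately.

The default response is log δ, the symmetric scale on which the density
analysis operates; raw δ is available via ``response="delta"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import GuildScore, guild_class_of, scores_to_frame
from .errors import ConfigError, InsufficientDataError

#: Significance-star thresholds (upper bounds on p), most stringent first.
STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))

AXES = ("station", "layer")


@dataclass
class FitMetrics:
    """Goodness-of-fit metrics of one GLM fit."""

    log_likelihood: float
    deviance: float
    pearson_chi2: float
    pseudo_r2_cragg_uhler: float


@dataclass
class GLMFit:
    """Coefficients and diagnostics of one Gaussian-identity GLM fit."""

    params: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    metrics: FitMetrics
    nobs: int


@dataclass
class ContrastResult:
    """One focal-category one-vs-rest contrast."""

    focal_context: str
    axis: str  # "station" | "layer"
    guild_class: str
    coef: float
    std_err: float
    p_value: float
    n: int
    n_focal: int

    def __post_init__(self) -> None:
        if self.std_err <= 0:
            raise ValueError("std_err must be > 0")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def _cragg_uhler(llf: float, llf_null: float, n: int) -> float:
    """Cragg–Uhler (Nagelkerke) pseudo R²: the Cox–Snell likelihood-ratio
    R² rescaled by its maximum attainable value, clipped to [0, 1]."""
    r2_cs = 1.0 - np.exp((2.0 / n) * (llf_null - llf))
    denom = 1.0 - np.exp((2.0 / n) * llf_null)
    if denom <= 0:
        return float(np.clip(r2_cs, 0.0, 1.0))
    return float(np.clip(r2_cs / denom, 0.0, 1.0))


def fit_glm_irls(response, design) -> GLMFit:
    """Fit a Gaussian-identity GLM by IRLS.

    ``design`` must already contain any intercept column.  p-values use the
    normal (z) approximation.  For this family/link IRLS converges to the
    ordinary-least-squares solution; the coefficients satisfy the normal
    equations to machine precision.
    """
    y = np.asarray(response, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n <= p:
        raise InsufficientDataError(f"n={n} observations for p={p} columns")
    if np.linalg.matrix_rank(X) < p:
        raise ConfigError("design matrix is rank deficient (collinear columns)")
    model = sm.GLM(y, X, family=sm.families.Gaussian(sm.families.links.Identity()))
    res = model.fit()  # IRLS
    null = sm.GLM(y, np.ones((n, 1)), family=sm.families.Gaussian()).fit()
    metrics = FitMetrics(
        log_likelihood=float(res.llf),
        deviance=float(res.deviance),
        pearson_chi2=float(res.pearson_chi2),
        pseudo_r2_cragg_uhler=_cragg_uhler(float(res.llf), float(null.llf), n),
    )
    return GLMFit(
        params=np.asarray(res.params, float),
        bse=np.asarray(res.bse, float),
        pvalues=np.asarray(res.pvalues, float),
        metrics=metrics,
        nobs=n,
    )


def _response_column(df: pd.DataFrame, response: str) -> np.ndarray:
    if response == "log_delta":
        y = df["log_delta"].to_numpy(float)
    elif response == "delta":
        y = df["delta"].to_numpy(float)
    else:
        raise ConfigError(f"unknown response {response!r}; use 'log_delta' or 'delta'")
    if not np.all(np.isfinite(y)):
        raise ConfigError("non-finite response values; filter scores first")
    return y


def one_vs_rest_rotation(
    scores,
    axes: tuple[str, ...] = AXES,
    response: str = "log_delta",
    by_guild_class: bool = True,
) -> list[ContrastResult]:
    """Rotate the focal category over every context and refit.

    For each axis ("station" → station_class categories, "layer" → depth
    layers) and each category on it, fit intercept + focal indicator and
    keep the indicator's estimate.  Categories with fewer than 2
    observations on either side are skipped (their contrast is undefined);
    all others are still emitted.
    """
    df = scores if isinstance(scores, pd.DataFrame) else scores_to_frame(list(scores))
    if df.empty:
        raise InsufficientDataError("no scores to contrast")
    df = df.copy()
    if "guild_class" not in df.columns:
        df["guild_class"] = df["gene"].map(guild_class_of)
    axis_cols = {"station": "station_class", "layer": "layer"}
    for ax in axes:
        if ax not in axis_cols:
            raise ConfigError(f"unknown axis {ax!r}")
    classes = sorted(df["guild_class"].unique()) if by_guild_class else ["all"]
    results: list[ContrastResult] = []
    for gclass in classes:
        sub = df if gclass == "all" else df[df["guild_class"] == gclass]
        y_all = _response_column(sub, response)
        for ax in axes:
            col = sub[axis_cols[ax]].to_numpy()
            categories = sorted(pd.unique(col))
            if len(categories) < 2:
                raise InsufficientDataError(f"axis {ax!r} has fewer than 2 categories")
            for cat in categories:
                focal = (col == cat).astype(float)
                n_focal = int(focal.sum())
                if n_focal < 2 or (len(focal) - n_focal) < 2:
                    continue  # contrast undefined for this category
                X = np.column_stack([np.ones_like(focal), focal])
                fit = fit_glm_irls(y_all, X)
                results.append(
                    ContrastResult(
                        focal_context=str(cat),
                        axis=ax,
                        guild_class=gclass,
                        coef=float(fit.params[1]),
                        std_err=float(fit.bse[1]),
                        p_value=float(fit.pvalues[1]),
                        n=fit.nobs,
                        n_focal=n_focal,
                    )
                )
    return results


def significance_stars(p: float) -> str:
    for bound, stars in STAR_LEVELS:
        if p < bound:
            return stars
    return ""


def summarize_table(contrasts: list[ContrastResult], alpha: float = 0.05) -> pd.DataFrame:
    """Contrast table, stations first then layers, with significance marks.

    ``significant`` applies the stated α; ``stars`` follow the documented
    thresholds (* <0.05, ** <0.01, *** <0.001, **** <0.0001).
    """
    if not contrasts:
        raise InsufficientDataError("no contrasts to summarize")
    order = {"station": 0, "layer": 1}
    rows = sorted(
        contrasts, key=lambda c: (order.get(c.axis, 9), c.focal_context, c.guild_class)
    )
    return pd.DataFrame(
        [
            (
                c.focal_context,
                c.axis,
                c.guild_class,
                c.coef,
                c.std_err,
                c.p_value,
                significance_stars(min(c.p_value, 1.0)),
                c.p_value < alpha,
                c.n,
            )
            for c in rows
        ],
        columns=[
            "context",
            "axis",
            "guild_class",
            "coef",
            "std_err",
            "p_value",
            "stars",
            "significant",
            "n",
        ],
    )


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------


@dataclass
class DeltaContrastModel:
    """One-vs-rest contrast model over a guild-score table.

    >>> model = DeltaContrastModel.from_scores(scores)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    data: pd.DataFrame
    response: str = "log_delta"
    axes: tuple[str, ...] = AXES
    by_guild_class: bool = True

    @classmethod
    def from_scores(cls, scores: list[GuildScore], **kw) -> "DeltaContrastModel":
        return cls(scores_to_frame(scores), **kw)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "DeltaContrastModel":
        return cls(df.copy(), **kw)

    def fit(self) -> "DeltaContrastResults":
        contrasts = one_vs_rest_rotation(
            self.data, axes=self.axes, response=self.response,
            by_guild_class=self.by_guild_class,
        )
        return DeltaContrastResults(model=self, contrasts=contrasts)


@dataclass
class DeltaContrastResults:
    model: DeltaContrastModel
    contrasts: list[ContrastResult] = field(default_factory=list)

    def table(self, alpha: float = 0.05) -> pd.DataFrame:
        return summarize_table(self.contrasts, alpha=alpha)

    def get(self, focal_context: str, guild_class: Optional[str] = None) -> ContrastResult:
        for c in self.contrasts:
            if c.focal_context == focal_context and (
                guild_class is None or c.guild_class == guild_class
            ):
                return c
        raise KeyError(f"no contrast for {focal_context!r} / {guild_class!r}")

    def summary(self, alpha: float = 0.05) -> str:
        df = self.table(alpha=alpha)
        lines = [
            f"One-vs-rest Gaussian-identity GLM contrasts of {self.model.response}",
            "",
            f"{'context':<16}{'axis':<9}{'class':<10}{'coef':>9}{'std err':>9}"
            f"{'P>|z|':>11}  stars",
        ]
        for r in df.itertuples(index=False):
            lines.append(
                f"{r.context:<16}{r.axis:<9}{r.guild_class:<10}{r.coef:>9.3f}"
                f"{r.std_err:>9.3f}{r.p_value:>11.3g}  {r.stars}"
            )
        return "\n".join(lines)
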