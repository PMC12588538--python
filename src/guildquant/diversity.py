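"""Expected-richness power law and per-stratum guild scores.

The number of distinct sequence variants (``d``) a marker gene shows in an
environment grows with its abundance ``A`` (FPM) approximately as a power
law::

    d_exp = c * A**gamma

Fitting this per gene — ordinary least squares of log d_obs on log A across
all of the gene's strata, pooled over taxa and environments — yields the
richness expected from abundance alone.  The diversification statistic of a
stratum is then

    delta = d_obs / d_exp

(1 = exactly as diverse as expected; <1 under-diversified; >1
over-diversified), and the guild-importance score is ``k = delta * A``,
which rewards unexpected diversity and penalizes its absence while keeping
the abundance component.  Logs are natural throughout.

The model/results pair follows the statsmodels idiom:

>>> model = RichnessAbundanceModel.from_strata(strata)
>>> res = model.fit()
>>> scores = res.score(strata)
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .abundance import top_taxa
from .datatypes import (
    DiversityFit,
    GuildScore,
    Stratum,
    frame_to_scores,
    guild_class_of,
    scores_to_frame,
    strata_to_frame,
)
from .errors import ConfigError, DegenerateInputError, InsufficientDataError, ReferenceLookupError

MIN_FIT_POINTS = 3


def _as_frame(strata) -> pd.DataFrame:
    if isinstance(strata, pd.DataFrame):
        return strata
    return strata_to_frame(list(strata))


def _fit_loglog(logA: np.ndarray, logd: np.ndarray, gene: str) -> DiversityFit:
    n = logA.size
    if n < MIN_FIT_POINTS:
        raise InsufficientDataError(
            f"{gene}: need >= {MIN_FIT_POINTS} usable strata, got {n}"
        )
    sxx = float(np.var(logA))
    if sxx == 0.0:
        raise DegenerateInputError(f"{gene}: zero variance in log A; power law unfittable")
    X = np.column_stack([np.ones(n), logA])
    beta, *_ = np.linalg.lstsq(X, logd, rcond=None)
    resid = logd - X @ beta
    dof = max(n - 2, 1)
    s2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(XtX_inv) * s2)
    ss_tot = float(np.sum((logd - logd.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    return DiversityFit(
        gene=gene,
        c=float(np.exp(beta[0])),
        gamma=float(beta[1]),
        n_points=int(n),
        r_squared=r2,
        resid_sd=float(np.sqrt(s2)),
        se_log_c=float(se[0]),
        se_gamma=float(se[1]),
    )


def fit_diversity_model(strata, gene: Optional[str] = None) -> DiversityFit:
    """Fit d = c·A^γ for one gene by least squares on log–log axes.

    ``strata`` may be a list of :class:`Stratum` or a DataFrame with columns
    A and d_obs (and gene).  Strata with A <= 0 or d_obs < 1 are excluded.
    """
    df = _as_frame(strata)
    if gene is not None:
        df = df[df["gene"] == gene]
    elif "gene" in df.columns:
        genes = df["gene"].unique()
        if len(genes) > 1:
            raise ConfigError("multiple genes present; pass gene= or use RichnessAbundanceModel")
        gene = genes[0] if len(genes) else "?"
    usable = df[(df["A"] > 0) & (df["d_obs"] >= 1)]
    return _fit_loglog(
        np.log(usable["A"].to_numpy(float)),
        np.log(usable["d_obs"].to_numpy(float)),
        gene or "?",
    )


def score_strata(strata, fits: dict[str, DiversityFit] | Iterable[DiversityFit]) -> list[GuildScore]:
    """Attach d_exp, δ, k, log δ, log k to every stratum.

    Every stratum's gene must have a fit; a missing one raises, naming the
    gene.  Scoring is row-wise and order-preserving.
    """
    if not isinstance(fits, dict):
        fits = {f.gene: f for f in fits}
    df = _as_frame(strata)
    missing = set(df["gene"]) - set(fits)
    if missing:
        raise ReferenceLookupError(f"no diversity fit for gene(s): {sorted(missing)}")
    c = df["gene"].map(lambda g: fits[g].c).to_numpy(float)
    gamma = df["gene"].map(lambda g: fits[g].gamma).to_numpy(float)
    A = df["A"].to_numpy(float)
    d_obs = df["d_obs"].to_numpy(float)
    d_exp = c * A**gamma
    delta = d_obs / d_exp
    k = delta * A
    out = df[["gene", "taxon", "station_class", "layer"]].copy()
    out["A"] = A
    out["d_obs"] = d_obs
    out["d_exp"] = d_exp
    out["delta"] = delta
    out["k"] = k
    with np.errstate(divide="ignore"):
        out["log_delta"] = np.log(delta)
        out["log_k"] = np.log(k)
    return frame_to_scores(out)


def radial_export(
    scores: list[GuildScore],
    top_n: int = 25,
    gene_order: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Radial-plot-ready table of log k by gene × taxon per analysis cell.

    Within each (station_class, layer) cell, taxa beyond the ``top_n``
    ranked by summed k are pooled as "Others".  Genes are ordered by guild
    grouping (uptake before redox, alphabetical within); ``gene_order`` may
    supply an alternative gene -> group mapping and must cover every gene.
    """
    if not scores:
        raise InsufficientDataError("radial_export needs at least one score")
    grouping = gene_order if gene_order is not None else None
    cells: dict[tuple[str, str], list[GuildScore]] = {}
    for s in scores:
        cells.setdefault((s.station_class, s.layer), []).append(s)

    def group_of(gene: str) -> str:
        if grouping is not None:
            try:
                return grouping[gene]
            except KeyError:
                raise ConfigError(f"gene {gene!r} missing from the supplied guild grouping")
        return guild_class_of(gene)

    rows = []
    for (sc, layer) in sorted(cells):
        pooled = top_taxa(cells[(sc, layer)], top_n)
        pooled.sort(key=lambda s: (group_of(s.gene) != "N_uptake", s.gene, s.taxon))
        for s in pooled:
            rows.append(
                (sc, layer, group_of(s.gene), s.gene, s.taxon, s.k, s.log_k)
            )
    return pd.DataFrame(
        rows,
        columns=["station_class", "layer", "guild_class", "gene", "taxon", "k", "log_k"],
    )


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------


@dataclass
class RichnessAbundanceModel:
    """Power-law richness model for a multi-gene stratum table.

    Parameters
    ----------
    data : DataFrame with columns gene, taxon, station_class, layer, A, d_obs.
    per_taxon : if True, fit separate (c, γ) per gene × taxon instead of the
        default per-gene fit pooled over taxa and environments.
    per_layer : if True, fit separately per gene × layer.
    """

    data: pd.DataFrame
    per_taxon: bool = False
    per_layer: bool = False

    @classmethod
    def from_strata(cls, strata: list[Stratum], **kw) -> "RichnessAbundanceModel":
        return cls(strata_to_frame(strata), **kw)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "RichnessAbundanceModel":
        return cls(df.copy(), **kw)

    def _groups(self):
        keys = ["gene"]
        if self.per_taxon:
            keys.append("taxon")
        if self.per_layer:
            keys.append("layer")
        return self.data.groupby(keys, sort=True)

    def fit(self) -> "RichnessAbundanceResults":
        fits: dict[str, DiversityFit] = {}
        for key, sub in self._groups():
            label = key[0] if len(key) == 1 else "|".join(map(str, key))
            usable = sub[(sub["A"] > 0) & (sub["d_obs"] >= 1)]
            fits[label] = _fit_loglog(
                np.log(usable["A"].to_numpy(float)),
                np.log(usable["d_obs"].to_numpy(float)),
                label,
            )
        return RichnessAbundanceResults(model=self, fits=fits)


@dataclass
class RichnessAbundanceResults:
    """Fitted per-gene power laws with uncertainties and diagnostics."""

    model: RichnessAbundanceModel
    fits: dict[str, DiversityFit]

    @property
    def params(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (f.gene, f.c, f.gamma, f.se_log_c, f.se_gamma, f.n_points, f.r_squared, f.resid_sd)
                for f in self.fits.values()
            ],
            columns=["gene", "c", "gamma", "se_log_c", "se_gamma", "n", "r_squared", "resid_sd"],
        )

    def score(self, strata=None) -> list[GuildScore]:
        """δ/k scores for ``strata`` (default: the fitting data)."""
        data = self.model.data if strata is None else strata
        return score_strata(data, self.fits)

    def score_frame(self, strata=None) -> pd.DataFrame:
        return scores_to_frame(self.score(strata))

    def summary(self) -> str:
        lines = ["Richness–abundance power law  d_exp = c · A^gamma  (log–log OLS)", ""]
        lines.append(
            f"{'gene':<12}{'c':>10}{'gamma':>10}{'se(gamma)':>11}{'n':>6}{'R2':>8}{'sd':>8}"
        )
        for f in self.fits.values():
            lines.append(
                f"{f.gene:<12}{f.c:>10.4g}{f.gamma:>10.4f}{f.se_gamma:>11.4f}"
                f"{f.n_points:>6d}{f.r_squared:>8.3f}{f.resid_sd:>8.3f}"
            )
        return "\n".join(lines)
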