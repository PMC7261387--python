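"""Repeated-measures inference on plot-level responses.

The study design is longitudinal: each plot is remeasured at every census,
so plot-level responses (AGB stock, stem count NS, mortality rate M) are
correlated within plots.  Inference uses Generalized Estimating Equations
(GEE) — population-averaged GLMs with the plot as the repeated-measures
cluster — with a log link and Gamma family for AGB, a log link and Poisson
family for stem counts, and a Gaussian family for rates.  Predictors are a
census (or interval) factor, the fire stratum (FF/NF), and their
interaction.

Term-level hypotheses use the Wald chi-square on the cluster-robust
covariance; with only 18 plot clusters the Mancl–DeRouen bias-reduced
sandwich is the default (plain and naive covariances are selectable).
Pairwise post hoc comparisons between time levels are Bonferroni-adjusted
and summarized as a compact letter display: groups sharing a letter do not
differ significantly at alpha.

Estimation itself is delegated to :mod:`statsmodels`; this module owns the
model specification, the clustering requirement, and the Wald / Bonferroni
/ letter-display post-processing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ModelSpec",
    "ModelResult",
    "fit_longitudinal",
    "bonferroni_adjust",
    "bonferroni_contrasts",
    "compact_letter_display",
]

_FAMILIES = {
    "AGB": lambda: sm.families.Gamma(link=sm.families.links.Log()),
    "NS": lambda: sm.families.Poisson(link=sm.families.links.Log()),
    "M": lambda: sm.families.Gaussian(),
}
_COV_STRUCTS = {
    "exchangeable": sm.cov_struct.Exchangeable,
    "independence": sm.cov_struct.Independence,
    "ar1": sm.cov_struct.Autoregressive,
}


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one longitudinal model.

    ``response`` selects the family: Gamma(log) for AGB, Poisson(log) for
    NS, Gaussian for M.  ``time`` names the within-plot time factor column;
    ``correlation`` is the GEE working structure; ``cov_type`` the sandwich
    flavour used for all Wald inference.
    """

    response: str  # AGB | NS | M
    value_col: str = "value"
    time: str = "census_year"
    site: str = "site"
    cluster: str = "plot_id"
    correlation: str = "exchangeable"
    cov_type: str = "bias_reduced"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.response not in _FAMILIES:
            raise ValueError(f"response must be one of {sorted(_FAMILIES)}")
        if self.correlation not in _COV_STRUCTS:
            raise ValueError(f"correlation must be one of {sorted(_COV_STRUCTS)}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class ModelResult:
    """Fitted longitudinal model plus Wald term tests."""

    spec: ModelSpec
    params: pd.DataFrame  # estimate, se, wald z, p per coefficient
    wald_terms: pd.DataFrame  # omnibus Wald chi-square per model term
    converged: bool
    gee_result: object = field(repr=False, default=None)
    data: pd.DataFrame = field(repr=False, default=None)


def fit_longitudinal(data: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Fit response ~ C(time) * C(site) by GEE with plots as clusters.

    ``data`` is a per-plot per-census table holding the cluster, time, site
    and response columns named by ``spec``.  Poisson responses must be
    non-negative integers; Gamma responses strictly positive.  A fit that
    fails to converge is returned flagged, never silently.
    """
    for col in (spec.cluster, spec.time, spec.site, spec.value_col):
        if col not in data.columns:
            raise ValueError(f"data is missing required column {col!r}")
    y = data[spec.value_col].to_numpy(dtype=float)
    if spec.response == "NS":
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("Poisson stem-count response must be "
                             "non-negative integers")
    if spec.response == "AGB" and np.any(y <= 0):
        raise ValueError("Gamma biomass response must be strictly positive")
    n_per_site = data.groupby(spec.site)[spec.cluster].nunique()
    if (n_per_site < 2).any():
        raise ValueError("need at least two plots per site for cluster-robust "
                         "inference")

    formula = (f"{spec.value_col} ~ C({spec.time}) * C({spec.site})")
    model = sm.GEE.from_formula(
        formula, groups=spec.cluster, data=data,
        family=_FAMILIES[spec.response](),
        cov_struct=_COV_STRUCTS[spec.correlation]())
    res = model.fit(cov_type=spec.cov_type, maxiter=100)
    converged = bool(getattr(res, "converged", True))

    params = pd.DataFrame({
        "term": res.params.index,
        "estimate": res.params.to_numpy(),
        "se": res.bse.to_numpy(),
        "wald_z": res.tvalues.to_numpy(),
        "p": res.pvalues.to_numpy(),
    })
    if not np.all(np.isfinite(params["se"])):
        converged = False

    wald = _wald_terms(res)
    return ModelResult(spec=spec, params=params, wald_terms=wald,
                       converged=converged, gee_result=res, data=data)


def _wald_terms(res) -> pd.DataFrame:
    """Omnibus Wald chi-square per model term (robust covariance).

    Tests that all coefficients belonging to a term are jointly zero; terms
    contributing no columns (degenerate one-level factors) are skipped.
    """
    di = res.model.data.design_info
    beta = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    rows = []
    for term, slc in di.term_name_slices.items():
        idx = np.arange(slc.start, slc.stop)
        if idx.size == 0:
            continue
        b = beta[idx]
        V = cov[np.ix_(idx, idx)]
        chi2 = float(b @ np.linalg.solve(V, b))
        rows.append({"term": term, "wald_chi2": chi2, "df": int(idx.size),
                     "p": float(stats.chi2.sf(chi2, df=idx.size))})
    return pd.DataFrame(rows)


def bonferroni_adjust(p, k: int | None = None):
    """Bonferroni family-wise adjustment: min(1, p * k); monotone, capped."""
    arr = np.asarray(p, dtype=float)
    m = k if k is not None else arr.size
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    out = np.minimum(1.0, arr * m)
    return float(out) if out.ndim == 0 else out


def _cell_rows(result: ModelResult) -> tuple[list, list, np.ndarray]:
    """Design rows for every (time, site) cell, via the fitted design info."""
    from patsy import build_design_matrices

    spec = result.spec
    di = result.gee_result.model.data.design_info
    times = sorted(result.data[spec.time].unique())
    sites = sorted(result.data[spec.site].unique())
    grid = pd.DataFrame([(t, s) for t in times for s in sites],
                        columns=[spec.time, spec.site])
    (X,) = build_design_matrices([di], grid)
    return times, sites, np.asarray(X)


def bonferroni_contrasts(result: ModelResult,
                         comparisons: list[tuple] | None = None) -> pd.DataFrame:
    """Pairwise time contrasts with Bonferroni-adjusted Wald p-values.

    Contrasts compare the marginal linear predictor of two time levels
    (averaged over sites) using the fitted model's robust covariance.
    ``comparisons`` defaults to all time-level pairs; an explicitly empty
    list is an error.  Returns a table with raw and adjusted p per pair.
    """
    if comparisons is not None and len(comparisons) == 0:
        raise ValueError("empty contrast list")
    times, sites, X = _cell_rows(result)
    n_sites = len(sites)
    # marginal (site-averaged) design row per time level
    rows = {t: X[i * n_sites:(i + 1) * n_sites].mean(axis=0)
            for i, t in enumerate(times)}
    if comparisons is None:
        comparisons = list(itertools.combinations(times, 2))
    beta = result.gee_result.params.to_numpy()
    cov = np.asarray(result.gee_result.cov_params())
    recs = []
    for a, b in comparisons:
        L = rows[a] - rows[b]
        est = float(L @ beta)
        var = float(L @ cov @ L)
        chi2 = est**2 / var if var > 0 else np.inf
        p = float(stats.chi2.sf(chi2, df=1))
        recs.append({"level_a": a, "level_b": b, "estimate": est,
                     "se": np.sqrt(var), "wald_chi2": chi2, "p_raw": p})
    out = pd.DataFrame(recs)
    out["p_adj"] = bonferroni_adjust(out["p_raw"].to_numpy(), len(out))
    out["significant"] = out["p_adj"] < result.spec.alpha
    return out


def compact_letter_display(levels: list, contrasts: pd.DataFrame,
                           alpha: float = 0.05) -> dict:
    """Letters per level; levels sharing a letter are not significantly different.

    ``contrasts`` needs columns ``level_a, level_b, p_adj``.  Uses the
    insert-and-absorb algorithm; deterministic given the (order-invariant)
    set of significant pairs.
    """
    sig = {frozenset((r.level_a, r.level_b))
           for r in contrasts.itertuples() if r.p_adj < alpha}
    groups: list[set] = [set(levels)]
    for pair in sorted(sig, key=lambda fs: sorted(map(str, fs))):
        a, b = sorted(pair, key=str)
        for g in [g for g in groups if a in g and b in g]:
            groups.remove(g)
            groups.extend([g - {a}, g - {b}])
        # absorb groups contained in another
        groups = [g for g in groups
                  if g and not any(g < h for h in groups if h is not g)]
        # deduplicate
        uniq = []
        for g in groups:
            if g not in uniq:
                uniq.append(g)
        groups = uniq
    groups.sort(key=lambda g: sorted(map(str, g)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {lv: "" for lv in levels}
    for i, g in enumerate(groups):
        for lv in sorted(g, key=str):
            letters[lv] += alphabet[i % 26]
    return letters
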