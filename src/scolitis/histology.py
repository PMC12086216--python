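"""Poisson and quasi-Poisson regression of probe-positive histology counts.

Per-image probe-positive cell counts are modeled on cohort (MC as the
reference level) with the log of the per-image DAPI-stained cell total as an
offset, so coefficients are log rate ratios of positive cells per imaged
cell.  Quasi-Poisson inference rescales the Poisson standard errors by the
square root of the Pearson dispersion (chi^2 / residual df) and takes
p-values from a t distribution on the residual df; Poisson p-values are Wald
z tests.  Images are treated as independent units.

Two significance modes mirror the two assay workflows: ``ihc`` BH-adjusts
p-values across stains and requires adjusted p < 0.05 against both control
cohorts; ``rnascope`` applies a raw p < 0.05 cutoff against both cohorts and
reports where Poisson and quasi-Poisson disagree.  IHC counts default to no
offset (summed field counts, constant exposure) with a flag to enable one.

The speckle rule (a cell is "high" for a speckle-pattern probe when it shows
at least 5 speckles) is a pure threshold kept here; image segmentation is
out of scope — the input boundary is the per-image count table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .pseudobulk import bh_adjust

logger = logging.getLogger(__name__)

REFERENCE_COHORT = "MC"


def classify_speckle_high(speckle_count: int, threshold: int = 5) -> bool:
    """True iff a cell's speckle count reaches the threshold (default 5)."""
    if speckle_count < 0:
        raise ValueError("speckle count must be nonnegative")
    return speckle_count >= threshold


@dataclass
class CountFit:
    """One probe's fitted count regression.

    ``params`` / ``bse`` / ``pvalues`` are indexed by coefficient name
    (intercept plus one contrast per non-reference cohort); ``rate_ratios``
    are exp(coefficient) per contrast.  ``dispersion`` is None for the plain
    Poisson fit and the Pearson chi^2 / df estimate after quasi-Poisson
    adjustment (SEs scaled by its square root).
    """

    probe: str
    reference: str
    cohorts: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    rate_ratios: pd.Series
    conf_int: pd.DataFrame
    df_resid: int
    kind: str = "poisson"
    dispersion: float | None = None
    degenerate: bool = False
    boundary_cohorts: tuple[str, ...] = ()
    _fitted: np.ndarray | None = field(default=None, repr=False)
    _observed: np.ndarray | None = field(default=None, repr=False)


def _design(records: pd.DataFrame, reference: str):
    cohorts = [reference] + sorted(c for c in records["cohort"].unique() if c != reference)
    if len(cohorts) < 2:
        raise ValueError("need at least 2 cohorts to fit a contrast model")
    X = np.ones((len(records), len(cohorts)))
    names = ["intercept"]
    for k, cohort in enumerate(cohorts[1:], start=1):
        X[:, k] = (records["cohort"] == cohort).to_numpy(dtype=float)
        names.append(f"cohort[{cohort}]")
    return X, names, tuple(cohorts)


def poisson_fit(
    records: pd.DataFrame,
    probe: str,
    reference: str = REFERENCE_COHORT,
    use_offset: bool = True,
) -> CountFit:
    """Maximum-likelihood Poisson regression of count ~ cohort with log-DAPI offset.

    Fitted by iteratively reweighted least squares (relative deviance change
    below 1e-8 or 50 iterations).  For a two-group model the fitted rate
    ratio equals the closed-form ratio of pooled rates.  A cohort whose
    counts are all zero puts its coefficient at the boundary and is flagged.
    """
    sub = records[records["probe"] == probe]
    if sub.empty:
        raise ValueError(f"no records for probe {probe!r}")
    if sub["cohort"].nunique() < 2:
        raise ValueError(f"probe {probe!r} observed in fewer than 2 cohorts")
    if use_offset and (sub["dapi_total"] <= 0).any():
        raise ValueError("dapi_total must be positive when used as offset")

    y = sub["count"].to_numpy(dtype=float)
    X, names, cohorts = _design(sub, reference)
    offset = np.log(sub["dapi_total"].to_numpy(dtype=float)) if use_offset else None

    boundary = tuple(
        cohort
        for cohort in cohorts
        if sub.loc[sub["cohort"] == cohort, "count"].sum() == 0
    )
    if boundary:
        logger.warning("probe %s: all-zero counts in cohorts %s (boundary)", probe, boundary)

    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
    res = model.fit(maxiter=50, tol=1e-8)
    if not res.converged and not boundary:
        raise RuntimeError(f"Poisson IRLS failed to converge for probe {probe!r}")

    params = pd.Series(res.params, index=names)
    bse = pd.Series(res.bse, index=names)
    pvalues = pd.Series(res.pvalues, index=names)  # Wald z
    ci = pd.DataFrame(res.conf_int(), index=names, columns=["lo", "hi"])
    rr = np.exp(params.drop("intercept"))
    return CountFit(
        probe=probe,
        reference=reference,
        cohorts=cohorts,
        params=params,
        bse=bse,
        pvalues=pvalues,
        rate_ratios=rr.rename("rate_ratio"),
        conf_int=ci,
        df_resid=int(res.df_resid),
        kind="poisson",
        boundary_cohorts=boundary,
        _fitted=np.asarray(res.mu),
        _observed=y,
    )


def quasipoisson_adjust(fit: CountFit) -> CountFit:
    """Quasi-Poisson inference: scale SEs by sqrt(Pearson chi^2 / df).

    P-values are recomputed from a t distribution on the residual df.  A fit
    with all observations exactly at their means has dispersion 0 and is
    flagged degenerate.
    """
    if fit._fitted is None or fit._observed is None:
        raise ValueError("fit does not carry residual information")
    if fit.df_resid <= 0:
        raise ValueError("residual degrees of freedom must be positive")
    pearson = float(((fit._observed - fit._fitted) ** 2 / fit._fitted).sum())
    dispersion = pearson / fit.df_resid
    if dispersion < 1e-12:  # all observations at their fitted means
        dispersion = 0.0
    degenerate = dispersion == 0
    scale = np.sqrt(dispersion) if dispersion > 0 else np.nan
    bse = fit.bse * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = fit.params / bse
    pvalues = pd.Series(
        2 * stats.t.sf(np.abs(tvals), df=fit.df_resid), index=fit.params.index
    )
    tcrit = stats.t.ppf(0.975, df=fit.df_resid)
    ci = pd.DataFrame(
        {"lo": fit.params - tcrit * bse, "hi": fit.params + tcrit * bse},
        index=fit.params.index,
    )
    if degenerate:
        pvalues[:] = np.nan
    return CountFit(
        probe=fit.probe,
        reference=fit.reference,
        cohorts=fit.cohorts,
        params=fit.params,
        bse=bse,
        pvalues=pvalues,
        rate_ratios=fit.rate_ratios,
        conf_int=ci,
        df_resid=fit.df_resid,
        kind="quasipoisson",
        dispersion=dispersion,
        degenerate=degenerate,
        _fitted=fit._fitted,
        _observed=fit._observed,
    )


def _contrast_p(fit: CountFit | None, cohort: str) -> float:
    if fit is None:
        return np.nan
    name = f"cohort[{cohort}]"
    return float(fit.pvalues.get(name, np.nan))


def cohort_significance(
    fits: dict[str, dict[str, CountFit]],
    mode: str = "rnascope",
    comparisons: tuple[str, ...] = ("chronic_diarrhea", "unaffected"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Apply the dual-comparison significance rule across probes.

    ``fits`` maps probe -> {"poisson": CountFit, "quasipoisson": CountFit}
    (quasipoisson optional).  ``ihc`` mode BH-adjusts the Poisson p-values
    across probes within each contrast and requires adjusted p < alpha for
    both contrasts; ``rnascope`` mode uses raw p < alpha for both contrasts,
    under each regression separately, and reports Poisson/quasi-Poisson
    discordance per probe.  Probes missing a contrast are flagged
    not-testable.
    """
    if mode not in ("ihc", "rnascope"):
        raise ValueError("mode must be 'ihc' or 'rnascope'")

    rows = []
    for probe, pair in fits.items():
        pois = pair.get("poisson")
        quasi = pair.get("quasipoisson")
        row = {"probe": probe}
        testable = True
        for cohort in comparisons:
            p = _contrast_p(pois, cohort)
            row[f"p_poisson_{cohort}"] = p
            row[f"p_quasipoisson_{cohort}"] = _contrast_p(quasi, cohort)
            name = f"cohort[{cohort}]"
            if pois is not None and name in pois.rate_ratios.index:
                row[f"rate_ratio_{cohort}"] = float(pois.rate_ratios[name])
            if np.isnan(p):
                testable = False
        row["testable"] = testable
        row["dispersion"] = None if quasi is None else quasi.dispersion
        rows.append(row)
    out = pd.DataFrame(rows)

    if mode == "ihc":
        for cohort in comparisons:
            adj = np.full(len(out), np.nan)
            mask = out["testable"].to_numpy()
            if mask.any():
                adj[mask] = bh_adjust(out.loc[mask, f"p_poisson_{cohort}"].to_numpy())
            out[f"p_adj_{cohort}"] = adj
        sig = out["testable"].to_numpy().copy()
        for cohort in comparisons:
            sig &= out[f"p_adj_{cohort}"].to_numpy() < alpha
        out["significant"] = sig
    else:
        sig_pois = out["testable"].to_numpy().copy()
        sig_quasi = out["testable"].to_numpy().copy()
        for cohort in comparisons:
            sig_pois &= out[f"p_poisson_{cohort}"].to_numpy() < alpha
            q = out[f"p_quasipoisson_{cohort}"].to_numpy()
            sig_quasi &= np.where(np.isnan(q), False, q < alpha)
        out["significant_poisson"] = sig_pois
        out["significant_quasipoisson"] = sig_quasi
        out["discordant"] = sig_pois != sig_quasi
        out["significant"] = sig_pois & sig_quasi
    return out


def fit_all_probes(
    records: pd.DataFrame,
    reference: str = REFERENCE_COHORT,
    use_offset: bool = True,
) -> dict[str, dict[str, CountFit]]:
    """Poisson + quasi-Poisson fits for every probe in a count table."""
    out: dict[str, dict[str, CountFit]] = {}
    for probe in sorted(records["probe"].unique()):
        pois = poisson_fit(records, probe, reference=reference, use_offset=use_offset)
        out[probe] = {"poisson": pois, "quasipoisson": quasipoisson_adjust(pois)}
    return out
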