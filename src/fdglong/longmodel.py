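"""Per-ROI longitudinal mixed-effects model for the carrier-by-time interaction.

For each region the SUVR trajectory is modelled as

    suvr ~ sex + education_years + baseline_age + month + carrier + carrier:month

with a random intercept per subject (optionally a random slope on
month), estimated by REML.  The carrier:month coefficient — the
difference in SUVR decline per month between ApoE e4 carriers and
non-carriers — is the quantity of interest, tested with a two-sided
Wald z test.  Time is continuous in months from baseline; the carrier
main effect is kept alongside the interaction for model hierarchy.

No multiple-testing correction is applied across regions, matching the
per-ROI p < .05 reporting convention of the study design this package
reproduces; this is a documented limitation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .phantom import SubjectRecord

__all__ = ["LMMResult", "fit_roi_lmm", "summarize_regions"]

_INTERACTION = "carrier:month"


@dataclass(frozen=True)
class LMMResult:
    """Fitted interaction for one region."""

    region: str
    interaction_estimate: float
    interaction_se: float
    interaction_p: float
    coefficients: dict[str, float] = field(default_factory=dict)
    n_obs: int = 0
    converged: bool = False


def _design_frame(table: pd.DataFrame, region: str, subjects: list[SubjectRecord]) -> pd.DataFrame:
    sub = table[table["region"] == region].copy()
    if sub.empty:
        raise ValueError(f"region {region!r} not present in the SUVR table")
    covars = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "male": [1 if s.sex == "M" else 0 for s in subjects],
            "education_years": [s.education_years for s in subjects],
            "baseline_age": [s.baseline_age for s in subjects],
            "carrier_int": [int(s.carrier) for s in subjects],
        }
    )
    df = sub.merge(covars, on="subject_id", how="inner")
    df["carrier"] = df["carrier_int"]
    return df


def fit_roi_lmm(
    table: pd.DataFrame,
    region: str,
    subjects: list[SubjectRecord],
    random_slope: bool = False,
    reml: bool = True,
) -> LMMResult:
    """Fit the longitudinal model for one region and test carrier:month.

    Returns ``converged=False`` with NaN statistics (no p-value is
    reported) if the optimiser fails or the fit is singular.
    """
    df = _design_frame(table, region, subjects)
    n_obs = len(df)
    if df.groupby("carrier")["subject_id"].nunique().reindex([0, 1]).fillna(0).min() < 2:
        raise ValueError("need at least 2 subjects per carrier group")

    # fit with time in years: with months the random-slope variance is
    # ~1e4 times smaller than the intercept variance and the REML
    # surface becomes too ill-conditioned for the optimisers.  All
    # reported quantities are rescaled back to per-month units.
    scale = 12.0
    df = df.assign(time=df["month"] / scale)
    formula = "suvr ~ male + education_years + baseline_age + time + carrier + carrier:time"
    re_formula = "~time" if random_slope else "1"
    best = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, df, groups=df["subject_id"], re_formula=re_formula)
            # optimisers can report convergence at spurious stationary
            # points of the REML surface; fit with several and keep the
            # converged result with the highest restricted likelihood
            methods = (None,) if not random_slope else (None, "powell", "cg")
            for method in methods:
                try:
                    result = model.fit(reml=reml) if method is None else model.fit(
                        reml=reml, method=method, maxiter=200
                    )
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if not np.isfinite(result.params.get("carrier:time", np.nan)):
                    continue
                if not np.isfinite(result.llf):
                    continue
                key = (bool(result.converged), float(result.llf))
                if best is None or key > best[0]:
                    best = (key, result)
            if (best is None or not best[0][0]) and not random_slope:
                try:
                    result = model.fit(reml=reml, method="powell", maxiter=200)
                    if np.isfinite(result.params.get("carrier:time", np.nan)):
                        key = (bool(result.converged), float(result.llf))
                        if best is None or key > best[0]:
                            best = (key, result)
                except (np.linalg.LinAlgError, ValueError):
                    pass
    except (np.linalg.LinAlgError, ValueError):
        best = None
    if best is None:
        return LMMResult(region, float("nan"), float("nan"), float("nan"), {}, n_obs, False)
    result = best[1]

    params = {}
    for k, v in result.params.items():
        name = k.replace("time", "month")
        params[name] = float(v / scale) if "time" in k and "Var" not in k and "Cov" not in k else float(v)
    est = float(result.params["carrier:time"] / scale)
    se = float(result.bse["carrier:time"] / scale)
    p = float(result.pvalues["carrier:time"])
    converged = bool(result.converged) and np.isfinite(est)
    if not converged:
        p = float("nan")
    return LMMResult(region, est, se, p, params, n_obs, converged)


def summarize_regions(
    results: list[LMMResult],
    alpha: float = 0.05,
    results_no_pvc: list[LMMResult] | None = None,
) -> pd.DataFrame:
    """Report table of regions sorted by interaction p-value.

    A region is flagged when its interaction estimate is negative
    (greater decline in carriers) and p < alpha.  When a matching
    non-PVC run is supplied its columns are placed side by side.
    """
    if not results:
        raise ValueError("no model results to summarize")

    def frame(res: list[LMMResult], suffix: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": [r.region for r in res],
                f"estimate{suffix}": [r.interaction_estimate for r in res],
                f"se{suffix}": [r.interaction_se for r in res],
                f"p{suffix}": [r.interaction_p for r in res],
                f"converged{suffix}": [r.converged for r in res],
                f"flagged{suffix}": [
                    bool(r.converged and r.interaction_estimate < 0 and r.interaction_p < alpha)
                    for r in res
                ],
            }
        )

    out = frame(results, "_pvc" if results_no_pvc is not None else "")
    if results_no_pvc is not None:
        out = out.merge(frame(results_no_pvc, "_nopvc"), on="region", how="outer")
        sort_col = "p_pvc"
    else:
        sort_col = "p"
    return out.sort_values(sort_col, ignore_index=True)
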