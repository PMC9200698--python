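"""Random-intercept model of log10 inlet concentrations.

The model explains measured inlet concentrations (log10 ng/L) from
application timing and amount, substance properties, event discharge and
the attributed transport category, with the sampled inlet as a random
intercept:

    log10(c) ~ t_appl + log10(m_appl) + log10(K_foc) + DT50_water
               + DT50_soil + log10(Q_mod) + C(p_transport) + (1 | inlet)

Estimation is by restricted maximum likelihood (statsmodels ``MixedLM``).
The two sorption covariates log10(K_foc) and log10(K_ow) are nearly
collinear for typical panels; when their correlation exceeds a gate the
one whose single-variable deletion yields the lower (ML) AIC is removed
before the final fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = ["ModelFrameReport", "LmmFit", "build_model_frame", "drop_collinear", "fit_lmm"]

#: fixed-effect covariates of the full frame, in model order
COVARIATES = [
    "t_appl",
    "log10_m_appl",
    "log10_k_foc",
    "log10_kow",
    "dt50_water",
    "dt50_soil",
    "log10_q_mod",
]


@dataclass
class ModelFrameReport:
    """Row/substance exclusions applied while building the frame."""

    n_samples_in: int = 0
    n_rows_out: int = 0
    substances_kept: list[str] = field(default_factory=list)
    substances_no_properties: list[str] = field(default_factory=list)
    substances_no_ca_application: list[str] = field(default_factory=list)
    rows_dropped_no_prior_application: int = 0
    rows_dropped_zero_mass: int = 0
    rows_dropped_zero_discharge: int = 0


def build_model_frame(
    samples: pd.DataFrame,
    exposure_table: pd.DataFrame,
    applications,
    substances,
    event_q_mod: pd.DataFrame,
    categories: pd.Series,
    events_by_id: dict,
    *,
    inlet_sites: list[str] | None = None,
    censored_substitution: str = "loq",
) -> tuple[pd.DataFrame, ModelFrameReport]:
    """Assemble the model frame: one row per retained (sample, substance).

    The dataset is reduced to substances with properties available and at
    least one application inside the contributing area of an inlet.
    Censored responses are substituted (by the LOQ by default, or LOQ/2)
    before the log transform.  ``t_appl`` is the number of days since the
    most recent application with runoff or drift potential to the sampled
    inlet, falling back to the most recent in-catchment application; rows
    without any prior application, with zero applied mass or with zero
    event discharge are dropped (log undefined) and counted in the report.
    """
    if censored_substitution not in ("loq", "half"):
        raise ValueError("censored_substitution must be 'loq' or 'half'")
    props = {s.name: s for s in substances}
    report = ModelFrameReport(n_samples_in=len(samples))

    # substance filter: properties + >= 1 application in an inlet CA
    if inlet_sites is None:
        inlet_sites = sorted(samples["site"].unique())
    in_ca = set()
    if len(exposure_table):
        mask = exposure_table["runoff"] & exposure_table["site"].isin(inlet_sites)
        in_ca = set(exposure_table.loc[mask, "substance"])
    sampled_subs = sorted(set(samples["substance"]))
    keep = []
    for s in sampled_subs:
        if s not in props:
            report.substances_no_properties.append(s)
        elif s not in in_ca:
            report.substances_no_ca_application.append(s)
        else:
            keep.append(s)
    report.substances_kept = keep

    apps_by_sub: dict[str, list] = {}
    for a in applications:
        apps_by_sub.setdefault(a.substance, []).append(a)

    q_mod = event_q_mod.set_index(["site", "event_id"])["q_mod_l"] if len(event_q_mod) else pd.Series(dtype=float)

    rows = []
    for idx, row in samples.iterrows():
        sub = row["substance"]
        if sub not in props or sub not in in_ca or row["site"] not in inlet_sites:
            continue
        p = props[sub]
        ev = events_by_id[row["event_id"]]
        event_date = pd.Timestamp(ev.start).normalize()

        prior = [a for a in apps_by_sub.get(sub, []) if pd.Timestamp(a.date).normalize() <= event_date]
        if not prior:
            report.rows_dropped_no_prior_application += 1
            continue
        # most recent application with transport potential to this inlet
        relevant_dates = []
        if len(exposure_table):
            er = exposure_table[
                (exposure_table["site"] == row["site"])
                & (exposure_table["substance"] == sub)
                & (exposure_table["application_date"].map(lambda d: pd.Timestamp(d).normalize()) <= event_date)
            ]
            relevant_dates = [pd.Timestamp(d).normalize() for d in er["application_date"]]
        if relevant_dates:
            last = max(relevant_dates)
        else:
            last = max(pd.Timestamp(a.date).normalize() for a in prior)
        t_appl = float((event_date - last).days)

        m_appl = sum(a.mass_g for a in prior)
        if m_appl <= 0:
            report.rows_dropped_zero_mass += 1
            continue
        q = float(q_mod.get((row["site"], row["event_id"]), np.nan))
        if not np.isfinite(q) or q <= 0:
            report.rows_dropped_zero_discharge += 1
            continue

        if row["censored"]:
            c = p.loq_ng_l if censored_substitution == "loq" else p.loq_ng_l / 2.0
        else:
            c = row["value_ng_l"]
        if c <= 0:
            report.rows_dropped_zero_mass += 1
            continue
        rows.append(
            {
                "log10_c": np.log10(c),
                "t_appl": t_appl,
                "log10_m_appl": np.log10(m_appl),
                "log10_k_foc": np.log10(p.k_foc),
                "log10_kow": p.log10_kow,
                "dt50_water": p.dt50_water_d,
                "dt50_soil": p.dt50_soil_d,
                "log10_q_mod": np.log10(q),
                "p_transport": categories.loc[idx],
                "inlet": row["site"],
                "substance": sub,
            }
        )
    frame = pd.DataFrame(rows)
    report.n_rows_out = len(frame)
    return frame, report


def _formula(covariates: list[str]) -> str:
    rhs = " + ".join(covariates + ["C(p_transport)"])
    return f"log10_c ~ {rhs}"


def drop_collinear(
    frame: pd.DataFrame,
    pair: tuple[str, str] = ("log10_k_foc", "log10_kow"),
    threshold: float = 0.7,
) -> tuple[pd.DataFrame, dict]:
    """Resolve the sorption-covariate collinearity by AIC of deletions.

    If |corr| of the pair exceeds ``threshold``, the model is fitted twice
    (maximum likelihood), once deleting each member; the member whose
    deletion gives the lower AIC is removed from the frame.  Below the
    gate the frame is returned unchanged.
    """
    a, b = pair
    report: dict = {"correlation": np.nan, "removed": None, "aic": {}}
    if a not in frame.columns or b not in frame.columns:
        return frame, report
    corr = float(frame[a].corr(frame[b]))
    report["correlation"] = corr
    if not np.isfinite(corr) or abs(corr) < threshold:
        return frame, report
    present = [c for c in COVARIATES if c in frame.columns]
    for drop in (a, b):
        covs = [c for c in present if c != drop]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.mixedlm(_formula(covs), frame, groups=frame["inlet"]).fit(reml=False)
        report["aic"][drop] = float(res.aic)
    removed = min(report["aic"], key=report["aic"].get)
    report["removed"] = removed
    return frame.drop(columns=[removed]), report


@dataclass
class LmmFit:
    """Fitted random-intercept model summary."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    re_variance: float
    llf: float
    n_rows: int
    n_substances: int
    singular: bool = False
    converged: bool = True


def fit_lmm(frame: pd.DataFrame, *, reml: bool = True) -> LmmFit:
    """Fit the random-intercept model (REML by default).

    Requires at least two inlets and ten rows.  Fixed-effect p-values are
    Wald normal-approximation values.  A singular fit (random-intercept
    variance collapsing to zero) is flagged and its variance reported
    as 0.
    """
    if frame["inlet"].nunique() < 2:
        raise ValueError("frame is degenerate: need >= 2 inlets")
    if len(frame) < 10:
        raise ValueError("frame is degenerate: need >= 10 rows")
    covs = [c for c in COVARIATES if c in frame.columns]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(_formula(covs), frame, groups=frame["inlet"])
        res = model.fit(reml=reml)
    # cov_re is already on the response scale in statsmodels
    re_var = float(np.asarray(res.cov_re).ravel()[0])
    singular = re_var < 1e-10
    fe = res.fe_params.index
    return LmmFit(
        params=res.params[fe],
        bse=res.bse[fe],
        pvalues=res.pvalues[fe],
        re_variance=0.0 if singular else re_var,
        llf=float(res.llf),
        n_rows=len(frame),
        n_substances=frame["substance"].nunique() if "substance" in frame.columns else 0,
        singular=singular,
        converged=bool(res.converged),
    )
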