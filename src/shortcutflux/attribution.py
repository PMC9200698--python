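"""Transport-pathway attribution of measured concentrations.

Each (sample, substance) concentration is assigned to one category from the
spatio-temporal relation between pesticide applications and the sampling
site:

* **A** — no reported application in the catchment before the event;
* **B** — applied before the event, but on a plot allowing neither spray
  drift nor surface runoff to the site ("other" processes: spills, droplet
  losses, farmyard runoff, ...);
* **C** — spray drift to the site possible (plot within 100 m of the site,
  directly or via a road draining to it), surface runoff not;
* **D** — surface runoff possible (plot intersects the site's contributing
  area); for the collector shaft and the stream this category additionally
  carries a tile-drainage annotation.

Precedence is D > C > B > A.  Application dates are day-resolved, so a
same-day application counts as "before" the event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TransportCategory", "assign_category", "assign_categories", "category_concentration_summary"]

_PRECEDENCE = {"A": 0, "B": 1, "C": 2, "D": 3}


@dataclass
class TransportCategory:
    """An attribution label with its supporting evidence."""

    label: str
    matched_applications: list = field(default_factory=list)
    runoff: bool = False
    drift: bool = False
    prior_application: bool = False
    tile_drainage_possible: bool = False
    #: set when the site's contributing area touches plots without
    #: application data, so the label could be an underestimate
    coverage_flag: bool = False


def _to_date(value) -> pd.Timestamp:
    return pd.Timestamp(value).normalize()


def assign_category(
    site: str,
    event_start,
    substance: str,
    exposure_table: pd.DataFrame,
    applications,
    *,
    downstream_sites: tuple[str, ...] = ("CS", "ST"),
    unknown_coverage_sites: tuple[str, ...] = (),
) -> TransportCategory:
    """Attribute one (site, event, substance) concentration to A/B/C/D."""
    event_date = _to_date(event_start)
    prior = [
        a for a in applications if a.substance == substance and _to_date(a.date) <= event_date
    ]
    runoff = False
    drift = False
    matched: list = []
    if len(exposure_table):
        rows = exposure_table[
            (exposure_table["site"] == site)
            & (exposure_table["substance"] == substance)
            & (exposure_table["application_date"].map(_to_date) <= event_date)
        ]
        runoff = bool(rows["runoff"].any())
        drift = bool((rows["drift_direct"] | rows["drift_indirect"]).any())
        matched = rows["application_id"].tolist()
    if runoff:
        label = "D"
    elif drift:
        label = "C"
    elif prior:
        label = "B"
    else:
        label = "A"
    return TransportCategory(
        label=label,
        matched_applications=matched,
        runoff=runoff,
        drift=drift,
        prior_application=bool(prior),
        tile_drainage_possible=(label == "D" and site in downstream_sites),
        coverage_flag=site in unknown_coverage_sites,
    )


def assign_categories(
    samples: pd.DataFrame,
    events_by_id: dict,
    exposure_table: pd.DataFrame,
    applications,
    **kwargs,
) -> pd.Series:
    """Vector version over a samples table with columns site/event_id/substance."""
    labels = []
    for _, row in samples.iterrows():
        ev = events_by_id[row["event_id"]]
        start = ev.start if hasattr(ev, "start") else ev
        labels.append(
            assign_category(
                row["site"], start, row["substance"], exposure_table, applications, **kwargs
            ).label
        )
    return pd.Series(labels, index=samples.index, name="category")


def category_concentration_summary(samples: pd.DataFrame) -> pd.DataFrame:
    """Concentration distribution per transport category.

    ``samples`` needs columns category, value_ng_l, loq_ng_l, censored and
    optionally a site-group column ``group``.  Censored values are
    represented by the substance LOQ.  Returns n, median and quartiles per
    category (and group, when present).
    """
    df = samples.copy()
    df["conc"] = np.where(df["censored"], df["loq_ng_l"], df["value_ng_l"])
    keys = ["group", "category"] if "group" in df.columns else ["category"]
    out = (
        df.groupby(keys)["conc"]
        .agg(n="count", median="median", q25=lambda s: s.quantile(0.25), q75=lambda s: s.quantile(0.75))
        .reset_index()
    )
    return out
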