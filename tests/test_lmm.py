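"""Random-intercept concentration model: frame building, collinearity, fitting."""

import subprocess
import sys
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from shortcutflux.lmm import build_model_frame, drop_collinear, fit_lmm
from shortcutflux.synthetic import DEFAULT_TRUE_COEFS, simulate_model_frame


class TestSimulatedFrame:
    def test_sorption_covariates_strongly_correlated(self):
        frame, _ = simulate_model_frame(seed=0)
        assert abs(frame["log10_k_foc"].corr(frame["log10_kow"])) > 0.9

    def test_determinism(self):
        a, _ = simulate_model_frame(seed=4)
        b, _ = simulate_model_frame(seed=4)
        assert a.equals(b)


class TestDropCollinear:
    def test_uncorrelated_covariates_not_removed(self):
        frame, _ = simulate_model_frame(seed=1, kow_noise_sd=10.0)  # destroys correlation
        assert abs(frame["log10_k_foc"].corr(frame["log10_kow"])) < 0.7
        out, report = drop_collinear(frame)
        assert report["removed"] is None and "log10_kow" in out.columns

    def test_duplicated_covariate_removes_exactly_one(self):
        frame, _ = simulate_model_frame(seed=2, kow_noise_sd=1e-12)
        out, report = drop_collinear(frame)
        assert report["removed"] in ("log10_k_foc", "log10_kow")
        assert ("log10_k_foc" in out.columns) != ("log10_kow" in out.columns)

    def test_noisy_copy_removed_in_most_seeds(self):
        """K_foc causal, K_ow a noisy copy with zero effect: the AIC
        deletion rule should drop K_ow almost always."""
        removed = []
        for seed in range(60):
            frame, _ = simulate_model_frame(n_substances=40, seed=seed)
            _, report = drop_collinear(frame)
            removed.append(report["removed"])
        share_kow = sum(r == "log10_kow" for r in removed) / len(removed)
        assert share_kow >= 0.95


class TestFit:
    def test_requires_non_degenerate_frame(self):
        frame, _ = simulate_model_frame(seed=0)
        with pytest.raises(ValueError, match="inlets"):
            fit_lmm(frame[frame["inlet"] == "I1"])
        with pytest.raises(ValueError, match="rows"):
            fit_lmm(frame.groupby("inlet").head(1))

    def test_zero_between_inlet_variation_gives_zero_variance(self):
        frame, _ = simulate_model_frame(seed=3, re_sd=0.0, n_inlets=4, n_per_inlet=80)
        fit = fit_lmm(frame.drop(columns=["log10_kow"]))
        assert fit.re_variance < 0.01

    def test_row_order_invariance(self):
        frame, _ = simulate_model_frame(seed=5, n_inlets=4, n_per_inlet=40)
        frame = frame.drop(columns=["log10_kow"])
        a = fit_lmm(frame)
        b = fit_lmm(frame.sample(frac=1.0, random_state=0))
        assert np.allclose(a.params.values, b.params[a.params.index].values, atol=1e-6)

    def test_matches_ols_when_group_effect_vanishes(self):
        """With no between-inlet variation the mixed fit collapses onto
        ordinary least squares (closed-form oracle)."""
        frame, _ = simulate_model_frame(seed=6, re_sd=0.0, n_inlets=4, n_per_inlet=100)
        frame = frame.drop(columns=["log10_kow"])
        fit = fit_lmm(frame)
        rhs = "t_appl + log10_m_appl + log10_k_foc + dt50_water + dt50_soil + log10_q_mod + C(p_transport)"
        ols = smf.ols(f"log10_c ~ {rhs}", frame).fit()
        common = [p for p in fit.params.index if p in ols.params.index]
        assert np.allclose(fit.params[common], ols.params[common], atol=5e-3)

    def test_matches_lme4_reference(self, tmp_path):
        """Cross-check the REML fixed effects against lme4 via Rscript."""
        frame, _ = simulate_model_frame(seed=7, n_inlets=4, n_per_inlet=40)
        frame = frame.drop(columns=["log10_kow"])
        fit = fit_lmm(frame)
        csv = tmp_path / "frame.csv"
        frame.to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- lmer(log10_c ~ t_appl + log10_m_appl + log10_k_foc + dt50_water
                      + dt50_soil + log10_q_mod + p_transport + (1|inlet),
                      data=d, REML=TRUE)
            fe <- fixef(m)
            write.csv(data.frame(term=names(fe), est=as.numeric(fe)),
                      "{tmp_path / 'fe.csv'}", row.names=FALSE)
            """
        )
        subprocess.run(["Rscript", str(rscript)], check=True, capture_output=True)
        fe = pd.read_csv(tmp_path / "fe.csv").set_index("term")["est"]
        mapping = {
            "(Intercept)": "Intercept",
            "t_appl": "t_appl",
            "log10_m_appl": "log10_m_appl",
            "log10_k_foc": "log10_k_foc",
            "dt50_water": "dt50_water",
            "dt50_soil": "dt50_soil",
            "log10_q_mod": "log10_q_mod",
            "p_transportB": "C(p_transport)[T.B]",
            "p_transportC": "C(p_transport)[T.C]",
            "p_transportD": "C(p_transport)[T.D]",
        }
        for r_name, py_name in mapping.items():
            assert fit.params[py_name] == pytest.approx(fe[r_name], abs=2e-3)


class TestBuildModelFrame:
    def test_frame_filters_and_substitution(self, small_dataset, small_report):
        """Substances need properties and an application in an inlet CA;
        censored responses become log10(LOQ)."""
        rep = small_report
        ds = small_dataset
        samples = ds.samples[ds.samples["site"].isin(["I1", "I2", "I3", "I4"])]
        events_by_id = {
            int(r.event_id): type("E", (), {"start": r.start})()
            for r in rep.events.itertuples()
        }
        q_mod = pd.DataFrame(
            [
                {"site": s, "event_id": e, "q_mod_l": 100.0}
                for s in ["I1", "I2", "I3", "I4"]
                for e in rep.events["event_id"]
            ]
        )
        frame, report = build_model_frame(
            samples,
            rep.exposure,
            ds.applications,
            ds.substances,
            q_mod,
            rep.categories.loc[samples.index],
            events_by_id,
            inlet_sites=["I1", "I2", "I3", "I4"],
        )
        assert report.n_rows_out == len(frame)
        kept = set(report.substances_kept)
        assert kept and set(frame["substance"]).issubset(kept)
        # censored substitution by the LOQ bounds every response from below
        loqs = {s.name: s.loq_ng_l for s in ds.substances}
        assert (frame["log10_c"] >= np.log10(min(loqs.values())) - 1e-9).all()

    def test_substance_without_properties_excluded(self, small_dataset, small_report):
        ds = small_dataset
        rep = small_report
        samples = ds.samples[ds.samples["site"].isin(["I1", "I2", "I3", "I4"])].copy()
        ghost = samples.iloc[[0]].assign(substance="unobtainium")
        samples2 = pd.concat([samples, ghost], ignore_index=False)
        cats = rep.categories.loc[samples.index]
        cats2 = pd.concat([cats, pd.Series(["A"], index=ghost.index)])
        events_by_id = {
            int(r.event_id): type("E", (), {"start": r.start})()
            for r in rep.events.itertuples()
        }
        frame, report = build_model_frame(
            samples2, rep.exposure, ds.applications, ds.substances,
            pd.DataFrame(columns=["site", "event_id", "q_mod_l"]),
            cats2, events_by_id, inlet_sites=["I1", "I2", "I3", "I4"],
        )
        assert "unobtainium" in report.substances_no_properties
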