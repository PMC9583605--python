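"""Outcome metrics and desk-scale scenario ensemble properties."""

from types import SimpleNamespace

import numpy as np
import pytest

from mcpafate import (
    Scenario,
    default_layers,
    depth_interval_series,
    detectability_duration,
    dt50,
    ensemble_summary,
    hre_clr_difference,
)


class TestDetectability:
    def test_never_above_threshold(self):
        assert detectability_duration(np.arange(10.0), np.ones(10)) == 0.0

    def test_step_series_above_until_day_k(self):
        t = np.arange(0.0, 31.0)
        c = np.where(t <= 12, 10.0, 0.0)
        dur = detectability_duration(t, c)
        assert dur == pytest.approx(12.0 + (10.0 - 3.0) / 10.0, abs=1e-9)

    def test_pulse_window_length(self):
        """A pulse arriving later counts only its detectable window."""
        t = np.arange(0.0, 21.0)
        c = np.zeros_like(t)
        c[5:15] = 8.0
        dur = detectability_duration(t, c)
        assert 9.0 < dur < 11.0

    def test_interpolated_crossing(self):
        t = np.array([0.0, 1.0, 2.0])
        c = np.array([9.0, 9.0, 1.0])
        # down-crossing at t = 1 + (9-3)/(9-1) = 1.75
        assert detectability_duration(t, c) == pytest.approx(1.75)


class TestDT50:
    @staticmethod
    def _fake(times, degraded_frac):
        return SimpleNamespace(times_days=times,
                               degraded_cum=degraded_frac * 100.0,
                               initial_mass=100.0)

    def test_first_order_decay_closed_form(self):
        k = 0.23
        t = np.linspace(0.0, 30.0, 301)
        res = self._fake(t, 1.0 - np.exp(-k * t))
        assert dt50(res) == pytest.approx(np.log(2.0) / k, rel=1e-3)

    def test_unreached_flagged_nan(self):
        t = np.arange(5.0)
        res = self._fake(t, 0.01 * t)
        assert np.isnan(dt50(res))


class TestEnsembleSummary:
    def test_identical_realizations_zero_width_ci(self):
        s = np.array([1.0, 2.0, 3.0])
        df = ensemble_summary([s, s, s])
        assert np.allclose(df["ci99_lo"], df["ci99_hi"])

    def test_three_value_toy_sem(self):
        df = ensemble_summary([np.array([1.0]), np.array([2.0]),
                               np.array([6.0])])
        assert df["mean"][0] == pytest.approx(3.0)
        assert df["sem"][0] == pytest.approx(
            np.std([1, 2, 6], ddof=1) / np.sqrt(3))
        assert df["ci99_hi"][0] == pytest.approx(3.0 + 2.5758293 * df["sem"][0])

    def test_ci_width_shrinks_with_sqrt_n(self):
        rng = np.random.default_rng(0)
        pool = [rng.normal(size=5) for _ in range(64)]
        w16 = ensemble_summary(pool[:16])["sem"].mean()
        w64 = ensemble_summary(pool)["sem"].mean()
        assert w64 == pytest.approx(w16 / 2.0, rel=0.35)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ensemble_summary([])


class TestHreClrDifference:
    @staticmethod
    def _fake(times, ct):
        return SimpleNamespace(times_days=times, domain_CT_mg_kg=ct)

    def test_identical_runs_zero(self):
        t = np.arange(4.0)
        ct = np.array([1.0, 0.8, 0.5, 0.2])
        df = hre_clr_difference(self._fake(t, ct), self._fake(t, ct.copy()))
        assert np.allclose(df["delta_CT_norm"], 0.0)

    def test_bounded_and_normalized(self):
        t = np.arange(3.0)
        clr = self._fake(t, np.array([2.0, 1.0, 0.5]))
        hre = self._fake(t, np.array([2.0, 1.6, 0.1]))
        diff = hre_clr_difference(clr, hre)["delta_CT_norm"].to_numpy()
        assert np.all(np.abs(diff) <= 1.0)
        assert diff[1] == pytest.approx(0.3)

    def test_mismatched_axes_rejected(self):
        with pytest.raises(ValueError):
            hre_clr_difference(self._fake(np.arange(3.0), np.ones(3)),
                               self._fake(np.arange(4.0), np.ones(4)))


class TestDepthIntervals:
    def test_initial_mass_in_top_interval(self, hom_hre_column, layers):
        df = depth_interval_series(hom_hre_column, layers)
        row0 = df.iloc[0]
        assert row0["0-10 cm"] > 0
        assert row0.drop("0-10 cm").max() < 1e-9 * row0["0-10 cm"]

    def test_interval_masses_sum_to_domain_mean(self, hom_hre_column, layers):
        df = depth_interval_series(hom_hre_column, layers)
        rho_default = default_layers()
        # reconstruct interval soil masses and compare the weighted sum
        res = hom_hre_column
        rho = np.concatenate([
            np.full(np.count_nonzero((res.y_centers >= l.depth_top)
                                     & (res.y_centers < l.depth_bottom)),
                    l.rho_b) for l in layers])
        total = 0.0
        msum = 0.0
        for col in df.columns:
            a, b = [float(v) / 100.0 for v in col.replace(" cm", "").split("-")]
            sel = (res.y_centers >= a) & (res.y_centers < b)
            m = (res.y_widths[sel] * rho[sel]).sum()
            total += df[col].iloc[-1] * m
            msum += m
        assert total / msum == pytest.approx(res.domain_CT_mg_kg[-1], rel=1e-9)

    def test_two_cell_toy_weighted_mean(self):
        res = SimpleNamespace(
            times_days=np.array([0.0]),
            y_centers=np.array([0.025, 0.075]),
            y_widths=np.array([0.05, 0.05]),
            row_CT_mg_kg=np.array([[2.0, 6.0]]),
        )
        layer = default_layers()[0]
        df = depth_interval_series(res, [layer], interval=0.1)
        assert df["0-10 cm"].iloc[0] == pytest.approx(4.0)


class TestScenarioDefinition:
    def test_hom_is_single_deterministic_realization(self):
        assert Scenario("HOM", "CLR").n_real == 1
        assert Scenario("HOM", "CLR", n_realizations=7).n_real == 1

    def test_unknown_labels_rejected(self):
        with pytest.raises(ValueError):
            Scenario("MED", "CLR")
        with pytest.raises(ValueError):
            Scenario("HOM", "DRIZZLE")


class TestDeskEnsembles:
    """Scaled-down scenario reproductions (identical code paths)."""

    def test_residual_concentration_ordering(self, desk_runs):
        """HOM ~ LOW <= HIGH <= EXTR residual MCPA at matched times."""
        final = {k: np.mean([r.domain_CT_mg_kg[-1]
                             for r in v.realizations])
                 for k, v in desk_runs.items() if k.endswith("CLR")}
        assert final["LOW-CLR"] == pytest.approx(final["HOM-CLR"], rel=0.10)
        assert final["HIGH-CLR"] >= final["LOW-CLR"] * 0.98
        assert final["EXTR-CLR"] >= final["HIGH-CLR"]

    def test_low_hardly_distinguishable_from_hom(self, desk_runs):
        hom = desk_runs["HOM-CLR"].realizations[0].domain_CT_mg_kg
        low = np.mean([r.domain_CT_mg_kg
                       for r in desk_runs["LOW-CLR"].realizations], axis=0)
        rel = np.abs(low[1:] - hom[1:]) / hom[1:]
        assert rel.max() < 0.10

    def test_r_minus_mfa_more_negative_with_heterogeneity(self, desk_runs):
        """Scale-transition correction deepens from HOM to HIGH to EXTR."""
        day = 10
        vals = {}
        for k in ("HOM-CLR", "HIGH-CLR", "EXTR-CLR"):
            d = desk_runs[k].summary_decomposition()
            vals[k] = d["R_minus_MFA"].iloc[day]
        assert vals["HOM-CLR"] >= vals["HIGH-CLR"] >= vals["EXTR-CLR"]

    def test_cov_zero_in_hom(self, desk_runs):
        d = desk_runs["HOM-CLR"].summary_decomposition()
        assert np.allclose(d["COV"], 0.0)
        d = desk_runs["HOM-HRE"].summary_decomposition()
        assert np.allclose(d["COV"], 0.0)

    def test_var_term_non_positive_everywhere(self, desk_runs):
        for k, v in desk_runs.items():
            d = v.summary_decomposition()
            assert (d["VAR"] <= 1e-15).all(), k

    def test_cov_magnitude_drops_during_heavy_rain(self, desk_runs):
        """Rain homogenizes the substrate: |COV| shrinks across an event."""
        d = desk_runs["EXTR-HRE"].summary_decomposition().set_index("time_days")
        assert abs(d["COV"].loc[3.0]) < abs(d["COV"].loc[2.0])

    def test_hre_clr_difference_sign_flip(self, desk_runs):
        """Rain events slow degradation in HOM but speed it up in EXTR."""
        from mcpafate import hre_clr_difference

        hom = hre_clr_difference(
            desk_runs["HOM-CLR"].realizations[0],
            desk_runs["HOM-HRE"].realizations[0])["delta_CT_norm"]
        assert hom.loc[8.0] > 0
        diffs = []
        for clr, hre in zip(desk_runs["EXTR-CLR"].realizations,
                            desk_runs["EXTR-HRE"].realizations):
            diffs.append(hre_clr_difference(clr, hre)["delta_CT_norm"].loc[8.0])
        assert np.mean(diffs) < 0

    def test_mcpa_stays_shallow(self, desk_runs):
        """Depth reach of the pulse: under continuous light rain nothing is
        detectable below 20 cm; heavy rain pushes MCPA to ~30 cm but the
        subsoil signal stays an order of magnitude below the layer above."""
        from mcpafate.params import default_layers as dl

        lay = dl(buffer_bottom=0.6)
        for key, sr in desk_runs.items():
            for r in sr.realizations:
                df = depth_interval_series(r, lay) * 1000.0  # ug/kg
                if key.endswith("CLR"):
                    for c in ("20-30 cm", "30-40 cm"):
                        assert (df[c] < 3.0).all(), (key, c)
                else:
                    deep = [c for c in df.columns
                            if float(c.split("-")[0]) >= 30]
                    peak_2030 = df["20-30 cm"].max()
                    for c in deep:
                        assert df[c].max() < 0.1 * peak_2030, (key, c)

    def test_dt50_insensitive_to_dispersivity(self, dispersivity_runs):
        """DT50 varies < 10% across lambda_L in 0.01-0.1 m."""
        vals = [dt50(r) for r in dispersivity_runs.values()]
        assert np.isfinite(vals).all()
        assert (max(vals) - min(vals)) / min(vals) < 0.10

    def test_leaching_increases_with_heterogeneity(self, desk_runs):
        hom = desk_runs["HOM-HRE"].realizations[0].cum_leached_frac[-1]
        extr = np.mean([r.cum_leached_frac[-1]
                        for r in desk_runs["EXTR-HRE"].realizations])
        assert extr >= hom

    def test_reproducible_ensemble(self):
        """Fixed seeds reproduce the ensemble summary bit-identically."""
        from mcpafate import run_scenario

        a = run_scenario(Scenario("HIGH", "CLR", n_realizations=2,
                                  t_end_days=3.0))
        b = run_scenario(Scenario("HIGH", "CLR", n_realizations=2,
                                  t_end_days=3.0))
        assert np.array_equal(a.summary_domain_CT()["mean"],
                              b.summary_domain_CT()["mean"])
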