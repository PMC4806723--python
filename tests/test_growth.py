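"""Growth components, log-linear growth slopes, Δ conversion, ANOVA battery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from invasionphys import growth as gr
from invasionphys import synthetic_data as sd

positive = st.floats(1e-3, 1e3, allow_nan=False, allow_infinity=False)


def record(total, leaf, root, area):
    return pd.DataFrame(
        [
            {
                "total_mass": total,
                "leaf_mass": leaf,
                "root_mass": root,
                "shoot_mass": total - root,
                "leaf_area": area,
            }
        ]
    )


class TestComponents:
    def test_worked_arithmetic(self):
        out = gr.compute_components(record(2.0, 1.0, 0.5, 200.0)).iloc[0]
        assert out.sla == pytest.approx(200.0)
        assert out.lar == pytest.approx(100.0)
        assert out.lmr == pytest.approx(0.5)
        assert out.rmr == pytest.approx(0.25)
        assert out.root_shoot == pytest.approx(0.5 / 1.5)
        assert not out.component_flag

    @given(leaf=positive, root=positive, extra=positive, area=positive)
    @settings(max_examples=200, derandomize=True)
    def test_identities_hold_for_any_positive_record(self, leaf, root, extra, area):
        """LAR = SLA x LMR and RMR + shoot fraction = 1, record-wise."""
        total = leaf + root + extra
        out = gr.compute_components(record(total, leaf, root, area)).iloc[0]
        assert out.lar == pytest.approx(out.sla * out.lmr, rel=1e-12)
        assert out.rmr + (total - root) / total == pytest.approx(1.0, rel=1e-12)

    def test_zero_denominator_flagged_not_nan_silent(self):
        out = gr.compute_components(record(2.0, 0.0, 0.5, 200.0)).iloc[0]
        assert out.component_flag
        assert np.isnan(out.sla)


class TestGrowthRates:
    @staticmethod
    def _exponential(rgr=0.10, lar_const=True):
        ages = np.repeat([10.0, 20.0, 30.0], 4)
        total = 0.01 * np.exp(rgr * ages)
        area = 100.0 * total if lar_const else 50.0 * total**0.5
        return pd.DataFrame(
            {
                "species": "invasive",
                "year": "warm",
                "age": ages,
                "total_mass": total,
                "leaf_area": area,
            }
        )

    def test_noiseless_exponential_recovers_slope_and_nar_zero(self):
        """Constant LAR: leaf area tracks mass, so ln(W/A) is flat."""
        (r,) = gr.fit_growth_rates(self._exponential())
        assert r.rgr == pytest.approx(0.10, abs=1e-12)
        assert r.leaf_area_rgr == pytest.approx(0.10, abs=1e-12)
        assert r.nar_slope == pytest.approx(0.0, abs=1e-12)

    def test_exact_line_through_ln_mass(self):
        df = pd.DataFrame(
            {
                "species": "s",
                "year": "y",
                "age": [0.0, 10.0, 20.0],
                "total_mass": np.exp([0.0, 1.0, 2.0]),
                "leaf_area": [1.0, 2.0, 3.0],
            }
        )
        (r,) = gr.fit_growth_rates(df)
        assert r.rgr == pytest.approx(0.10, abs=1e-14)

    def test_slope_matches_closed_form_least_squares(self):
        rng = np.random.default_rng(8)
        ages = rng.uniform(10, 100, 50)
        ln_mass = 0.07 * ages + rng.normal(0, 0.3, 50)
        df = pd.DataFrame(
            {
                "species": "s",
                "year": "y",
                "age": ages,
                "total_mass": np.exp(ln_mass),
                "leaf_area": np.exp(ln_mass) * 80.0,
            }
        )
        (r,) = gr.fit_growth_rates(df)
        xc = ages - ages.mean()
        slope_ref = np.sum(xc * ln_mass) / np.sum(xc * xc)
        assert r.rgr == pytest.approx(slope_ref, rel=1e-12)

    def test_slope_additivity_identity(self, harvests):
        """RGR = NAR slope + leaf-area slope, by linearity of least squares."""
        for r in gr.fit_growth_rates(harvests):
            assert r.rgr == pytest.approx(r.nar_slope + r.leaf_area_rgr, abs=1e-12)

    def test_single_age_rejected(self):
        df = self._exponential().query("age == 10.0")
        with pytest.raises(ValueError, match="two distinct ages"):
            gr.fit_growth_rates(df)


class TestRelativeChangeLar:
    @pytest.mark.parametrize(
        "early, late, expected", [(100, 150, 0.5), (100, 100, 0.0), (100, 60, -0.4)]
    )
    def test_examples(self, early, late, expected):
        assert gr.relative_change_lar(early, late) == pytest.approx(expected)

    def test_nonpositive_early_rejected(self):
        with pytest.raises(ValueError):
            gr.relative_change_lar(0.0, 50.0)


class TestDelta:
    def test_zero_when_plant_equals_air(self):
        assert gr.delta_from_d13c(-8.0, -8.0) == pytest.approx(0.0)

    def test_direct_evaluation(self):
        # (−8 − (−28)) / (1 − 28/1000) = 20 / 0.972
        assert gr.delta_from_d13c(-28.0, -8.0) == pytest.approx(20.0 / 0.972)

    def test_monotone_decreasing_in_plant_delta(self):
        grid = np.linspace(-35.0, -10.0, 50)
        vals = gr.delta_from_d13c(grid)
        assert np.all(np.diff(vals) < 0)

    @given(st.floats(-40, -5), st.floats(-12, -6))
    @settings(max_examples=100, derandomize=True)
    def test_round_trip_inversion(self, d_plant, d_air):
        delta = gr.delta_from_d13c(d_plant, d_air)
        assert gr.d13c_from_delta(delta, d_air) == pytest.approx(d_plant, abs=1e-10)

    def test_singularity_rejected(self):
        with pytest.raises(ValueError):
            gr.delta_from_d13c(-1000.0)


class TestAnovaBattery:
    def test_rgr_ancova_structure(self, harvests):
        t = gr.rgr_ancova(harvests)
        assert list(t.term[:4]) == ["age", "species", "year", "species x year"]
        age = t[t.term == "age"].iloc[0]
        assert age.df_num == 1
        assert age.p < 1e-6  # growth through time is unmissable
        # year varies between plots -> tested in the plot stratum
        year = t[t.term == "year"].iloc[0]
        assert year.df_den == t[t.term == "plot"].iloc[0].df_num

    def test_rgr_ancova_detects_true_interaction(self, harvests):
        """Defaults have a 0.04 vs 0.005 day^-1 species-by-year RGR contrast."""
        t = gr.rgr_ancova(harvests)
        assert t[t.term == "species x year"].iloc[0].p < 0.01

    def test_midseason_anova_log_transform_matters(self, harvests):
        """ln-transform is applied: skipping it changes the species F."""
        from invasionphys.linear_models import ModelSpec, fit_anova

        t_log = gr.midseason_anova(harvests, "sla")
        recs = gr.compute_components(harvests)
        at95 = recs[recs.age == 95]
        t_raw = fit_anova(
            at95,
            ModelSpec(
                response="sla",
                fixed_factors=["species", "year"],
                interactions=[("species", "year")],
                random_factor="plot",
            ),
        )
        f_log = t_log[t_log.term == "species"].iloc[0].F
        f_raw = t_raw[t_raw.term == "species"].iloc[0].F
        assert f_log != pytest.approx(f_raw, rel=1e-3)

    def test_midseason_anova_unknown_component_rejected(self, harvests):
        with pytest.raises(ValueError, match="unknown component"):
            gr.midseason_anova(harvests, "nar")

    def test_leafchem_error_df_is_n_minus_4(self):
        """Five plants per species x year cell leaves 16 error df."""
        rng = np.random.default_rng(12)
        iso = pd.DataFrame(
            {
                "species": np.repeat(["invasive", "native"], 10),
                "year": np.tile(np.repeat(["warm", "cool"], 5), 2),
                "leaf_n": rng.normal(2.5, 0.3, 20),
            }
        )
        t = gr.leafchem_anova(iso, "leaf_n")
        assert t[t.term == "residual"].iloc[0].df_num == 16

    def test_leafchem_matches_hand_2x2_sums_of_squares(self):
        """n=2 per cell, worked by hand from cell and marginal means."""
        iso = pd.DataFrame(
            {
                "species": ["i", "i", "i", "i", "n", "n", "n", "n"],
                "year": ["w", "w", "c", "c", "w", "w", "c", "c"],
                "leaf_n": [1.0, 2.0, 2.0, 3.0, 3.0, 4.0, 2.0, 5.0],
            }
        )
        # cell means: iw 1.5, ic 2.5, nw 3.5, nc 3.5 ; grand 2.75
        # SS_species = 8*(1.0/2)^2 ... computed below from first principles
        y = iso.leaf_n.to_numpy()
        grand = y.mean()
        ss_sp = 4 * ((2.0 - grand) ** 2 + (3.5 - grand) ** 2)
        ss_yr = 4 * ((2.5 - grand) ** 2 + (3.0 - grand) ** 2)
        ss_cells = 2 * sum((m - grand) ** 2 for m in (1.5, 2.5, 3.5, 3.5))
        ss_int = ss_cells - ss_sp - ss_yr
        ss_err = sum((v - m) ** 2 for v, m in zip(y, [1.5, 1.5, 2.5, 2.5, 3.5, 3.5, 3.5, 3.5]))
        t = gr.leafchem_anova(iso, "leaf_n")
        get = lambda term: t[t.term == term].iloc[0]
        assert get("species").ss == pytest.approx(ss_sp, abs=1e-10)
        assert get("year").ss == pytest.approx(ss_yr, abs=1e-10)
        assert get("species x year").ss == pytest.approx(ss_int, abs=1e-10)
        assert get("residual").ss == pytest.approx(ss_err, abs=1e-10)
        assert get("species").F == pytest.approx((ss_sp / 1) / (ss_err / 4), rel=1e-10)

    def test_leafchem_rejects_sparse_cells(self):
        iso = pd.DataFrame(
            {"species": ["i", "i", "n"], "year": ["w", "c", "w"], "leaf_n": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError):
            gr.leafchem_anova(iso, "leaf_n")


class TestParameterRecovery:
    def test_noiseless_generator_recovers_rgr_exactly(self, noiseless_config):
        h = sd.gen_harvests(noiseless_config)
        for r in gr.fit_growth_rates(h):
            sp, yr = r.group
            assert r.rgr == pytest.approx(
                noiseless_config.rgr_true[sp][yr], abs=1e-12
            )
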