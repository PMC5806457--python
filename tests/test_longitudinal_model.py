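import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import leafagree as la
from leafagree.errors import MissingDataError, ModelError
from leafagree.longitudinal_model import (
    build_count_table,
    fit_interaction_anova,
    growth_curves,
)


def gaussian_table(seed=0, n_rep=5, slope_gap=0.0, sd_int=0.3, sd_slope=0.05,
                   sd_noise=0.5, drop_rows=()):
    """Continuous-response random intercept + slope table for model tests."""
    rng = np.random.default_rng(seed)
    t = np.arange(13) * 2.0
    rows = []
    for cultivar, base in (("mutant", 0.35), ("wild_type", 0.35 + slope_gap)):
        for r in range(n_rep):
            a = 2.0 + rng.normal(0, sd_int)
            b = base + rng.normal(0, sd_slope)
            y = a + b * t + rng.normal(0, sd_noise, len(t))
            for tt, yy in zip(t, y):
                rows.append((f"{cultivar}_r{r}", cultivar, tt, yy))
    table = pd.DataFrame(rows, columns=["plant_id", "cultivar", "time_days", "count"])
    if drop_rows:
        table = table.drop(index=list(drop_rows)).reset_index(drop=True)
    return table


class TestBuildCountTable:
    def test_single_observer_full_design(self, expert_annotations, design130):
        table = build_count_table(expert_annotations, design130, "single")
        assert len(table) == 130
        assert set(table.columns) == {"plant_id", "cultivar", "time_days", "count"}

    def test_mean_over_observers_averages(self, design130):
        one = design130.iloc[:1]
        counts = pd.DataFrame(
            {"observer_id": ["a", "b"], "image_id": one["image_id"].tolist() * 2,
             "count": [4, 6]}
        )
        # restrict design to that single plant-time row
        table = build_count_table(counts, one, "mean_over_observers")
        assert table["count"].tolist() == [5.0]

    def test_single_aggregation_rejects_multiple_observers(
        self, pool_annotations, design130
    ):
        with pytest.raises(ModelError):
            build_count_table(pool_annotations, design130, "single")

    def test_missing_images_reported(self, expert_annotations, design130):
        partial = expert_annotations.iloc[:100]
        with pytest.raises(MissingDataError) as err:
            build_count_table(partial, design130, "single")
        assert len(err.value.image_ids) == 30

    def test_multi_variant_design_rejected(self, expert_annotations):
        wide = la.build_design(resolution_variants=("low", "high"))
        with pytest.raises(ModelError):
            build_count_table(expert_annotations, wide, "single")


class TestInteractionAnova:
    def test_identical_deterministic_trajectories_give_null(self, design130):
        params = la.GrowthParams(
            rate_per_cultivar={"wild_type": 0.4, "mutant": 0.4},
            plant_effect_sd=0.0,
        )
        truth = la.simulate_growth(design130, params, seed=0)
        table = build_count_table(
            truth.counts.rename(columns={"true_count": "count"}), design130, "single"
        )
        res = fit_interaction_anova(table)
        assert res.interaction_coef == pytest.approx(0.0, abs=1e-10)
        assert res.interaction_p == 1.0

    def test_balanced_table_uses_exact_decomposition(self, expert_annotations,
                                                     design130):
        table = build_count_table(expert_annotations, design130, "single")
        res = fit_interaction_anova(table)
        assert res.method == "rm_anova"
        assert res.terms["df_den"].tolist() == [8.0, 8.0, 8.0]
        # default cultivars differ: strong interaction expected
        assert res.interaction_p < 0.05
        assert res.interaction_coef == pytest.approx(0.15, abs=0.08)

    def test_row_order_invariance(self, expert_annotations, design130):
        table = build_count_table(expert_annotations, design130, "single")
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = fit_interaction_anova(table)
        b = fit_interaction_anova(shuffled)
        pd.testing.assert_frame_equal(a.terms, b.terms)

    def test_exact_equals_per_plant_slope_anova(self, expert_annotations, design130):
        # independent oracle: one-way ANOVA on per-plant OLS slopes
        from scipy import stats

        table = build_count_table(expert_annotations, design130, "single")
        slopes, groups = [], []
        for _, sub in table.groupby("plant_id"):
            slopes.append(np.polyfit(sub["time_days"], sub["count"], 1)[0])
            groups.append(sub["cultivar"].iloc[0])
        slopes = np.array(slopes)
        groups = np.array(groups)
        f_oracle, p_oracle = stats.f_oneway(
            slopes[groups == "wild_type"], slopes[groups == "mutant"]
        )
        res = fit_interaction_anova(table)
        assert res.interaction_f == pytest.approx(f_oracle, rel=1e-10)
        assert res.interaction_p == pytest.approx(p_oracle, rel=1e-10)

    def test_mixed_engine_matches_lmerTest_reference(self, tmp_path):
        # independent cross-check of the REML/Satterthwaite path against R
        table = gaussian_table(seed=4, slope_gap=0.1)
        csv = tmp_path / "table.csv"
        table.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lmerTest))
            tab <- read.csv("{csv}")
            m <- lmer(count ~ time_days * cultivar + (1 | plant_id)
                      + (0 + time_days | plant_id), data = tab, REML = TRUE)
            co <- summary(m)$coefficients
            row <- co["time_days:cultivarwild_type", ]
            cat(row[["Estimate"]], row[["Std. Error"]], row[["df"]],
                row[["Pr(>|t|)"]], sep = "\\n")
        """)
        proc = subprocess.run(["Rscript", "-"], input=script, text=True,
                              capture_output=True, timeout=120)
        assert proc.returncode == 0, proc.stderr
        est, se, df, p = map(float, proc.stdout.split())
        res = fit_interaction_anova(table, engine="mixed")
        assert res.method == "mixed"
        assert res.interaction_coef == pytest.approx(est, rel=1e-4)
        assert res.interaction_se == pytest.approx(se, rel=1e-3)
        assert res.interaction_df == pytest.approx(df, rel=0.02)
        assert res.interaction_p == pytest.approx(p, rel=0.02)

    def test_unbalanced_zero_variance_falls_back_to_ols(self):
        import statsmodels.api as sm

        table = gaussian_table(seed=1, n_rep=6, sd_int=0.0, sd_slope=0.0,
                               sd_noise=1.0, drop_rows=(0, 17, 55))
        res = fit_interaction_anova(table)
        assert res.method == "ols"
        # direct OLS oracle on the same design matrix
        t = table["time_days"].to_numpy()
        dummy = (table["cultivar"] == "wild_type").astype(float).to_numpy()
        X = np.column_stack([np.ones(len(table)), t, dummy, t * dummy])
        fit = sm.OLS(table["count"].to_numpy(), X).fit()
        f_oracle = float(fit.tvalues[3] ** 2)
        assert res.interaction_f == pytest.approx(f_oracle, abs=1e-6)

    def test_power_at_default_effect(self, design130):
        hits = 0
        n = 100
        for s in range(n):
            truth = la.simulate_growth(design130, la.GrowthParams(), seed=s)
            ann = la.simulate_observer_counts(
                truth, design130, la.expert_profile(), seed=s + 50_000
            )
            table = build_count_table(ann, design130, "single")
            hits += fit_interaction_anova(table).interaction_p < 0.05
        assert hits / n >= 0.90

    @pytest.mark.parametrize(
        "mutate",
        [
            lambda t: t[t["cultivar"] == "mutant"],  # one cultivar
            lambda t: t[t["time_days"] < 3],  # two time points
            lambda t: t.assign(plant_id="p0"),  # plant in both cultivars
        ],
    )
    def test_precondition_violations_raise(self, expert_annotations, design130,
                                           mutate):
        table = build_count_table(expert_annotations, design130, "single")
        with pytest.raises(ModelError):
            fit_interaction_anova(mutate(table).reset_index(drop=True))


class TestGrowthCurves:
    def test_hand_computed_means(self):
        table = pd.DataFrame(
            {
                "plant_id": ["a", "a", "b", "b"],
                "cultivar": ["wt", "wt", "wt", "wt"],
                "time_days": [0.0, 2.0, 0.0, 2.0],
                "count": [2.0, 4.0, 4.0, 6.0],
            }
        )
        curves = growth_curves(table)
        assert curves["mean"].tolist() == [3.0, 5.0]
        assert curves["sd"].tolist() == pytest.approx([np.sqrt(2)] * 2)
        assert curves["n"].tolist() == [2, 2]

    def test_single_plant_reports_zero_sd_with_n_flag(self):
        table = pd.DataFrame(
            {"plant_id": ["a"], "cultivar": ["wt"], "time_days": [0.0],
             "count": [2.0]}
        )
        curves = growth_curves(table)
        assert curves["sd"].tolist() == [0.0]
        assert curves["n"].tolist() == [1]

    def test_deterministic_growth_gives_zero_sd(self, design130):
        params = la.GrowthParams(plant_effect_sd=0.0)
        truth = la.simulate_growth(design130, params, seed=0)
        table = build_count_table(
            truth.counts.rename(columns={"true_count": "count"}), design130, "single"
        )
        curves = growth_curves(table)
        assert (curves["sd"] == 0.0).all()
        assert (curves["n"] == 5).all()
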