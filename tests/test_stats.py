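"""Aggregation, composite, Sidak, and the group x time mixed model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cartiq import (
    CohortSpec,
    GroupTimeModel,
    balanced_table,
    composite,
    contrasts,
    fit_group_time_model,
    fit_map,
    generate_cohort,
    laminar_split,
    region_layer_means,
    sidak_adjust,
)
from cartiq.images import Grid, LaminarMask, T2Map


def uniform_map_and_laminae(value=50.0, shape=(1, 6, 10), invalid=()):
    """A map of constant value over a 6-row region split 3/3."""
    t2 = np.full(shape, value)
    valid = np.ones(shape, dtype=bool)
    for idx in invalid:
        valid[idx] = False
        t2[idx] = np.nan
    grid = Grid(0.5, 3.0)
    codes = np.zeros(shape, dtype=np.int8)
    codes[:, :3, :] = 1
    codes[:, 3:, :] = 2
    regions = np.full(shape, 2, dtype=np.int16)
    lam = LaminarMask(codes, regions, grid)
    t2map = T2Map(t2, np.full(shape, 1.0), np.zeros(shape), valid, grid)
    return t2map, lam


class TestRegionLayerMeans:
    def test_uniform_value(self):
        t2map, lam = uniform_map_and_laminae(50.0)
        tab = region_layer_means(t2map, lam)
        assert (tab.value == 50.0).all()
        assert tab.n_voxels.tolist() == [30, 30]

    def test_arithmetic_mean_of_two_values(self):
        t2map, lam = uniform_map_and_laminae(40.0)
        t2map.t2[:, :, 5:] = 60.0
        tab = region_layer_means(t2map, lam)
        assert (tab.value == 50.0).all()

    def test_invalid_voxels_excluded(self):
        t2map, lam = uniform_map_and_laminae(50.0, invalid=[(0, 0, 0)])
        tab = region_layer_means(t2map, lam)
        sup = tab[tab.layer == "superficial"].iloc[0]
        assert sup.value == 50.0 and sup.n_voxels == 29

    def test_empty_cell_emitted_as_missing(self):
        t2map, lam = uniform_map_and_laminae(50.0)
        t2map.valid[:, :3, :] = False
        tab = region_layer_means(t2map, lam)
        sup = tab[tab.layer == "superficial"].iloc[0]
        assert np.isnan(sup.value) and sup.n_voxels == 0


class TestComposite:
    regions = ["mf", "mt", "lf", "lt", "pat", "tro"]

    def rows(self, values, pid="p1", time="pre"):
        return pd.DataFrame(
            [
                {
                    "participant_id": pid,
                    "group": "healthy",
                    "time": time,
                    "region": r,
                    "layer": "superficial",
                    "value": v,
                }
                for r, v in zip(self.regions, values)
            ]
        )

    def test_mean_of_six_regions(self):
        tab = self.rows([45, 47, 49, 51, 53, 55])
        out = composite(tab, self.regions, "superficial")
        assert out.value.iloc[0] == 50.0
        assert out.region.iloc[0] == "composite"

    def test_constant_regions(self):
        out = composite(self.rows([50.0] * 6), self.regions, "superficial")
        assert out.value.iloc[0] == 50.0

    def test_missing_region_marks_composite_missing(self):
        tab = self.rows([45, 47, 49, 51, 53, 55]).iloc[:-1]
        out = composite(tab, self.regions, "superficial")
        assert np.isnan(out.value.iloc[0])


class TestSidak:
    @pytest.mark.parametrize(
        "p, m, expected", [(0.05, 1, 0.05), (0.0, 7, 0.0), (0.01, 3, 0.029701)]
    )
    def test_closed_form(self, p, m, expected):
        assert sidak_adjust(p, m) == pytest.approx(expected, abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            sidak_adjust(1.5, 2)

    @given(
        p=st.floats(min_value=0.0, max_value=1.0),
        m=st.integers(min_value=1, max_value=50),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_bounded(self, p, m):
        adj = sidak_adjust(p, m)
        assert p <= adj <= 1.0
        assert adj <= sidak_adjust(p, m + 1)
        assert adj >= sidak_adjust(max(p - 0.01, 0.0), m)


def cell_means_2g(h=(50.0, 46.0), r=(52.0, 49.0), region="composite", layer="superficial"):
    return {
        ("healthy", "pre", region, layer): h[0],
        ("healthy", "post", region, layer): h[1],
        ("at-risk", "pre", region, layer): r[0],
        ("at-risk", "post", region, layer): r[1],
    }


class TestGroupTimeModel:
    def test_balanced_noiseless_cell_mean_arithmetic(self):
        tab = balanced_table(cell_means_2g(), n_per_group=8)
        res = fit_group_time_model(tab, "composite", "superficial")
        assert res.within_change("healthy") == pytest.approx(-4.0, abs=1e-8)
        assert res.within_change("at-risk") == pytest.approx(-3.0, abs=1e-8)
        assert res.between_difference("at-risk", "healthy") == pytest.approx(1.0, abs=1e-8)
        means = res.cell_means.set_index(["group", "time"])["mean"]
        assert means[("healthy", "pre")] == pytest.approx(50.0, abs=1e-8)
        assert means[("at-risk", "post")] == pytest.approx(49.0, abs=1e-8)

    def test_between_difference_equals_interaction(self):
        tab = generate_cohort(CohortSpec(cell_means=cell_means_2g()), seed=3)
        res = fit_group_time_model(tab, "composite", "superficial")
        assert res.between_difference("at-risk", "healthy") == pytest.approx(
            res.interaction, abs=1e-10
        )

    def test_constant_shift_moves_intercept_only(self):
        tab = generate_cohort(CohortSpec(cell_means=cell_means_2g()), seed=4)
        res = fit_group_time_model(tab, "composite", "superficial")
        shifted = tab.copy()
        shifted["value"] += 100.0
        res2 = fit_group_time_model(shifted, "composite", "superficial")
        assert res2.params["intercept"] == pytest.approx(
            res.params["intercept"] + 100.0, abs=1e-6
        )
        pd.testing.assert_frame_equal(
            contrasts(res)[["estimate", "se"]],
            contrasts(res2)[["estimate", "se"]],
            atol=1e-6,
            rtol=0,
        )

    def test_adjusted_p_at_least_raw(self):
        tab = generate_cohort(CohortSpec(cell_means=cell_means_2g()), seed=5)
        res = fit_group_time_model(tab, "composite", "superficial")
        assert (res.contrasts.p_sidak >= res.contrasts.p_raw - 1e-15).all()
        assert res.m_sidak == 3

    def test_three_group_pairwise_cell_mean_arithmetic(self):
        means = {}
        for g, pre, post in (
            ("healthy", 50.0, 46.0),
            ("at-risk-ACL", 52.0, 50.0),
            ("at-risk-noACL", 53.0, 49.5),
        ):
            means[(g, "pre", "composite", "superficial")] = pre
            means[(g, "post", "composite", "superficial")] = post
        tab = balanced_table(means, n_per_group=6)
        res = fit_group_time_model(tab, "composite", "superficial")
        assert len(res.groups) == 3
        assert res.m_sidak == 6  # 3 within + 3 pairwise between
        assert res.within_change("at-risk-noACL") == pytest.approx(-3.5, abs=1e-8)
        assert res.between_difference("at-risk-ACL", "healthy") == pytest.approx(2.0, abs=1e-8)
        assert res.between_difference("at-risk-noACL", "at-risk-ACL") == pytest.approx(
            -1.5, abs=1e-8
        )

    def test_uncorrelated_covariate_leaves_interaction_unbiased(self):
        from cartiq import CovariateSpec

        spec = CohortSpec(
            cell_means=cell_means_2g(),
            sd_intercept=4.0,
            sd_residual=1.0,
            age=CovariateSpec(mean=30.0, sd=6.0, coef=0.3),
        )
        diffs = []
        for k in range(30):
            tab = generate_cohort(spec, seed=500 + k)
            plain = fit_group_time_model(tab, "composite", "superficial")
            adj = fit_group_time_model(
                tab, "composite", "superficial", covariates=("age",)
            )
            diffs.append(adj.interaction - plain.interaction)
        assert abs(np.mean(diffs)) < 0.15

    def test_single_group_rejected(self):
        tab = balanced_table(
            {k: v for k, v in cell_means_2g().items() if k[0] == "healthy"}, 4
        )
        with pytest.raises(ValueError, match="two groups"):
            GroupTimeModel(tab, "composite", "superficial")

    def test_one_timepoint_rejected(self):
        tab = balanced_table(cell_means_2g(), 4)
        tab = tab[~((tab.group == "at-risk") & (tab.time == "post"))]
        with pytest.raises(ValueError, match="timepoint"):
            GroupTimeModel(tab, "composite", "superficial")

    def test_summary_mentions_key_quantities(self):
        tab = generate_cohort(CohortSpec(cell_means=cell_means_2g()), seed=6)
        text = fit_group_time_model(tab, "composite", "superficial").summary()
        assert "within:healthy" in text and "Sidak" in text


class TestRecoverySimulation:
    def test_estimator_recovers_generating_change(self):
        # small-scale parameter-recovery study: bias within Monte-Carlo
        # error and near-nominal CI coverage for the within-group change
        true_change = -3.8
        spec = CohortSpec(
            cell_means=cell_means_2g(h=(50.0, 50.0 - 3.89), r=(52.0, 52.0 + true_change)),
            sd_intercept=8.0,
            sd_residual=2.0,
        )
        ests, cover = [], 0
        n_rep = 80
        for k in range(n_rep):
            tab = generate_cohort(spec, seed=900 + k)
            res = fit_group_time_model(tab, "composite", "superficial")
            ests.append(res.within_change("at-risk"))
            row = res.contrasts[res.contrasts.contrast == "within:at-risk"].iloc[0]
            cover += row.ci_low <= true_change <= row.ci_high
        se_mc = np.std(ests, ddof=1) / np.sqrt(n_rep)
        assert abs(np.mean(ests) - true_change) < 4 * se_mc
        assert 0.85 <= cover / n_rep <= 1.0


class TestPipelineIntegrationOfMeans:
    def test_phantom_means_equal_truth(self, noiseless_phantom):
        spec, series, mask, truth = noiseless_phantom
        t2map = fit_map(series, mask)
        lam = laminar_split(mask, 2)
        tab = region_layer_means(t2map, lam)
        sup = tab[tab.layer == "superficial"].value.iloc[0]
        deep = tab[tab.layer == "deep"].value.iloc[0]
        assert sup == pytest.approx(spec.t2_superficial, abs=1e-6)
        assert deep == pytest.approx(spec.t2_deep, abs=1e-6)
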