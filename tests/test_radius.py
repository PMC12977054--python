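"""Gaussian fitting of delta-distance samples and radius transfer."""

import numpy as np
import pytest

from chelastab.errors import ChelastabError, EmptySelectionError, SingularComponentError
from chelastab.geometry import ContactPair
from chelastab.radius import (
    GaussianFit,
    SHANNON_LA3_CN9,
    collect_deltas,
    estimate_radius,
    fit_gaussians,
)


def _pairs(deltas, classes):
    return [
        ContactPair("X", cls, i, i, 2.5, 2.5 + d)
        for i, (d, cls) in enumerate(zip(deltas, classes))
    ]


class TestCollectDeltas:
    def test_subsets_partition_the_sample(self):
        rng = np.random.default_rng(1)
        classes = rng.choice(["O_carboxylate", "N_pyridine", "N_amine"], 60)
        deltas = rng.normal(0.06, 0.02, 60)
        pairs = _pairs(deltas, classes)
        allv = collect_deltas(pairs, "all")
        excl = collect_deltas(pairs, "excluding_amine")
        amin = collect_deltas(pairs, "amine_only")
        assert len(allv) == 60
        assert len(excl) + len(amin) == len(allv)
        assert sorted(np.concatenate([excl.values, amin.values])) == pytest.approx(
            sorted(allv.values)
        )

    def test_filter_count(self):
        pairs = _pairs([0.05, 0.06, 0.10], ["O_carboxylate", "N_pyridine", "N_amine"])
        assert len(collect_deltas(pairs, "excluding_amine")) == 2

    def test_empty_subset_fails_by_name(self):
        pairs = _pairs([0.05], ["O_carboxylate"])
        with pytest.raises(EmptySelectionError, match="amine_only"):
            collect_deltas(pairs, "amine_only")


class TestFitGaussians:
    def test_single_component_recovers_generator_truth(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0.059, 0.02, 500)
        fit = fit_gaussians(x, 1, "mle")
        assert abs(fit.centers[0] - 0.059) < 3 * fit.center_se[0]
        assert fit.widths[0] == pytest.approx(0.02, rel=0.2)

    def test_two_components_recover_both_means(self):
        rng = np.random.default_rng(11)
        x = np.concatenate(
            [rng.normal(0.050, 0.015, 300), rng.normal(0.095, 0.025, 100)]
        )
        fit = fit_gaussians(x, 2, "mle")
        assert fit.centers[0] < fit.centers[1]  # ascending convention
        assert abs(fit.centers[0] - 0.050) < 3 * max(fit.center_se[0], 1e-3)
        assert abs(fit.centers[1] - 0.095) < 3 * max(fit.center_se[1], 1e-3)
        assert sum(fit.weights) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_sample_raises_singular(self):
        with pytest.raises(SingularComponentError):
            fit_gaussians(np.full(50, 0.06), 1, "mle")

    def test_mle_and_binned_agree_on_unimodal_sample(self):
        rng = np.random.default_rng(19)
        x = rng.normal(0.059, 0.02, 400)
        f_mle = fit_gaussians(x, 1, "mle")
        f_bin = fit_gaussians(x, 1, "binned_ls", bin_width=0.01)
        assert abs(f_mle.centers[0] - f_bin.centers[0]) < 0.002

    def test_reorder_invariance(self):
        rng = np.random.default_rng(23)
        x = np.concatenate(
            [rng.normal(0.05, 0.015, 150), rng.normal(0.10, 0.02, 100)]
        )
        perm = rng.permutation(len(x))
        f1 = fit_gaussians(x, 2, "mle")
        f2 = fit_gaussians(x[perm], 2, "mle")
        np.testing.assert_allclose(f1.centers, f2.centers, atol=1e-6)
        np.testing.assert_allclose(f1.weights, f2.weights, atol=1e-6)
        f3 = fit_gaussians(x[::-1].copy(), 1, "mle")
        f4 = fit_gaussians(x, 1, "mle")
        np.testing.assert_allclose(f3.centers, f4.centers, atol=1e-12)

    def test_two_components_on_unimodal_keeps_conventions(self):
        rng = np.random.default_rng(29)
        x = rng.normal(0.06, 0.02, 300)
        fit = fit_gaussians(x, 2, "mle")
        assert fit.centers[0] <= fit.centers[1]
        assert all(0 < w <= 1 for w in fit.weights)

    def test_too_few_points_rejected(self):
        with pytest.raises(ChelastabError):
            fit_gaussians([0.05, 0.06, 0.07], 1)

    def test_bias_over_replicates(self):
        """Mean fitted center over 20 replicates stays within 0.003 A of truth."""
        for true_center in (0.03, 0.059, 0.09):
            centers = []
            for rep in range(20):
                rng = np.random.default_rng(1000 + rep)
                x = rng.normal(true_center, 0.02, 150)
                centers.append(fit_gaussians(x, 1, "mle").centers[0])
            assert abs(np.mean(centers) - true_center) < 0.003


class TestEstimateRadius:
    def test_reference_plus_center(self):
        fit = GaussianFit(1, (0.059,), (0.020,), (1.0,), (0.001,), 0.0, "mle", 100)
        est = estimate_radius(fit, 0, SHANNON_LA3_CN9)
        assert est.r_estimated == pytest.approx(1.275)
        assert est.spread == pytest.approx(0.020)

    def test_zero_center_identity(self):
        fit = GaussianFit(1, (0.0,), (0.01,), (1.0,), (0.001,), 0.0, "mle", 50)
        assert estimate_radius(fit, 0, 1.100).r_estimated == pytest.approx(1.100)

    def test_negative_center(self):
        fit = GaussianFit(1, (-0.010,), (0.01,), (1.0,), (0.001,), 0.0, "mle", 50)
        assert estimate_radius(fit, 0, 1.216).r_estimated == pytest.approx(1.206)

    def test_invalid_component_rejected(self):
        fit = GaussianFit(1, (0.0,), (0.01,), (1.0,), (0.001,), 0.0, "mle", 50)
        with pytest.raises(ChelastabError):
            estimate_radius(fit, 1)
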