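import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from exmkit import population as pop
from exmkit import synthgen as sg
from exmkit.segmentation import LabelImage, SegmentationConfig, segment

from conftest import PX, make_scene, make_species


def make_pop(widths, n_images=5, seed=0):
    widths = np.asarray(widths, dtype=float)
    rng = np.random.default_rng(seed)
    ids = rng.integers(0, n_images, size=widths.size)
    return pop.WidthPopulation(widths_um=widths, image_ids=ids)


class TestExpansionRatio:
    def test_identity(self):
        p = make_pop(np.linspace(0.5, 1.5, 100))
        res = pop.expansion_ratio(p, p, n_boot=100, seed=1)
        assert res.ratio == 1.0
        assert res.sem >= 0

    def test_constant_populations_exact(self):
        pre = make_pop(np.full(50, 0.8))
        post = make_pop(np.full(60, 1.76))
        res = pop.expansion_ratio(pre, post, n_boot=200, seed=0)
        assert res.ratio == pytest.approx(2.2, rel=1e-12)
        assert res.sem == pytest.approx(0.0, abs=1e-12)
        assert (res.n_pre, res.n_post) == (50, 60)

    def test_large_sample_recovery(self):
        rng = np.random.default_rng(3)
        pre = make_pop(rng.normal(0.8, 0.05, 500), seed=1)
        post = make_pop(rng.normal(3.2, 0.2, 500), seed=2)
        res = pop.expansion_ratio(pre, post, n_boot=500, seed=0)
        assert res.ratio == pytest.approx(4.0, rel=0.02)

    def test_empty_population_rejected(self):
        good = make_pop(np.full(10, 1.0))
        empty = pop.WidthPopulation(np.ones(0), np.ones(0))
        with pytest.raises(ValueError):
            pop.expansion_ratio(empty, good)
        with pytest.raises(ValueError):
            pop.expansion_ratio(good, empty)

    def test_single_image_falls_back_to_cells(self, caplog):
        pre = pop.WidthPopulation(np.full(30, 1.0), np.zeros(30))
        post = make_pop(np.full(30, 2.0))
        with caplog.at_level("WARNING"):
            res = pop.expansion_ratio(pre, post, n_boot=100, seed=0)
        assert res.ratio == pytest.approx(2.0)
        assert any("single image" in r.message for r in caplog.records)

    def test_linear_scaling_property(self):
        rng = np.random.default_rng(5)
        pre = make_pop(rng.uniform(0.5, 1.0, 200), seed=3)
        post_w = rng.uniform(1.0, 2.0, 200)
        r1 = pop.expansion_ratio(pre, make_pop(post_w, seed=4), n_boot=2)
        r2 = pop.expansion_ratio(pre, make_pop(3.0 * post_w, seed=4), n_boot=2)
        assert r2.ratio == pytest.approx(3.0 * r1.ratio, rel=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(
        widths=st.lists(st.floats(0.1, 10.0), min_size=5, max_size=40),
    )
    def test_identity_property(self, widths):
        p = make_pop(widths, n_images=2)
        assert pop.expansion_ratio(p, p, n_boot=2).ratio == 1.0


class TestFitReference:
    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            pop.fit_reference(make_pop(np.ones(19)), "x")

    def test_constant_widths_sd_floor(self):
        ref = pop.fit_reference(make_pop(np.full(30, 2.0)), "x")
        assert ref.mean_um == 2.0
        assert ref.sd_um == pop.DEFAULT_SD_FLOOR_UM

    def test_estimator_consistency(self):
        rng = np.random.default_rng(11)
        ref = pop.fit_reference(make_pop(rng.normal(2.0, 0.1, 500)), "x")
        assert ref.mean_um == pytest.approx(2.0, abs=0.02)
        assert ref.sd_um == pytest.approx(0.1, abs=0.02)

    def test_disjoint_references_distinct(self):
        a = pop.fit_reference(make_pop(np.full(25, 1.0)), "a")
        b = pop.fit_reference(make_pop(np.full(25, 3.0)), "b")
        assert a.mean_um != b.mean_um


class TestClassify:
    def refs(self):
        return [
            pop.ReferenceModel("small", 1.0, 0.08),
            pop.ReferenceModel("large", 2.2, 0.15),
        ]

    def test_single_reference(self):
        p = make_pop(np.linspace(0.5, 3.0, 40))
        _, comp = pop.classify(p, [pop.ReferenceModel("only", 1.0, 0.1)])
        assert comp.fractions["only"] == 1.0
        assert comp.n_total == 40

    def test_two_well_separated_accuracy(self):
        rng = np.random.default_rng(2)
        w = np.concatenate(
            [rng.normal(1.0, 0.08, 300), rng.normal(2.2, 0.15, 300)]
        )
        labels = ["small"] * 300 + ["large"] * 300
        assignments, comp = pop.classify(make_pop(w), self.refs())
        acc = np.mean([a == t for a, t in zip(assignments, labels)])
        assert acc >= 0.99
        assert comp.counts["small"] + comp.counts["large"] == 600

    def test_mixture_1_2_3_recovery(self):
        rng = np.random.default_rng(4)
        refs = [
            pop.ReferenceModel("a", 1.0, 0.08),
            pop.ReferenceModel("b", 2.0, 0.12),
            pop.ReferenceModel("c", 3.2, 0.2),
        ]
        w = np.concatenate(
            [
                rng.normal(1.0, 0.08, 100),
                rng.normal(2.0, 0.12, 200),
                rng.normal(3.2, 0.2, 300),
            ]
        )
        _, comp = pop.classify(make_pop(w), refs)
        for sp, target in zip("abc", (1 / 6, 2 / 6, 3 / 6)):
            assert comp.fractions[sp] == pytest.approx(target, abs=0.04)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(9)
        _, comp = pop.classify(make_pop(rng.uniform(0.5, 3, 123)), self.refs())
        assert sum(comp.fractions.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(comp.counts.values()) == comp.n_total

    def test_reference_order_irrelevant(self):
        rng = np.random.default_rng(8)
        p = make_pop(rng.uniform(0.5, 3.0, 200))
        a1, _ = pop.classify(p, self.refs())
        a2, _ = pop.classify(p, list(reversed(self.refs())))
        assert a1 == a2

    def test_duplicate_means_rejected(self):
        refs = [
            pop.ReferenceModel("a", 1.0, 0.1),
            pop.ReferenceModel("b", 1.0, 0.2),
        ]
        with pytest.raises(ValueError):
            pop.classify(make_pop(np.ones(10)), refs)

    def test_bayes_error_bound(self):
        # misclassification within 1% of the closed-form two-normal Bayes
        # error when the means are >= 6 sd apart
        mu1, sd1, mu2, sd2 = 1.0, 0.1, 1.8, 0.13
        assert mu2 - mu1 >= 6 * max(sd1, sd2)
        x = np.linspace(0.0, 3.0, 200_001)
        f1 = norm.pdf(x, mu1, sd1)
        f2 = norm.pdf(x, mu2, sd2)
        bayes = 0.5 * np.trapezoid(np.minimum(f1, f2), x)
        rng = np.random.default_rng(12)
        n = 2000
        w = np.concatenate(
            [rng.normal(mu1, sd1, n), rng.normal(mu2, sd2, n)]
        )
        truth = ["a"] * n + ["b"] * n
        refs = [
            pop.ReferenceModel("a", mu1, sd1),
            pop.ReferenceModel("b", mu2, sd2),
        ]
        assignments, _ = pop.classify(make_pop(w), refs)
        err = np.mean([a != t for a, t in zip(assignments, truth)])
        assert err <= bayes + 0.01


class TestFitMixture:
    def test_k1_matches_moments(self):
        rng = np.random.default_rng(1)
        w = rng.normal(2.0, 0.3, 400)
        fit = pop.fit_mixture(make_pop(w), k=1, seed=0)
        (comp,) = fit.components
        assert comp.mean_um == pytest.approx(w.mean(), abs=0.01)
        assert comp.sd_um == pytest.approx(w.std(), abs=0.02)

    def test_well_separated_recovery(self):
        rng = np.random.default_rng(2)
        w = np.concatenate(
            [rng.normal(1.0, 0.05, 500), rng.normal(4.0, 0.2, 500)]
        )
        fit = pop.fit_mixture(make_pop(w), k=2, seed=0)
        assert fit.converged
        assert fit.unresolved == []
        lo, hi = fit.components
        assert lo.mean_um == pytest.approx(1.0, abs=0.05)
        assert hi.mean_um == pytest.approx(4.0, abs=0.1)

    def test_unimodal_flagged_unresolved(self):
        rng = np.random.default_rng(3)
        w = rng.normal(2.0, 0.3, 500)
        fit = pop.fit_mixture(make_pop(w), k=2, seed=0)
        assert fit.unresolved  # overlapping components reported

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        w = rng.normal(2.0, 0.4, 300)
        f1 = pop.fit_mixture(make_pop(w), k=2, seed=7)
        f2 = pop.fit_mixture(make_pop(w), k=2, seed=7)
        assert [c.mean_um for c in f1.components] == [
            c.mean_um for c in f2.components
        ]

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            pop.fit_mixture(make_pop(np.ones(15)), k=2)


def draw_rod(img, labels, lab, r0, c0, rows, cols, value=1000.0):
    img[r0:r0 + rows, c0:c0 + cols] = value
    labels[r0:r0 + rows, c0:c0 + cols] = lab


class TestDetectHalo:
    def test_colocalized_dna_not_expanded(self):
        img = np.zeros((80, 80))
        labels = np.zeros((80, 80), dtype=np.int32)
        draw_rod(img, labels, 1, 30, 20, 8, 40)
        calls = pop.detect_halo(LabelImage(labels, PX), img, cutoff=2.0)
        assert len(calls) == 1
        assert calls[0].ratio == pytest.approx(1.0, abs=0.1)
        assert not calls[0].expanded

    def test_synthetic_halo_ratio_near_four(self):
        spec = make_scene(
            counts=(5,),
            species=(make_species(width_mean_um=0.5, width_sd_um=0.0,
                                  length_mean_um=1.8, length_sd_um=0.0),),
            shape=(500, 500),
            min_separation_um=6.0,
            psf_sigma_um=0.03,
        )
        cyto, dna, truth = sg.render_halo_scene(spec, 1.0, 4.0, seed=5)
        labels = segment(cyto, SegmentationConfig(), pixel_size_um=PX)
        calls = pop.detect_halo(labels, dna, cutoff=2.0)
        assert len(calls) == 5
        for c in calls:
            assert c.expanded
            assert c.ratio == pytest.approx(4.0, rel=0.2)

    def test_binomial_fraction_recovery(self):
        spec = make_scene(
            counts=(100,),
            species=(make_species(width_mean_um=0.5, width_sd_um=0.04,
                                  length_mean_um=1.8, length_sd_um=0.15),),
            shape=(800, 800),
            min_separation_um=4.5,
            psf_sigma_um=0.03,
            background_level=5.0,
            noise=sg.NoiseSpec(shot_scale=5.0, read_sd=1.0),
        )
        n_called, n_exp = 0, 0
        for seed in (1, 2, 3):
            cyto, dna, truth = sg.render_halo_scene(spec, 0.3, 4.0, seed=seed)
            labels = segment(cyto, SegmentationConfig(), pixel_size_um=PX)
            calls = pop.detect_halo(labels, dna, cutoff=2.0)
            n_called += len(calls)
            n_exp += sum(c.expanded for c in calls)
        frac = n_exp / n_called
        sd = math.sqrt(0.3 * 0.7 / n_called)
        assert abs(frac - 0.3) <= 3 * sd

    def test_cutoff_validation(self):
        labels = LabelImage(np.zeros((10, 10), dtype=np.int32), PX)
        with pytest.raises(ValueError):
            pop.detect_halo(labels, np.zeros((10, 10)), cutoff=0.9)

    def test_no_dna_signal_skipped(self):
        img = np.zeros((80, 80))
        labels = np.zeros((80, 80), dtype=np.int32)
        draw_rod(img, labels, 1, 30, 20, 8, 40)
        calls = pop.detect_halo(LabelImage(labels, PX), np.zeros((80, 80)))
        assert calls == []


class TestHaloFraction:
    def test_constant_replicates(self):
        calls = [
            [pop.HaloCall(i, 1.0, 4.0, 4.0, i < 3) for i in range(10)]
        ] * 3
        frac, sem = pop.halo_fraction(calls)
        assert frac == pytest.approx(0.3)
        assert sem == pytest.approx(0.0)

    def test_closed_form_sem(self):
        def rep(k, n=10):
            return [pop.HaloCall(i, 1.0, 4.0, 4.0, i < k) for i in range(n)]

        frac, sem = pop.halo_fraction([rep(2), rep(3), rep(4)])
        assert frac == pytest.approx(0.3)
        assert sem == pytest.approx(0.1 / math.sqrt(3))

    def test_empty_replicate_excluded(self):
        def rep(k, n=10):
            return [pop.HaloCall(i, 1.0, 4.0, 4.0, i < k) for i in range(n)]

        frac, _ = pop.halo_fraction([rep(3), []])
        assert frac == pytest.approx(0.3)

    def test_all_empty_rejected(self):
        with pytest.raises(ValueError):
            pop.halo_fraction([[], []])

    def test_dose_series_monotone_plateau(self):
        # simulated dose series: generating fractions rise then saturate
        rng = np.random.default_rng(6)
        generating = [0.05, 0.15, 0.3, 0.3, 0.3]
        estimates = []
        for p in generating:
            reps = []
            for _ in range(3):
                flags = rng.random(400) < p
                reps.append(
                    [
                        pop.HaloCall(i, 1.0, 4.0, 4.0, bool(f))
                        for i, f in enumerate(flags)
                    ]
                )
            frac, sem = pop.halo_fraction(reps)
            estimates.append((frac, sem))
        # monotone within error, plateau recovered
        for (f1, s1), (f2, s2) in zip(estimates, estimates[1:]):
            assert f2 >= f1 - 3 * (s1 + s2 + 1e-3)
        plateau = [f for f, _ in estimates[2:]]
        assert all(abs(f - 0.3) < 0.1 for f in plateau)
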