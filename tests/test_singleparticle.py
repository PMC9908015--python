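"""Single-particle detection, per-particle RG, and spacing statistics."""

import numpy as np
import pytest

from aptaruler import (
    DarkFieldImage,
    detect_particles,
    nn_spacing,
    particle_rg,
    population_shift,
    synth_darkfield_image,
)


def _spot_image(centers, rg=1.5, peak=400.0, background=20.0, size=96, psf=1.5):
    yy, xx = np.mgrid[:size, :size]
    img = np.full((size, size, 3), background)
    for cx, cy in centers:
        g = np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * psf**2)))
        img[..., 0] += peak * rg * g
        img[..., 1] += peak * g
        img[..., 2] += peak * g
    return DarkFieldImage(img, pixel_size=0.16)


class TestDetect:
    def test_clean_field_found_exactly(self):
        img, truth = synth_darkfield_image(
            n_particles=10, poisson_noise=False, read_noise_sd=0.0, seed=2
        )
        dets = detect_particles(img)
        assert len(dets) == 10
        found = np.array([(d.x, d.y) for d in dets])
        for cx, cy in truth.parameters["centers_px"]:
            d = np.hypot(found[:, 0] - cx, found[:, 1] - cy).min()
            assert d <= 0.5

    def test_blank_noise_rarely_triggers(self):
        false_positive_images = 0
        rng_master = np.random.default_rng(0)
        for _ in range(100):
            noise = rng_master.normal(100.0, 3.0, (128, 128, 3)).clip(0)
            img = DarkFieldImage(noise, pixel_size=0.16)
            if detect_particles(img, threshold_sigmas=5.0):
                false_positive_images += 1
        assert false_positive_images <= 5

    def test_close_pair_suppressed_to_one(self):
        img = _spot_image([(40.0, 40.0), (43.0, 40.0)])
        dets = detect_particles(img, min_separation=8)
        assert len(dets) == 1

    def test_precision_and_recall_on_noisy_fields(self):
        tp = fp = fn = 0
        for seed in range(20):
            img, truth = synth_darkfield_image(n_particles=30, seed=seed)
            dets = detect_particles(img)
            found = np.array([(d.x, d.y) for d in dets]).reshape(-1, 2)
            centers = truth.parameters["centers_px"]
            matched = set()
            for cx, cy in centers:
                if found.size:
                    dist = np.hypot(found[:, 0] - cx, found[:, 1] - cy)
                    j = int(dist.argmin())
                    if dist[j] <= 2.0 and j not in matched:
                        matched.add(j)
                        tp += 1
                        continue
                fn += 1
            fp += len(dets) - len(matched)
        assert tp / (tp + fp) >= 0.95
        assert tp / (tp + fn) >= 0.95


class TestParticleRg:
    def test_rendered_ratio_recovered(self):
        img = _spot_image([(48.0, 48.0)], rg=1.5)
        assert particle_rg(img, (48.0, 48.0)) == pytest.approx(1.5, abs=0.05)

    def test_grayscale_spot_is_unity(self):
        img = _spot_image([(48.0, 48.0)], rg=1.0)
        assert particle_rg(img, (48.0, 48.0)) == pytest.approx(1.0, abs=0.01)

    def test_global_gain_and_offset_invariance(self):
        img = _spot_image([(48.0, 48.0)], rg=1.4)
        rg1 = particle_rg(img, (48.0, 48.0))
        scaled = DarkFieldImage(img.pixels * 10 + 37.0, pixel_size=0.16)
        assert particle_rg(scaled, (48.0, 48.0)) == pytest.approx(rg1, rel=1e-9)

    def test_aperture_outside_image_rejected(self):
        img = _spot_image([(48.0, 48.0)])
        with pytest.raises(ValueError):
            particle_rg(img, (2.0, 2.0))


class TestPopulationShift:
    def test_incubation_shift_always_detected(self):
        n_sig = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            before = rng.normal(1.24, 0.05, 145)
            after = rng.normal(1.56, 0.05, 145)
            cmp, summary = population_shift(before, after)
            if cmp.significant and summary["shift"] > 0:
                n_sig += 1
        assert n_sig == 100

    def test_identical_populations_not_significant(self):
        rng = np.random.default_rng(1)
        pop = rng.normal(1.24, 0.05, 145)
        cmp, _ = population_shift(pop, pop)
        assert not cmp.significant

    def test_swapped_arguments_flip_shift(self):
        rng = np.random.default_rng(2)
        a = rng.normal(1.24, 0.05, 50)
        b = rng.normal(1.56, 0.05, 50)
        _, fwd = population_shift(a, b)
        _, rev = population_shift(b, a)
        assert fwd["shift"] == pytest.approx(-rev["shift"])


class TestNnSpacing:
    def test_two_points(self):
        mean, sd = nn_spacing(np.array([[0.0, 0.0], [5.0, 0.0]]))
        assert mean == 5.0 and sd == 0.0

    def test_square_lattice(self):
        a = 2.5
        pts = np.array([(i * a, j * a) for i in range(5) for j in range(5)], float)
        mean, sd = nn_spacing(pts)
        assert mean == pytest.approx(a)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_duplicate_coordinates_warn(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 0.0]])
        with pytest.warns(UserWarning, match="duplicate"):
            nn_spacing(pts)

    def test_generator_spacing_recovered(self):
        means = []
        for seed in (0, 1, 2):
            _, truth = synth_darkfield_image(n_particles=150, target_spacing=3.6, seed=seed)
            centers_um = (
                np.asarray(truth.parameters["centers_px"]) * truth.parameters["pixel_size_um"]
            )
            means.append(nn_spacing(centers_um)[0])
        assert np.mean(means) == pytest.approx(3.6, rel=0.10)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            nn_spacing(np.array([[1.0, 2.0]]))
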