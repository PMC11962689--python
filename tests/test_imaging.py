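import numpy as np
import pytest
from scipy.special import ellipe

from cytomech.containers import ImageGray
from cytomech.errors import AmbiguousMaskError, CytomechError, ZeroEnergyError
from cytomech.imaging import (
    OrientationHistogram,
    alignment_sd,
    area_ratio,
    histogram_from_angles,
    intensity_metrics,
    measure_shape,
    orientation_histogram,
    positive_fraction,
    radial_profile,
    segment_particles,
)
from cytomech.synth import (
    FilamentImageSpec,
    ParticleImageSpec,
    generate_filament_image,
    generate_particle_image,
)


def _stripes(period=8, shape=(128, 128), horizontal=True):
    y, x = np.mgrid[0:shape[0], 0:shape[1]]
    coord = y if horizontal else x
    pix = 100.0 + 50.0 * np.sin(2 * np.pi * coord / period)
    return ImageGray(pixels=pix, scale=1.0)


# ------------------------------------------------------- directionality

def test_horizontal_stripes_modal_zero():
    h = orientation_histogram(_stripes(horizontal=True))
    assert abs(h.modal_angle) <= h.bin_width


def test_rotation_shifts_modal_by_90():
    img = _stripes(horizontal=True)
    rot = ImageGray(pixels=np.rot90(img.pixels), scale=1.0)
    h0 = orientation_histogram(img)
    h90 = orientation_histogram(rot)
    shift = (h90.modal_angle - h0.modal_angle) % 180.0
    assert min(abs(shift - 90.0), abs(shift + 90.0 - 180.0)) <= h0.bin_width


def test_kappa_contrast_in_histogram_peaks():
    img0, _ = generate_filament_image(
        FilamentImageSpec(n_fibers=1000, kappa=0.0, seed=1))
    img20, _ = generate_filament_image(
        FilamentImageSpec(n_fibers=1000, kappa=20.0, seed=1))
    peak = lambda im: orientation_histogram(im).weights.max()
    assert peak(img20) > peak(img0)


def test_constant_image_raises_zero_energy():
    with pytest.raises(ZeroEnergyError):
        orientation_histogram(ImageGray(pixels=np.full((32, 32), 7.0),
                                        scale=1.0))


def test_alignment_sd_flat_and_spike():
    n = 90
    flat = OrientationHistogram(
        bin_centers=np.linspace(-89, 89, n), weights=np.full(n, 1.0 / n))
    assert alignment_sd(flat).sd == 0.0
    w = np.zeros(n)
    w[0] = 1.0
    spike = OrientationHistogram(
        bin_centers=np.linspace(-89, 89, n), weights=w)
    expected = np.sqrt((1 - 1 / n) ** 2 + (n - 1) * (1 / n) ** 2) / np.sqrt(n)
    assert alignment_sd(spike).sd == pytest.approx(expected, rel=1e-12)


def test_alignment_sd_kappa_sweep_strictly_increasing():
    kappas = [0.0, 2.0, 5.0, 20.0]
    means = []
    for kappa in kappas:
        vals = []
        for seed in range(10):
            img, _ = generate_filament_image(FilamentImageSpec(
                shape=(128, 128), n_fibers=150, length_px=(20, 50),
                kappa=kappa, seed=seed))
            vals.append(alignment_sd(orientation_histogram(img)).sd)
        means.append(np.mean(vals))
    assert all(b > a for a, b in zip(means, means[1:]))


def test_alignment_sd_mixing_toward_uniform():
    rng = np.random.default_rng(0)
    w = rng.dirichlet(np.ones(90))
    centers = np.linspace(-89, 89, 90)
    uniform = np.full(90, 1 / 90)
    sds = []
    for lam in (1.0, 0.6, 0.2):
        h = OrientationHistogram(bin_centers=centers,
                                 weights=lam * w + (1 - lam) * uniform)
        sds.append(alignment_sd(h).sd)
    assert sds[0] > sds[1] > sds[2]
    assert sds[1] == pytest.approx(0.6 * sds[0], rel=1e-9)


# ------------------------------------------------------- radial profile

def test_radial_profile_uniform_disc():
    img = ImageGray(pixels=np.full((64, 64), 7.0), scale=1.0)
    prof = radial_profile(img, center=(32, 32), r_max=20)
    assert np.allclose(prof.mean[prof.count > 0], 7.0)


def test_radial_profile_ring_fixture_argmax():
    y, x = np.mgrid[0:64, 0:64]
    rr = np.sqrt((y - 32.0) ** 2 + (x - 32.0) ** 2)
    pix = np.where(np.abs(rr - 10.0) < 0.5, 100.0, 1.0)
    prof = radial_profile(ImageGray(pixels=pix, scale=1.0),
                          center=(32, 32), r_max=20)
    assert prof.radius[np.argmax(prof.mean)] == 10


def test_radial_profile_conservation_identity():
    rng = np.random.default_rng(3)
    img = ImageGray(pixels=rng.uniform(0, 255, (64, 64)), scale=1.0)
    r_max = 15
    prof = radial_profile(img, center=(30, 31), r_max=r_max)
    y, x = np.mgrid[0:64, 0:64]
    ring = np.rint(np.sqrt((y - 30.0) ** 2 + (x - 31.0) ** 2)).astype(int)
    total = img.pixels[ring <= r_max].sum()
    recon = np.sum(prof.mean[prof.count > 0]
                   * prof.count[prof.count > 0])
    assert recon == pytest.approx(total, rel=1e-12)


# ------------------------------------------------------- particles

@pytest.fixture(scope="module")
def particle_fixture():
    spec = ParticleImageSpec(n_above=30, n_below=20, seed=4)
    img, table = generate_particle_image(spec)
    return spec, img, table


def test_particle_filter_exact_counts(particle_fixture):
    _, img, _ = particle_fixture
    assert segment_particles(img).count == 30
    assert segment_particles(img, min_area_um2=0.0).count == 50


def test_particle_blank_image():
    blank = ImageGray(pixels=np.full((64, 64), 10.0), scale=0.05)
    assert segment_particles(blank).count == 0


def test_particle_count_invariant_to_rescale(particle_fixture):
    _, img, _ = particle_fixture
    scaled = ImageGray(pixels=img.pixels * 3.0, scale=img.scale)
    assert segment_particles(scaled).count == segment_particles(img).count


def test_particle_count_per_unit_area(particle_fixture):
    spec, img, _ = particle_fixture
    ps = segment_particles(img)
    full = np.ones(img.pixels.shape, dtype=bool)
    expected = 30 / (full.sum() * spec.scale ** 2)
    assert ps.count_per_unit_area(full) == pytest.approx(expected)


# ------------------------------------------------------- shapes

def _disc_mask(radius=50, pad=5):
    n = 2 * (radius + pad)
    y, x = np.mgrid[0:n, 0:n]
    return (y - n / 2 + 0.5) ** 2 + (x - n / 2 + 0.5) ** 2 <= radius ** 2


def test_disc_circularity_near_one():
    m = measure_shape(_disc_mask(50), scale=1.0)
    assert abs(m.circularity - 1.0) <= 0.02


def test_square_circularity_near_pi_over_4():
    mask = np.zeros((120, 120), dtype=bool)
    mask[10:110, 10:110] = True
    m = measure_shape(mask, scale=1.0)
    assert abs(m.circularity - np.pi / 4) <= 0.03 * np.pi / 4


def test_ellipse_circularity_below_disc():
    y, x = np.mgrid[0:140, 0:540]
    mask = ((y - 70.0) / 50.0) ** 2 + ((x - 270.0) / 250.0) ** 2 <= 1.0
    m = measure_shape(mask, scale=1.0)
    # exact 5:1 ellipse: 4*pi*A/P^2 with P from the complete elliptic integral
    a, b = 250.0, 50.0
    P_exact = 4 * a * ellipe(1 - (b / a) ** 2)
    exact = 4 * np.pi * (np.pi * a * b) / P_exact ** 2
    assert m.circularity < 0.6
    assert m.circularity < measure_shape(_disc_mask(50), 1.0).circularity
    assert m.circularity == pytest.approx(exact, rel=0.05)


def test_multi_component_mask_raises():
    mask = np.zeros((40, 40), dtype=bool)
    mask[5:10, 5:10] = True
    mask[25:30, 25:30] = True
    with pytest.raises(AmbiguousMaskError):
        measure_shape(mask, scale=1.0)


def test_circularity_scale_invariance_under_resampling():
    small = _disc_mask(40)
    big = np.kron(small, np.ones((2, 2), dtype=bool))
    c1 = measure_shape(small, scale=1.0).circularity
    c2 = measure_shape(big, scale=0.5).circularity
    assert abs(c2 - c1) / c1 < 0.02


# ------------------------------------------------------- intensity

def test_intensity_metrics_arithmetic():
    pix = np.zeros((20, 20))
    cell = np.zeros((20, 20), dtype=bool)
    cell[:10, :10] = True                      # 100 px
    pix[cell] = 50.0                           # IntDen 5000
    bg = np.zeros((20, 20), dtype=bool)
    bg[15:, 15:] = True
    pix[bg] = 10.0
    img = ImageGray(pixels=pix, scale=1.0)
    assert intensity_metrics(img, cell, bg) == pytest.approx(4000.0)
    with pytest.raises(CytomechError):
        intensity_metrics(img, cell, cell)     # overlapping masks


def test_positive_fraction_and_area_ratio():
    pix = np.zeros((20, 20))
    cell = np.zeros((20, 20), dtype=bool)
    cell[:10, :20] = True                      # 200 px
    pix[:5, :10] = 99.0                        # 50 positive px in cell
    img = ImageGray(pixels=pix, scale=1.0)
    assert positive_fraction(img, cell, threshold=50.0) == pytest.approx(0.25)
    before = np.zeros((20, 20), dtype=bool)
    before[:10, :10] = True                    # 100 px
    after = np.zeros((20, 20), dtype=bool)
    after[:10, :12] = True                     # 120 px
    assert area_ratio(after, before) == pytest.approx(1.2)
    with pytest.raises(ZeroDivisionError):
        area_ratio(after, np.zeros((20, 20), dtype=bool))
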