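import numpy as np
import pytest

from cytomech.containers import ForceCurve
from cytomech.errors import (
    CollinearityError,
    InsufficientIndentationError,
    InvalidRadiusError,
    NoContactError,
    TopographyQualityError,
)
from cytomech.mechanics import (
    ContactModelParams,
    ContactPoint,
    IndentationSeries,
    TipCoefficients,
    detect_contact,
    effective_radius,
    fit_curve,
    force_basis,
    model_force,
    to_indentation,
    topography,
)
from cytomech.synth import _solve_deflection

from conftest import make_plane_map

PARAMS = ContactModelParams()


def _stiff_curve(noise_force=0.0, seed=0, E=1e5, zc=0.5e-6, z_step=1e-8,
                 k=0.2):
    """Synthetic approach curve solved from the force law (constant R)."""
    z = np.arange(0.0, 1.2e-6, z_step)
    defl = _solve_deflection(z - zc, k, 5e-8, 0.0, 0.0, E, PARAMS)
    if noise_force:
        rng = np.random.default_rng(seed)
        defl = defl + rng.normal(0.0, noise_force / k, z.size)
    return ForceCurve(z_piezo=z, deflection=defl, spring_constant=k,
                      pixel=(0, 0)), zc, z_step


# ------------------------------------------------------------ detection

def test_detect_contact_noiseless_within_one_step(fv16, fv16_spec):
    fv, truth = fv16
    spec = fv16_spec
    r, c = spec.rows // 2, spec.cols // 2          # soft cell-top pixel
    cp = detect_contact(fv.curve_at(r, c))
    assert abs(cp.z - truth.contact_z[r, c]) < spec.z_step


def test_detect_contact_all_zero_deflection_raises():
    z = np.linspace(0, 1e-6, 50)
    curve = ForceCurve(z_piezo=z, deflection=np.zeros(50),
                       spring_constant=0.2, pixel=(0, 0))
    with pytest.raises(NoContactError):
        detect_contact(curve)


def test_detect_contact_10pN_noise_calibration():
    """>= 95% of 200 seeded trials within 3 z-steps on a stiff curve."""
    hits = 0
    for seed in range(200):
        curve, zc, z_step = _stiff_curve(noise_force=1e-11, seed=seed)
        try:
            cp = detect_contact(curve)
        except NoContactError:
            continue
        hits += abs(cp.z - zc) <= 3 * z_step
    assert hits >= 190


# ------------------------------------------------------------ kinematics

def test_to_indentation_arithmetic():
    k = 0.2
    z = np.linspace(0.0, 200e-9, 21)               # 10 nm steps, zc = 100 nm
    zc = 100e-9
    defl = np.where(z > zc, (z - zc) * 0.2, 0.0)
    curve = ForceCurve(z_piezo=z, deflection=defl, spring_constant=k,
                       pixel=(0, 0))
    cp = ContactPoint(index=10, z=zc, baseline=0.0, noise_sd=0.0)
    s = to_indentation(curve, cp)
    # at z - zc = 50 nm: deflection 10 nm -> F = 2 nN, d = 40 nm
    i = np.argmin(np.abs(s.F - 2e-9))
    assert s.F[i] == pytest.approx(2e-9, rel=1e-12)
    assert s.d[i] == pytest.approx(40e-9, rel=1e-12)
    assert np.all(np.diff(s.d) > 0)


def test_to_indentation_rigid_limit_raises():
    z = np.linspace(0.0, 200e-9, 21)
    zc = 100e-9
    defl = np.where(z > zc, z - zc, 0.0)           # 1:1 rise -> d = 0
    curve = ForceCurve(z_piezo=z, deflection=defl, spring_constant=0.2,
                       pixel=(0, 0))
    cp = ContactPoint(index=10, z=zc, baseline=0.0, noise_sd=0.0)
    with pytest.raises(InsufficientIndentationError):
        to_indentation(curve, cp)


def test_to_indentation_round_trip_matches_force_law(fv16, fv16_spec):
    fv, truth = fv16
    spec = fv16_spec
    r, c = spec.rows // 2, spec.cols // 2
    curve = fv.curve_at(r, c)
    cp = ContactPoint(index=-1, z=float(truth.contact_z[r, c]),
                      baseline=0.0, noise_sd=0.0)
    s = to_indentation(curve, cp)
    R = effective_radius(truth.tip_true, truth.gx[r, c], truth.gy[r, c], s.d)
    F_model = model_force(s.d, R, truth.sigma_true, truth.E_field[r, c],
                          spec.params)
    assert np.allclose(s.F, F_model, rtol=1e-12, atol=0)


# ------------------------------------------------------------ topography

def test_topography_flat_has_zero_gradients():
    fv, contacts = make_plane_map(alpha=0.0)
    h = topography(fv, contacts)
    assert np.all(h.gx == 0) and np.all(h.gy == 0)


def test_topography_tilted_plane_gradients_exact():
    alpha = 0.1
    fv, contacts = make_plane_map(alpha=alpha)
    h = topography(fv, contacts)
    assert np.all(np.abs(h.gx[:, 1:-1] - alpha) < 1e-9)
    assert np.all(np.abs(h.gy[1:-1, :]) < 1e-9)


def test_topography_dome_recovers_heights(fv16, fv16_spec):
    fv, truth = fv16
    spec = fv16_spec
    contacts = [detect_contact(c) for c in fv.curves]
    h = topography(fv, contacts)
    true_h = truth.height - truth.height.min()
    assert np.all(np.abs(h.z - true_h)[~h.mask] < spec.z_step)


def test_topography_masking_limits():
    fv, contacts = make_plane_map(alpha=0.1)
    holed = list(contacts)
    holed[9] = None
    h = topography(fv, holed)
    assert h.mask[1, 1] and np.isfinite(h.z[1, 1])
    too_many = [cp if i % 3 else None for i, cp in enumerate(contacts)]
    with pytest.raises(TopographyQualityError):
        topography(fv, too_many)


# ------------------------------------------------------------ force law

def test_effective_radius_examples():
    assert effective_radius(TipCoefficients(r=50e-9), 0.7, -0.3, 1e-7) \
        == pytest.approx(50e-9)
    tip = TipCoefficients(r=50e-9, a=20e-9, b=10e-9, c=0.05)
    assert effective_radius(tip, 0.5, -0.2, 100e-9) \
        == pytest.approx(63e-9, rel=1e-12)


def test_model_force_hertz_example():
    p = ContactModelParams(gamma=0.0)
    F = model_force(np.array([1e-7]), np.array([1e-6]), 0.0, 1000.0, p)
    assert F[0] == pytest.approx((4 / 3) * 1000 * 1e-3 * (1e-7) ** 1.5,
                                 rel=1e-12)
    assert F[0] == pytest.approx(4.216e-11, rel=1e-3)


def test_model_force_stress_example():
    F = model_force(np.array([200e-9]), np.array([50e-9]), 1e-3, 0.0, PARAMS)
    expected = 4 * np.pi * 50e-9 * 200e-9 * 1e-3 / np.sqrt(1.25)
    assert F[0] == pytest.approx(expected, rel=1e-12)
    assert F[0] == pytest.approx(1.124e-16, rel=1e-3)


def test_model_force_angular_factor_at_R_half_d():
    d = np.array([2e-7])
    R = np.array([1e-7])                            # 2R/d = 1
    F = model_force(d, R, 1e-3, 0.0, PARAMS)
    assert F[0] == pytest.approx(4 * np.pi * R[0] * d[0] * 1e-3 / np.sqrt(2),
                                 rel=1e-14)


def test_model_force_domain_errors():
    with pytest.raises(Exception):
        model_force(np.array([-1e-9]), np.array([5e-8]), 0.0, 1000.0, PARAMS)
    with pytest.raises(Exception):
        model_force(np.array([1e-9]), np.array([-5e-8]), 0.0, 1000.0, PARAMS)


def test_cos_arctan_identity():
    d = np.linspace(1e-9, 1e-6, 50)
    R = np.full_like(d, 5e-8)
    u, _ = force_basis(d, R, PARAMS)
    u_alt = 4 * np.pi * R * d * np.cos(np.arctan(2 * R / d))
    assert np.allclose(u, u_alt, rtol=1e-15)


# ------------------------------------------------------------ fitting

def test_fit_curve_noiseless_round_trip(fv16, fv16_spec):
    fv, truth = fv16
    spec = fv16_spec
    r, c = spec.rows // 2, spec.cols // 2
    curve = fv.curve_at(r, c)
    cp = ContactPoint(index=-1, z=float(truth.contact_z[r, c]),
                      baseline=0.0, noise_sd=0.0)
    s = to_indentation(curve, cp)
    tip = truth.tip_true
    gx, gy = truth.gx[r, c], truth.gy[r, c]
    fit = fit_curve(s, lambda d: effective_radius(tip, gx, gy, d),
                    spec.params)
    assert fit.sigma == pytest.approx(truth.sigma_true, rel=1e-9)
    assert fit.E == pytest.approx(truth.E_field[r, c], rel=1e-9)


def test_fit_curve_single_basis_hertz_inversion():
    d = np.linspace(10e-9, 800e-9, 80)
    R = np.full_like(d, 50e-9)
    E_true = 2000.0
    F = (4 / 3) * PARAMS.gamma_factor * E_true * np.sqrt(R) * d ** 1.5
    s = IndentationSeries(d=d, F=F, pixel=(0, 0), contact_z=0.0, baseline=0.0)
    fit = fit_curve(s, R, PARAMS, fix_sigma=0.0)
    E_pointwise = 3 * F / (4 * PARAMS.gamma_factor * np.sqrt(R) * d ** 1.5)
    assert np.all(np.abs(E_pointwise / fit.E - 1) < 1e-12)


def test_fit_curve_pure_noise_null():
    rng = np.random.default_rng(12)
    d = np.linspace(10e-9, 1e-6, 200)
    noise = 1e-11
    F = rng.normal(0.0, noise, d.size)
    R = np.full_like(d, 50e-9)
    s = IndentationSeries(d=d, F=F, pixel=(0, 0), contact_z=0.0, baseline=0.0)
    fit = fit_curve(s, R, PARAMS)
    u, v = force_basis(d, R, PARAMS)
    A = np.column_stack([u, v])
    cov = noise ** 2 * np.linalg.inv(A.T @ A)
    se_E = np.sqrt(cov[1, 1])
    assert abs(fit.E) < 3 * se_E
    assert fit.rms == pytest.approx(noise, rel=0.2)
    assert fit.flagged                                # negative sigma or E
    # residual orthogonality to both bases (normal equations)
    resid = F - fit.sigma * u - fit.E * v
    for basis in (u, v):
        cosang = np.dot(resid, basis) / (
            np.linalg.norm(resid) * np.linalg.norm(basis))
        assert abs(cosang) < 1e-10


def test_fit_curve_collinear_raises():
    d = 1e-6 + np.arange(4) * 1e-16
    R = np.full_like(d, 50e-9)
    F = np.ones_like(d) * 1e-9
    s = IndentationSeries(d=d, F=F, pixel=(0, 0), contact_z=0.0, baseline=0.0)
    with pytest.raises(CollinearityError):
        fit_curve(s, R, PARAMS)


def test_fit_curve_rejects_nonpositive_radius():
    d = np.linspace(10e-9, 1e-6, 20)
    F = np.ones_like(d) * 1e-10
    s = IndentationSeries(d=d, F=F, pixel=(0, 0), contact_z=0.0, baseline=0.0)
    with pytest.raises(InvalidRadiusError):
        fit_curve(s, lambda x: np.full_like(x, -1e-9), PARAMS)
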