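"""Synthetic ground-truth generators.

Force volumes: a dome-shaped cell (spherical cap) on a flat, effectively
rigid substrate, with a two-region elastic modulus field (cytoplasm plus a
stiffer elliptical nucleus region), probed by a tip whose effective radius
follows the linear model ``R = r + a*gx + b*gy + c*d``.  Each approach
curve is synthesized by solving the cantilever-sample force balance
``k * deflection = F(z - z_contact - deflection)`` exactly at every piezo
step, adding Gaussian force noise, and truncating at the first sample at or
above the force setpoint (1.5 nN by default), which is how force-volume
mapping instruments terminate each indentation.

Images: oriented filament textures (axial von Mises orientation law),
planted bright particles with known calibrated areas, and elliptical
nuclei.  Every generator returns its ground truth alongside the data and is
deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.draw import disk as _draw_disk
from skimage.draw import line_aa

from .containers import ForceCurve, ForceVolumeMap, ImageGray
from .errors import GenerationError, PlacementError
from .mechanics import (
    ContactModelParams,
    ContactPoint,
    HeightMap,
    TipCoefficients,
    force_basis,
)

__all__ = [
    "SynthFVSpec",
    "GroundTruthFV",
    "generate_force_volume",
    "FilamentImageSpec",
    "ParticleImageSpec",
    "NucleusImageSpec",
    "generate_filament_image",
    "generate_particle_image",
    "generate_nucleus_image",
    "dome_height_field",
    "modulus_field",
]


# --------------------------------------------------------------------------
# force volumes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthFVSpec:
    """Specification of a synthetic force-volume acquisition.

    Lengths in metres, forces in newtons, moduli in pascals.  The default
    geometry is a 32 x 32 grid at 1 um pitch carrying a spherical-cap cell
    of 12 um base radius and 4 um peak height, a 2 kPa cytoplasm with a
    5 kPa elliptical nucleus region, and a surface stress of 0.5 mN/m.
    The substrate is effectively rigid (1 GPa) rather than infinite so no
    pixel needs special-casing.
    """

    rows: int = 32
    cols: int = 32
    pitch: float = 1.0e-6
    substrate_height: float = 0.0
    dome_center: tuple[float, float] | None = None   # (row, col) px; None = grid centre
    dome_radius: float = 12.0e-6
    dome_height: float = 4.0e-6
    E_cytoplasm: float = 2000.0
    E_nucleus: float = 5000.0
    E_substrate: float = 1.0e9
    nucleus_axes: tuple[float, float] | None = None  # (m); None = (0.4, 0.3) x dome radius
    sigma_true: float = 0.5e-3
    tip_true: TipCoefficients = TipCoefficients(r=50e-9, a=20e-9, b=10e-9, c=0.05)
    gamma: float = 0.5
    hertz_convention: str = "as_printed"
    noise_sd: float = 0.0
    setpoint: float = 1.5e-9
    z_step: float = 10e-9
    spring_constant: float = 0.2
    pre_contact: float = 1.0e-6       # approach travel before first contact
    z_range: float | None = None      # max piezo travel; None = auto
    seed: int = 0

    def __post_init__(self):
        if self.E_cytoplasm <= 0 or self.E_nucleus <= 0 or self.E_substrate <= 0:
            raise GenerationError("all moduli must be > 0")
        if self.noise_sd < 0:
            raise GenerationError("noise_sd must be >= 0")
        if self.z_step <= 0 or self.pitch <= 0:
            raise GenerationError("z_step and pitch must be > 0")
        cr, cc = self._center_px
        half_r = self.dome_radius / self.pitch
        if (cr - half_r < -0.5 or cc - half_r < -0.5
                or cr + half_r > self.rows - 0.5 or cc + half_r > self.cols - 0.5):
            raise GenerationError("dome does not fit inside the grid")

    @property
    def _center_px(self) -> tuple[float, float]:
        if self.dome_center is not None:
            return self.dome_center
        return ((self.rows - 1) / 2.0, (self.cols - 1) / 2.0)

    @property
    def params(self) -> ContactModelParams:
        return ContactModelParams(self.gamma, self.hertz_convention)


@dataclass
class GroundTruthFV:
    """Everything the generator knew: the oracle for downstream fits."""

    E_field: np.ndarray          # true modulus per pixel (Pa)
    sigma_true: float
    tip_true: TipCoefficients
    height: np.ndarray           # true surface height above substrate (m)
    gx: np.ndarray               # true discrete gradients used by the forward model
    gy: np.ndarray
    contact_z: np.ndarray        # true contact piezo position per pixel (m)
    cell_mask: np.ndarray        # pixels on the cell (height > 0)
    spec: SynthFVSpec = field(repr=False, default=None)

    def height_map(self) -> HeightMap:
        """True topography in the same reference frame the fitter uses."""
        return HeightMap(z=self.height - self.height.min(),
                         gx=self.gx, gy=self.gy, pitch=self.spec.pitch)

    def contacts(self) -> list[ContactPoint]:
        """Exact contact points, row-major, for ground-truth-assisted fits."""
        out = []
        for r in range(self.contact_z.shape[0]):
            for c in range(self.contact_z.shape[1]):
                out.append(ContactPoint(index=-1, z=float(self.contact_z[r, c]),
                                        baseline=0.0, noise_sd=0.0))
        return out


def dome_height_field(spec: SynthFVSpec) -> np.ndarray:
    """Spherical-cap height field (m above the substrate plane)."""
    rr, cc = np.meshgrid(np.arange(spec.rows), np.arange(spec.cols), indexing="ij")
    cr, cc0 = spec._center_px
    rho = np.hypot(rr - cr, cc - cc0) * spec.pitch
    h_max, r_base = spec.dome_height, spec.dome_radius
    R_sphere = (r_base**2 + h_max**2) / (2.0 * h_max)
    with np.errstate(invalid="ignore"):
        cap = np.sqrt(np.maximum(R_sphere**2 - rho**2, 0.0)) - (R_sphere - h_max)
    h = np.where(rho <= r_base, np.maximum(cap, 0.0), 0.0)
    return spec.substrate_height + h


def modulus_field(spec: SynthFVSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel true modulus and the on-cell mask."""
    h = dome_height_field(spec)
    on_cell = h > spec.substrate_height
    rr, cc = np.meshgrid(np.arange(spec.rows), np.arange(spec.cols), indexing="ij")
    cr, cc0 = spec._center_px
    ax = spec.nucleus_axes or (0.4 * spec.dome_radius, 0.3 * spec.dome_radius)
    ex = (cc - cc0) * spec.pitch / ax[0]
    ey = (rr - cr) * spec.pitch / ax[1]
    in_nucleus = (ex**2 + ey**2 <= 1.0) & on_cell
    E = np.full((spec.rows, spec.cols), spec.E_substrate)
    E[on_cell] = spec.E_cytoplasm
    E[in_nucleus] = spec.E_nucleus
    return E, on_cell


def _force_of_depth(d, R0, c, sigma, E, params):
    """Force law with the depth-dependent radius folded in."""
    d = np.asarray(d, dtype=np.float64)
    R = R0 + c * d
    if np.any(R <= 0):
        raise GenerationError("tip model gives non-positive radius during generation")
    u, v = force_basis(d, R, params)
    return sigma * u + E * v


def _solve_deflection(zrel, k, R0, c, sigma, E, params, iters=90):
    """Solve k*delta = F(zrel - delta) for every piezo offset by bisection.

    The balance function is strictly increasing in delta, so bisection on
    [0, zrel] converges to the unique root; 90 halvings reach double
    precision over any realistic bracket.
    """
    zrel = np.asarray(zrel, dtype=np.float64)
    lo = np.zeros_like(zrel)
    hi = zrel.copy()
    tiny = 1e-18
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        d = np.maximum(zrel - mid, tiny)
        g = k * mid - _force_of_depth(d, R0, c, sigma, E, params)
        pos = g > 0
        hi = np.where(pos, mid, hi)
        lo = np.where(pos, lo, mid)
    return 0.5 * (lo + hi)


def _depth_at_force(F_target, k, R0, c, sigma, E, params, d_cap):
    """Invert F(d) = F_target for the noiseless truncation depth."""
    lo, hi = 1e-15, d_cap
    if float(_force_of_depth(hi, R0, c, sigma, E, params)) < F_target:
        raise GenerationError("setpoint unreachable within z range")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if float(_force_of_depth(mid, R0, c, sigma, E, params)) < F_target:
            lo = mid
        else:
            hi = mid
    return hi


def generate_force_volume(spec: SynthFVSpec) -> tuple[ForceVolumeMap, GroundTruthFV]:
    """Synthesize a force-volume map and its ground truth.

    The forward model uses the discrete central-difference gradients of the
    true height field -- the same operator the analysis applies to its
    recovered topography -- so that a noiseless generate-then-fit round
    trip is exact rather than limited by gradient discretisation.
    """
    rng = np.random.default_rng(spec.seed)
    params = spec.params
    h = dome_height_field(spec)
    E_field, on_cell = modulus_field(spec)
    gy, gx = np.gradient(h, spec.pitch)
    h_top = h.max()
    contact_z = spec.pre_contact + (h_top - h)
    z_range = spec.z_range
    if z_range is None:
        z_range = spec.pre_contact + (h_top - h.min()) + 8.0e-6

    k = spec.spring_constant
    tip = spec.tip_true
    curves = []
    for row in range(spec.rows):
        for col in range(spec.cols):
            R0 = tip.r + tip.a * gx[row, col] + tip.b * gy[row, col]
            E = float(E_field[row, col])
            z_c = float(contact_z[row, col])
            d_cap = z_range - z_c
            if d_cap <= 0:
                raise GenerationError("setpoint unreachable within z range")
            d_set = _depth_at_force(spec.setpoint, k, R0, tip.c,
                                    spec.sigma_true, E, params, d_cap)
            delta_set = spec.setpoint / k
            n_total = int(np.ceil((z_c + d_set + delta_set) / spec.z_step)) + 4

            while True:
                z = np.arange(n_total, dtype=np.float64) * spec.z_step
                if z[-1] > z_range:
                    raise GenerationError(
                        f"pixel ({row},{col}): setpoint unreachable within z range"
                    )
                delta = np.zeros_like(z)
                post = z > z_c
                if np.any(post):
                    delta[post] = _solve_deflection(
                        z[post] - z_c, k, R0, tip.c, spec.sigma_true, E, params
                    )
                F = k * delta
                if spec.noise_sd > 0:
                    F = F + rng.normal(0.0, spec.noise_sd, size=F.size)
                hit = np.flatnonzero(F >= spec.setpoint)
                if hit.size:
                    stop = int(hit[0])
                    break
                n_total += 8  # noise pushed the crossing past the ladder

            curves.append(ForceCurve(
                z_piezo=z[: stop + 1],
                deflection=F[: stop + 1] / k,
                spring_constant=k,
                pixel=(row, col),
                direction="approach",
            ))

    fv = ForceVolumeMap(rows=spec.rows, cols=spec.cols, pitch=spec.pitch,
                        curves=curves, setpoint=spec.setpoint)
    truth = GroundTruthFV(E_field=E_field, sigma_true=spec.sigma_true,
                          tip_true=tip, height=h, gx=gx, gy=gy,
                          contact_z=contact_z, cell_mask=on_cell, spec=spec)
    return fv, truth


# --------------------------------------------------------------------------
# images
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FilamentImageSpec:
    """Oriented fiber texture with an axial von Mises orientation law.

    Orientations are axial (period 180 deg): a fiber at angle theta is drawn
    from the distribution of ``phi/2`` with ``phi ~ VonMises(2*mu, kappa)``.
    ``kappa = 0`` gives isotropic textures; larger kappa gives alignment
    about ``mu_deg``.
    """

    shape: tuple[int, int] = (256, 256)
    scale: float = 0.323              # um per pixel
    n_fibers: int = 300
    length_px: tuple[float, float] = (30.0, 80.0)
    mu_deg: float = 0.0
    kappa: float = 0.0
    psf_sigma: float = 1.0
    poisson_noise: bool = False
    amplitude: float = 150.0
    background: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.kappa < 0 or self.n_fibers < 0:
            raise GenerationError("kappa and n_fibers must be >= 0")


def sample_axial_von_mises(mu_deg, kappa, size, rng) -> np.ndarray:
    """Sample axial orientations (degrees in [-90, 90))."""
    if kappa == 0:
        theta = rng.uniform(-90.0, 90.0, size=size)
    else:
        phi = rng.vonmises(np.deg2rad(2.0 * mu_deg), kappa, size=size)
        theta = np.rad2deg(phi) / 2.0
    return (theta + 90.0) % 180.0 - 90.0


def generate_filament_image(spec: FilamentImageSpec):
    """Render oriented fibers; returns (image, sampled ground-truth angles).

    Ground truth is the array of sampled fiber orientations in degrees;
    use :func:`cytomech.imaging.histogram_from_angles` to bin it.
    """
    rng = np.random.default_rng(spec.seed)
    img = np.zeros(spec.shape, dtype=np.float64)
    h, w = spec.shape
    angles = sample_axial_von_mises(spec.mu_deg, spec.kappa, spec.n_fibers, rng)
    lengths = rng.uniform(*spec.length_px, size=spec.n_fibers)
    for theta, L in zip(angles, lengths):
        t = np.deg2rad(theta)
        dx, dy = np.cos(t) * L / 2.0, -np.sin(t) * L / 2.0
        m = int(np.ceil(L / 2.0)) + 2
        if 2 * m >= min(h, w):
            m = min(h, w) // 2 - 1
        cy = rng.uniform(m, h - 1 - m)
        cx = rng.uniform(m, w - 1 - m)
        r0, c0 = int(round(cy - dy)), int(round(cx - dx))
        r1, c1 = int(round(cy + dy)), int(round(cx + dx))
        r0, r1 = np.clip([r0, r1], 0, h - 1)
        c0, c1 = np.clip([c0, c1], 0, w - 1)
        rr, cc, val = line_aa(r0, c0, r1, c1)
        img[rr, cc] += val
    if spec.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.psf_sigma)
    img = spec.background + spec.amplitude * img
    if spec.poisson_noise:
        img = rng.poisson(np.maximum(img, 0.0)).astype(np.float64)
    return ImageGray(pixels=img, scale=spec.scale), angles


@dataclass(frozen=True)
class ParticleImageSpec:
    """Planted bright discs on a dark background, with calibrated areas.

    ``n_above`` particles are drawn with areas in ``area_above_um2`` and
    ``n_below`` with areas in ``area_below_um2``; both ranges should stay
    clear of the analysis area cutoff so the planted above/below labels are
    unambiguous after pixel discretisation.
    """

    shape: tuple[int, int] = (512, 512)
    scale: float = 0.05               # um per pixel
    n_above: int = 30
    n_below: int = 20
    area_above_um2: tuple[float, float] = (0.15, 0.6)
    area_below_um2: tuple[float, float] = (0.02, 0.05)
    foreground: float = 200.0
    background: float = 10.0
    min_gap_px: int = 3
    max_tries: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.n_above < 0 or self.n_below < 0:
            raise GenerationError("particle counts must be >= 0")


def generate_particle_image(spec: ParticleImageSpec):
    """Render non-overlapping discs; returns (image, truth DataFrame).

    The truth table lists each particle's centre, its *rendered* pixel
    count, the calibrated area in um^2 and whether it lies at or above the
    0.1 um^2 focal-adhesion cutoff.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    img = np.full(spec.shape, spec.background, dtype=np.float64)
    h, w = spec.shape
    rows = []
    placed: list[tuple[float, float, float]] = []

    targets = [(True, rng.uniform(*spec.area_above_um2)) for _ in range(spec.n_above)]
    targets += [(False, rng.uniform(*spec.area_below_um2)) for _ in range(spec.n_below)]
    for above, area_um2 in targets:
        radius_px = np.sqrt(area_um2 / np.pi) / spec.scale
        for _ in range(spec.max_tries):
            cy = rng.uniform(radius_px + 1, h - radius_px - 2)
            cx = rng.uniform(radius_px + 1, w - radius_px - 2)
            ok = all(
                np.hypot(cy - py, cx - px) >= radius_px + pr + spec.min_gap_px
                for py, px, pr in placed
            )
            if ok:
                break
        else:
            raise PlacementError(
                f"could not place particle of {area_um2:.3f} um^2 without overlap"
            )
        rr, cc = _draw_disk((cy, cx), radius_px, shape=spec.shape)
        img[rr, cc] = spec.foreground
        placed.append((cy, cx, radius_px))
        n_px = rr.size
        rows.append({
            "row": cy, "col": cx, "pixels": n_px,
            "area_um2": n_px * spec.scale**2,
            "above_cutoff": bool(above),
        })
    truth = pd.DataFrame(
        rows, columns=["row", "col", "pixels", "area_um2", "above_cutoff"]
    )
    return ImageGray(pixels=img, scale=spec.scale), truth


@dataclass(frozen=True)
class NucleusImageSpec:
    """A single bright elliptical nucleus on a dark background."""

    shape: tuple[int, int] = (256, 256)
    scale: float = 0.323
    axes_um: tuple[float, float] = (8.0, 6.0)
    center: tuple[float, float] | None = None
    foreground: float = 180.0
    background: float = 8.0
    seed: int = 0


def generate_nucleus_image(spec: NucleusImageSpec):
    """Render an elliptical nucleus; returns (image, mask, truth area um^2)."""
    h, w = spec.shape
    cy, cx = spec.center or ((h - 1) / 2.0, (w - 1) / 2.0)
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    ey = (rr - cy) * spec.scale / spec.axes_um[1]
    ex = (cc - cx) * spec.scale / spec.axes_um[0]
    mask = ex**2 + ey**2 <= 1.0
    img = np.where(mask, spec.foreground, spec.background).astype(np.float64)
    area_um2 = float(mask.sum()) * spec.scale**2
    return ImageGray(pixels=img, scale=spec.scale), mask, area_um2
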