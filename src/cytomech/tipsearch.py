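"""Monte-Carlo calibration of the effective tip-radius coefficients.

The tip-radius model ``R = r + a*gx + b*gy + c*d`` has four unknown
coefficients.  They are found by minimising, over the whole force-volume
map, the *variance* of the per-curve RMS fitting errors: if the radius
model is right, the fit quality should not depend on where on the cell a
curve was taken, so the spread of fitting errors across the map is the
calibration signal.  The search is a Gaussian random walk over
``(r, a, b, c)`` with Metropolis acceptance; the default temperature of
zero makes it greedy (accept only improvements), matching a pure
minimisation.  The map is refit at the best coefficients to produce the
final elasticity and surface-stress maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ForceVolumeMap
from .errors import (
    CytomechError,
    InitializationError,
    InsufficientDataError,
    SearchFailureError,
)
from .mechanics import (
    ContactModelParams,
    ContactPoint,
    HeightMap,
    TipCoefficients,
    detect_contact,
    refine_contact,
    to_indentation,
    topography,
)

__all__ = [
    "MCState",
    "MCTrace",
    "ModulusMap",
    "PackedMap",
    "detect_all_contacts",
    "refine_all_contacts",
    "process_map",
    "pack_map",
    "map_objective",
    "optimize_tip",
    "line_scan_summary",
]


@dataclass(frozen=True)
class MCState:
    """One step of the Monte-Carlo trace."""

    coeffs: TipCoefficients
    objective: float          # variance of per-curve rms residuals (N^2)
    iteration: int
    accepted: bool


@dataclass
class MCTrace:
    """The full proposal history of one search run."""

    states: list[MCState] = field(default_factory=list)

    @property
    def best(self) -> MCState:
        return min(self.states, key=lambda s: s.objective)

    @property
    def best_so_far(self) -> np.ndarray:
        """Running minimum of the objective; non-increasing by construction."""
        return np.minimum.accumulate([s.objective for s in self.states])


@dataclass
class ModulusMap:
    """Per-pixel fit results over the grid.

    ``mask`` is True where no valid fit exists (contact failure, too few
    indentation points, or inadmissible radius); masked pixels carry NaN
    and are excluded from the objective and from all summaries.
    """

    E: np.ndarray
    sigma: np.ndarray
    rms: np.ndarray
    mask: np.ndarray
    coeffs_used: TipCoefficients
    objective: float = np.nan


@dataclass
class PackedMap:
    """Indentation series of a whole map packed into padded arrays.

    Padding entries have d = F = 0, which contribute nothing to any of the
    basis sums, so per-pixel least squares vectorises across the map.
    """

    d: np.ndarray            # (n_pix, L) deformations, zero-padded
    F: np.ndarray            # (n_pix, L) forces, zero-padded
    n: np.ndarray            # (n_pix,) valid sample counts
    gx: np.ndarray           # (n_pix,) slope dz/dx at each pixel
    gy: np.ndarray
    valid: np.ndarray        # (n_pix,) pixels with a usable fit
    shape: tuple[int, int]
    params: ContactModelParams

    @property
    def w(self) -> np.ndarray:
        return self.d > 0


def detect_all_contacts(
    fv: ForceVolumeMap,
    n_sigma: float = 3.0,
    baseline_frac: float = 0.3,
) -> list[ContactPoint | None]:
    """Threshold-detect the contact point of every curve (None on failure)."""
    contacts: list[ContactPoint | None] = []
    for curve in fv.curves:
        try:
            contacts.append(detect_contact(curve, n_sigma=n_sigma,
                                           baseline_frac=baseline_frac))
        except CytomechError:
            contacts.append(None)
    return contacts


def refine_all_contacts(
    fv: ForceVolumeMap,
    contacts: list[ContactPoint | None],
    height: HeightMap,
    tip: TipCoefficients,
    params: ContactModelParams = ContactModelParams(),
    **kwargs,
) -> list[ContactPoint | None]:
    """Changepoint-refine every contact under a tip hypothesis.

    Wraps :func:`cytomech.mechanics.refine_contact` with the per-pixel
    topographic gradients.  The refinement inherits the hypothesis' bias:
    a wrong tip shifts all refined contacts coherently, so refining is
    only an improvement when the supplied coefficients are roughly right.
    """
    out: list[ContactPoint | None] = []
    for cp, curve in zip(contacts, fv.curves):
        if cp is None:
            out.append(None)
            continue
        out.append(refine_contact(curve, cp, tip, params,
                                  gx=float(height.gx[curve.pixel]),
                                  gy=float(height.gy[curve.pixel]),
                                  **kwargs))
    return out


def pack_map(
    fv: ForceVolumeMap,
    height: HeightMap,
    contacts: list[ContactPoint | None],
    params: ContactModelParams = ContactModelParams(),
) -> PackedMap:
    """Convert every curve to an indentation series and pad into arrays."""
    n_pix = fv.rows * fv.cols
    series = []
    valid = np.zeros(n_pix, dtype=bool)
    for i, (curve, cp) in enumerate(zip(fv.curves, contacts)):
        if cp is None:
            series.append(None)
            continue
        try:
            s = to_indentation(curve, cp)
        except CytomechError:
            series.append(None)
            continue
        series.append(s)
        valid[i] = True
    L = max((s.d.size for s in series if s is not None), default=0)
    if L == 0:
        raise InsufficientDataError("no pixel yielded a usable indentation series")
    d = np.zeros((n_pix, L))
    F = np.zeros((n_pix, L))
    n = np.zeros(n_pix, dtype=int)
    for i, s in enumerate(series):
        if s is None:
            continue
        d[i, : s.d.size] = s.d
        F[i, : s.d.size] = s.F
        n[i] = s.d.size
    return PackedMap(d=d, F=F, n=n,
                     gx=height.gx.ravel(), gy=height.gy.ravel(),
                     valid=valid, shape=fv.shape, params=params)


def process_map(
    fv: ForceVolumeMap,
    params: ContactModelParams = ContactModelParams(),
    refine_tip: TipCoefficients | None = None,
):
    """Full per-curve preprocessing: contacts, topography, packed series.

    When ``refine_tip`` is given, threshold contacts are changepoint-refined
    under that tip hypothesis and the topography is rebuilt from the refined
    contacts before packing.
    """
    contacts = detect_all_contacts(fv)
    height = topography(fv, contacts)
    if refine_tip is not None:
        contacts = refine_all_contacts(fv, contacts, height, refine_tip, params)
        height = topography(fv, contacts)
    packed = pack_map(fv, height, contacts, params)
    return contacts, height, packed


def _fit_packed(packed: PackedMap, tip: TipCoefficients):
    """Vectorised per-pixel two-basis least squares at fixed coefficients.

    Returns (sigma, E, rms, fit_ok) flat arrays, or None if the radius
    model is inadmissible (R <= 0 at any used sample).
    """
    d, F, w = packed.d, packed.F, packed.w
    R = tip.r + tip.a * packed.gx[:, None] + tip.b * packed.gy[:, None] + tip.c * d
    if np.any(R[w] <= 0):
        return None
    R = np.maximum(R, 1e-18)  # padding columns only; never used in sums
    gfac = packed.params.gamma_factor
    u = 4.0 * np.pi * R * d * d / np.sqrt(d * d + 4.0 * R * R)
    v = (4.0 / 3.0) * gfac * np.sqrt(R) * d**1.5
    # padded entries have d = 0 hence u = v = F = 0: sums need no masking
    Suu = np.einsum("ij,ij->i", u, u)
    Svv = np.einsum("ij,ij->i", v, v)
    Suv = np.einsum("ij,ij->i", u, v)
    SuF = np.einsum("ij,ij->i", u, F)
    SvF = np.einsum("ij,ij->i", v, F)
    with np.errstate(invalid="ignore", divide="ignore"):
        su, sv = np.sqrt(Suu), np.sqrt(Svv)
        rho = Suv / (su * sv)
        one_m = 1.0 - rho * rho

        def _solve(rhs_u, rhs_v):
            A = rhs_u / su
            B = rhs_v / sv
            alpha = (A - rho * B) / one_m
            beta = (B - rho * A) / one_m
            return alpha / su, beta / sv

        sigma, E = _solve(SuF, SvF)
        # two passes of iterative refinement: the surface-stress term can be
        # orders of magnitude below the Hertz term, and refinement restores
        # the digits the normal equations lose on such imbalanced columns
        for _ in range(2):
            resid = F - sigma[:, None] * u - E[:, None] * v
            dsig, dE = _solve(np.einsum("ij,ij->i", u, resid),
                              np.einsum("ij,ij->i", v, resid))
            sigma = sigma + dsig
            E = E + dE
    fit_ok = packed.valid & np.isfinite(sigma) & np.isfinite(E) & (one_m > 1e-12)
    resid = F - sigma[:, None] * u - E[:, None] * v
    resid[~w] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        rms = np.sqrt(np.einsum("ij,ij->i", resid, resid)
                      / np.maximum(packed.n, 1))
    return sigma, E, rms, fit_ok


def _objective_from_rms(rms: np.ndarray, ok: np.ndarray) -> float:
    """Population variance of per-curve RMS residuals over usable pixels."""
    if ok.sum() == 0:
        return np.inf
    return float(np.var(rms[ok]))


def map_objective(
    fv_or_packed,
    height: HeightMap | None = None,
    tip: TipCoefficients = None,
    params: ContactModelParams = ContactModelParams(),
    contacts: list[ContactPoint | None] | None = None,
) -> tuple[float, ModulusMap]:
    """Fit every pixel at fixed tip coefficients; return (variance, maps).

    ``fv_or_packed`` may be a :class:`ForceVolumeMap` (contacts are
    detected unless supplied -- pass the generator's ground-truth contacts
    for an exact round trip) or an already-built :class:`PackedMap`.
    An inadmissible radius model yields an infinite objective and a fully
    masked map, the signal the search uses to reject a proposal.
    """
    if isinstance(fv_or_packed, PackedMap):
        packed = fv_or_packed
    else:
        fv = fv_or_packed
        if contacts is None:
            contacts = detect_all_contacts(fv)
        if height is None:
            height = topography(fv, contacts)
        packed = pack_map(fv, height, contacts, params)

    shape = packed.shape
    res = _fit_packed(packed, tip)
    if res is None:
        nanmap = np.full(shape, np.nan)
        return np.inf, ModulusMap(E=nanmap.copy(), sigma=nanmap.copy(),
                                  rms=nanmap.copy(),
                                  mask=np.ones(shape, dtype=bool),
                                  coeffs_used=tip, objective=np.inf)
    sigma, E, rms, ok = res
    obj = _objective_from_rms(rms, ok)

    def _grid(x):
        g = np.where(ok, x, np.nan).reshape(shape)
        return g

    mm = ModulusMap(E=_grid(E), sigma=_grid(sigma), rms=_grid(rms),
                    mask=~ok.reshape(shape), coeffs_used=tip, objective=obj)
    return obj, mm


def optimize_tip(
    fv_or_packed,
    height: HeightMap | None = None,
    init: TipCoefficients = TipCoefficients(r=50e-9),
    n_loops: int = 1000,
    step_scales=None,
    temperature: float = 0.0,
    seed: int = 0,
    params: ContactModelParams = ContactModelParams(),
    contacts: list[ContactPoint | None] | None = None,
    adapt: bool = True,
) -> tuple[MCTrace, ModulusMap]:
    """Random-walk Monte-Carlo minimisation of the map-wide error variance.

    Gaussian proposals on ``(r, a, b, c)`` with per-coefficient step
    scales; Metropolis acceptance ``exp(-delta/T)`` with greedy behaviour
    at ``temperature = 0``.  Exactly ``n_loops`` proposals are evaluated.
    With ``adapt`` the step scales shrink when proposals keep being
    rejected and grow when most are accepted, which sharpens convergence
    near the optimum without changing which moves are acceptable.
    Fully reproducible for a given seed.
    """
    if isinstance(fv_or_packed, PackedMap):
        packed = fv_or_packed
    else:
        fv = fv_or_packed
        if contacts is None:
            contacts = detect_all_contacts(fv)
        if height is None:
            height = topography(fv, contacts)
        packed = pack_map(fv, height, contacts, params)

    rng = np.random.default_rng(seed)
    res = _fit_packed(packed, init)
    if res is None:
        raise InitializationError("initial tip coefficients are inadmissible")
    cur_obj = _objective_from_rms(res[2], res[3])
    if not np.isfinite(cur_obj):
        raise InitializationError("initial coefficients give no valid fits")

    scale_ref = abs(init.r) if init.r != 0 else 50e-9
    if step_scales is None:
        step_scales = np.array([0.10 * scale_ref, 0.05 * scale_ref,
                                0.05 * scale_ref, 0.02])
    else:
        step_scales = np.asarray(step_scales, dtype=np.float64)

    cur = init.as_array()
    trace = MCTrace()
    trace.states.append(MCState(TipCoefficients.from_array(cur), cur_obj, 0, True))
    n_admissible = 0
    window_accepts = 0
    scales = step_scales.copy()

    for it in range(1, n_loops + 1):
        prop = cur + rng.normal(0.0, 1.0, size=4) * scales
        tip_prop = TipCoefficients.from_array(prop)
        res = _fit_packed(packed, tip_prop)
        if res is None:
            obj = np.inf
        else:
            obj = _objective_from_rms(res[2], res[3])
            n_admissible += 1
        delta = obj - cur_obj
        if delta < 0:
            accept = True
        elif temperature > 0 and np.isfinite(delta):
            accept = rng.random() < np.exp(-delta / temperature)
        else:
            accept = False
        if accept:
            cur, cur_obj = prop, obj
            window_accepts += 1
        trace.states.append(MCState(tip_prop, obj, it, accept))

        if adapt and it % 25 == 0:
            rate = window_accepts / 25.0
            if rate < 0.10:
                scales *= 0.7
            elif rate > 0.50:
                scales *= 1.3
            window_accepts = 0

    if n_admissible == 0:
        raise SearchFailureError("all proposals were inadmissible")

    best = trace.best
    _, mm = map_objective(packed, tip=best.coeffs)
    return trace, mm


def line_scan_summary(
    E_line,
    height_line=None,
    substrate_cutoff: float = 200e-9,
    min_points: int = 4,
) -> float:
    """Mean modulus along a line scan after substrate and outlier removal.

    Pixels whose height is at or below ``substrate_cutoff`` (height above
    the substrate, m) are excluded so the average covers only nucleus and
    cytoplasm.  Outliers are then removed with Tukey fences: values outside
    ``[Q1 - 1.5*IQR, Q3 + 1.5*IQR]``, quartiles by linear interpolation of
    order statistics.  Returns the mean of the survivors.
    """
    E_line = np.asarray(E_line, dtype=np.float64)
    if height_line is not None:
        height_line = np.asarray(height_line, dtype=np.float64)
        if height_line.shape != E_line.shape:
            raise ValueError("E and height lines must have equal length")
        E_line = E_line[height_line > substrate_cutoff]
    E_line = E_line[np.isfinite(E_line)]
    if E_line.size < min_points:
        raise InsufficientDataError(
            f"only {E_line.size} on-cell values (need >= {min_points})"
        )
    q1, q3 = np.percentile(E_line, [25.0, 75.0])
    iqr = q3 - q1
    keep = (E_line >= q1 - 1.5 * iqr) & (E_line <= q3 + 1.5 * iqr)
    survivors = E_line[keep]
    if survivors.size < min_points:
        raise InsufficientDataError("too few values survive the IQR fences")
    return float(np.mean(survivors))
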