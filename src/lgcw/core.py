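"""Local gray-scale clustering level-set model with bias-field estimation.

The model segments a 2-D grayscale image into two clusters while jointly
estimating a smooth multiplicative intensity-inhomogeneity ("bias") field,
which makes it robust to the shading artifacts typical of MRI.  Around every
pixel ``n`` the image is modelled locally as ``P(m) ~ e(n) * t_i`` for pixels
``m`` belonging to cluster ``i``, where ``e`` is the bias field and ``t_1,
t_2`` are two global cluster intensities.  The locality is expressed through
a truncated Gaussian window ``K``, giving the energy

    E(phi, e, t) = sum_n sum_m K(n - m) * [ (P(m) - e(n) t1)^2 M1(m)
                                          + (P(m) - e(n) t2)^2 M2(m) ]

with memberships read off a smoothed Heaviside of the level-set function:
``M1 = 1 - H_eps(phi)`` (interior, phi < 0 inside) and ``M2 = H_eps(phi)``.
The energy is minimized by alternating exact closed-form updates of the
cluster centers and the bias field with gradient-descent steps on ``phi``,
augmented by standard contour-length and distance-regularization terms that
keep the evolution well-posed.

Because ``K`` is symmetric, every double sum above collapses to convolutions,
so one outer iteration costs a handful of 2-D convolutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import convolve as _ndi_convolve
from scipy.ndimage import distance_transform_edt
from skimage.filters import threshold_multiotsu, threshold_otsu, threshold_triangle
from skimage.morphology import remove_small_objects

from .errors import (
    DegenerateFitError,
    DegenerateRegionError,
    InitializationError,
    InvalidParameterError,
    OptimizationFailureError,
    ShapeError,
)

__all__ = [
    "Image2D",
    "Kernel2D",
    "LevelSetState",
    "EnergyParams",
    "EnergyBreakdown",
    "gaussian_kernel",
    "smoothed_heaviside",
    "smoothed_delta",
    "memberships",
    "update_cluster_centers",
    "update_bias_field",
    "compute_energy",
    "data_force",
    "evolve_level_set",
    "initialize_level_set",
    "segment_lgscm",
]

_MIN_SIDE = 8


@dataclass(frozen=True)
class Image2D:
    """A 2-D scalar intensity field on a pixel grid.

    Parameters
    ----------
    pixels
        Non-negative intensities, arbitrary units (8- or 16-bit images are
        stored as floats without rescaling).
    pixel_size
        Physical spacing of the grid, used only to convert pixel distances to
        physical units in reports.  Default 1.0 (distances stay in px).
    """

    pixels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self):
        arr = np.asarray(self.pixels, dtype=float)
        if arr.ndim != 2:
            raise ShapeError(f"expected a 2-D image, got ndim={arr.ndim}")
        if not np.all(np.isfinite(arr)):
            raise InvalidParameterError("image intensities must be finite")
        object.__setattr__(self, "pixels", arr)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def require_segmentable(self) -> None:
        if self.height < _MIN_SIDE or self.width < _MIN_SIDE:
            raise ShapeError(
                f"segmentation needs at least {_MIN_SIDE}x{_MIN_SIDE} pixels, "
                f"got {self.height}x{self.width}"
            )


@dataclass(frozen=True)
class Kernel2D:
    """A normalized, truncated, 180-degree-symmetric convolution window."""

    sigma: float
    radius: int
    weights: np.ndarray


def gaussian_kernel(sigma: float, radius: int | None = None) -> Kernel2D:
    """Truncated Gaussian window, normalized to unit sum.

    ``radius`` defaults to ``ceil(2 * sigma)``; the support is the square
    ``(2*radius+1) x (2*radius+1)``.
    """
    if sigma <= 0:
        raise InvalidParameterError(f"sigma must be positive, got {sigma}")
    if radius is None:
        radius = math.ceil(2 * sigma)
    radius = int(radius)
    if radius < 1:
        raise InvalidParameterError(f"radius must be >= 1, got {radius}")
    ax = np.arange(-radius, radius + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    w = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    w /= w.sum()
    return Kernel2D(sigma=float(sigma), radius=radius, weights=w)


def _convolve(arr: np.ndarray, kernel: Kernel2D) -> np.ndarray:
    # zero padding so the result equals the double sum restricted to the grid
    return _ndi_convolve(arr, kernel.weights, mode="constant", cval=0.0)


def smoothed_heaviside(phi: np.ndarray | float, epsilon: float) -> np.ndarray | float:
    """C-infinity step ``H_eps(x) = 0.5 * (1 + (2/pi) * arctan(x / eps))``."""
    if epsilon <= 0:
        raise InvalidParameterError("epsilon must be positive")
    return 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(np.asarray(phi, dtype=float) / epsilon))


def smoothed_delta(phi: np.ndarray | float, epsilon: float) -> np.ndarray | float:
    """Derivative of :func:`smoothed_heaviside`: ``eps / (pi * (eps^2 + x^2))``."""
    if epsilon <= 0:
        raise InvalidParameterError("epsilon must be positive")
    x = np.asarray(phi, dtype=float)
    return epsilon / (np.pi * (epsilon**2 + x**2))


@dataclass
class LevelSetState:
    """Joint state of the alternating minimization.

    ``phi`` is negative inside the segmented region; cluster 1 (``t1``) is
    the interior with membership ``M1 = 1 - H_eps(phi)``.
    """

    phi: np.ndarray
    epsilon: float
    bias: np.ndarray
    centers: tuple[float, float]
    energy: float = np.nan

    def membership_interior(self) -> np.ndarray:
        return 1.0 - smoothed_heaviside(self.phi, self.epsilon)

    def interior_mask(self) -> np.ndarray:
        """Boolean interior: membership >= 0.5 (phi <= 0; ties go inside)."""
        return self.membership_interior() >= 0.5


@dataclass
class EnergyParams:
    """Tunables of the alternating minimization.

    All intensity-scale-dependent defaults assume 8-bit-like image values
    (0-255); ``length_weight`` scales with intensity squared because the data
    term does.
    """

    sigma: float = 4.0                      # bias window scale, px
    epsilon: float = 1.0                    # Heaviside smoothing width, px
    time_step: float = 0.1                  # gradient-descent step on phi
    length_weight: float = 0.003 * 255.0**2  # contour-length penalty (nu)
    distreg_weight: float = 1.0             # distance regularization (mu)
    max_outer_iters: int = 200
    tol: float = 1e-4                       # relative energy-change stop
    phi_substeps: int = 10                  # descent steps on phi per outer iter

    def __post_init__(self):
        if self.sigma <= 0 or self.epsilon <= 0 or self.time_step < 0:
            raise InvalidParameterError("sigma, epsilon must be > 0; time_step >= 0")
        if self.length_weight < 0 or self.distreg_weight < 0:
            raise InvalidParameterError("regularization weights must be >= 0")
        if self.tol <= 0:
            raise InvalidParameterError("tol must be > 0")

    def kernel(self) -> Kernel2D:
        return gaussian_kernel(self.sigma)


@dataclass(frozen=True)
class EnergyBreakdown:
    data: float
    length: float
    distreg: float

    @property
    def total(self) -> float:
        return self.data + self.length + self.distreg


def _check_shapes(image: Image2D, state: LevelSetState) -> None:
    if state.phi.shape != image.pixels.shape or state.bias.shape != image.pixels.shape:
        raise ShapeError(
            f"state arrays {state.phi.shape}/{state.bias.shape} do not match "
            f"image {image.pixels.shape}"
        )


def memberships(state: LevelSetState) -> tuple[np.ndarray, np.ndarray]:
    """(interior, exterior) membership fields; they sum to 1 pixelwise."""
    m1 = state.membership_interior()
    return m1, 1.0 - m1


def _local_fit_residuals(
    image: Image2D, state: LevelSetState, kernel: Kernel2D
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel aggregated squared residuals d_i(m) against each cluster.

    d_i(m) = sum_n K(n-m) (P(m) - e(n) t_i)^2
           = P(m)^2 * (K*1)(m) - 2 t_i P(m) (K*e)(m) + t_i^2 (K*e^2)(m)
    """
    P = image.pixels
    t1, t2 = state.centers
    s1 = _convolve(np.ones_like(P), kernel)
    c1 = _convolve(state.bias, kernel)
    c2 = _convolve(state.bias**2, kernel)
    base = P**2 * s1
    d1 = base - 2.0 * t1 * P * c1 + t1**2 * c2
    d2 = base - 2.0 * t2 * P * c1 + t2**2 * c2
    return d1, d2


def update_cluster_centers(
    image: Image2D, state: LevelSetState, kernel: Kernel2D
) -> tuple[float, float]:
    """Closed-form minimizers of the energy over (t1, t2), phi and e fixed.

    t_i = sum_m P(m) (K*e)(m) M_i(m) / sum_m (K*e^2)(m) M_i(m)
    """
    _check_shapes(image, state)
    P = image.pixels
    m1, m2 = memberships(state)
    c1 = _convolve(state.bias, kernel)
    c2 = _convolve(state.bias**2, kernel)
    out = []
    for mi in (m1, m2):
        den = float(np.sum(c2 * mi))
        if den <= 0 or not np.isfinite(den):
            raise DegenerateRegionError("cluster region has zero membership weight")
        out.append(float(np.sum(P * c1 * mi)) / den)
    return out[0], out[1]


def update_bias_field(
    image: Image2D, state: LevelSetState, kernel: Kernel2D
) -> np.ndarray:
    """Pointwise minimizer of the energy over e(n), phi and t fixed.

    e(n) = (K * [P (t1 M1 + t2 M2)])(n) / (K * [t1^2 M1 + t2^2 M2])(n)
    """
    _check_shapes(image, state)
    P = image.pixels
    t1, t2 = state.centers
    m1, m2 = memberships(state)
    num = _convolve(P * (t1 * m1 + t2 * m2), kernel)
    den = _convolve(t1**2 * m1 + t2**2 * m2, kernel)
    if np.any(den <= 0) or not np.all(np.isfinite(den)):
        raise DegenerateFitError("bias normal equations have a non-positive denominator")
    return num / den


def _gradient(phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gr, gc = np.gradient(phi)
    return gr, gc


def _divergence(fr: np.ndarray, fc: np.ndarray) -> np.ndarray:
    return np.gradient(fr, axis=0) + np.gradient(fc, axis=1)


_GRAD_EPS = 1e-10


def compute_energy(
    image: Image2D,
    state: LevelSetState,
    kernel: Kernel2D,
    params: EnergyParams,
) -> EnergyBreakdown:
    """Evaluate the full energy: clustering data term plus regularizers.

    The data term is the double sum over pixel pairs within the kernel
    support; the length term is ``nu * sum delta_eps(phi) |grad phi|`` and the
    distance-regularization term ``mu * sum 0.5 (|grad phi| - 1)^2``.
    """
    _check_shapes(image, state)
    m1, m2 = memberships(state)
    d1, d2 = _local_fit_residuals(image, state, kernel)
    e_data = float(np.sum(m1 * d1 + m2 * d2))
    gr, gc = _gradient(state.phi)
    gmag = np.sqrt(gr**2 + gc**2)
    delta = smoothed_delta(state.phi, state.epsilon)
    e_len = float(params.length_weight * np.sum(delta * gmag))
    e_dr = float(params.distreg_weight * 0.5 * np.sum((gmag - 1.0) ** 2))
    return EnergyBreakdown(data=e_data, length=e_len, distreg=e_dr)


def data_force(
    image: Image2D, state: LevelSetState, kernel: Kernel2D
) -> np.ndarray:
    """Descent direction of the data term with respect to phi.

    The exact derivative of the discretized data term is
    ``dE/dphi = delta_eps(phi) * (d2 - d1)`` (interior membership decreases
    with phi), so the returned descent force is ``delta_eps(phi) * (d1 - d2)``.
    """
    d1, d2 = _local_fit_residuals(image, state, kernel)
    return smoothed_delta(state.phi, state.epsilon) * (d1 - d2)


def _regularization_force(state: LevelSetState, params: EnergyParams) -> np.ndarray:
    phi = state.phi
    gr, gc = _gradient(phi)
    gmag = np.sqrt(gr**2 + gc**2)
    safe = np.maximum(gmag, _GRAD_EPS)
    curvature = _divergence(gr / safe, gc / safe)
    force = np.zeros_like(phi)
    if params.length_weight > 0:
        force += params.length_weight * smoothed_delta(phi, state.epsilon) * curvature
    if params.distreg_weight > 0:
        lap = _divergence(gr, gc)
        force += params.distreg_weight * (lap - curvature)
    return force


def _phi_descent(
    image: Image2D,
    state: LevelSetState,
    kernel: Kernel2D,
    params: EnergyParams,
    d1: np.ndarray,
    d2: np.ndarray,
) -> LevelSetState:
    """Backtracking gradient steps on phi; never increases the total energy.

    The data residuals d1/d2 are fixed during the sweep (centers and bias do
    not change), so each trial energy is cheap to evaluate.
    """
    delta_cache = None  # recomputed per step from current phi

    def total_energy(phi: np.ndarray) -> float:
        m1 = 1.0 - smoothed_heaviside(phi, state.epsilon)
        e_data = float(np.sum(m1 * d1 + (1.0 - m1) * d2))
        gr, gc = np.gradient(phi)
        gmag = np.sqrt(gr**2 + gc**2)
        e_len = params.length_weight * float(
            np.sum(smoothed_delta(phi, state.epsilon) * gmag)
        )
        e_dr = params.distreg_weight * 0.5 * float(np.sum((gmag - 1.0) ** 2))
        return e_data + e_len + e_dr

    phi = state.phi
    if params.time_step == 0 or params.phi_substeps == 0:
        return state
    energy = total_energy(phi)
    for _ in range(params.phi_substeps):
        cur = LevelSetState(
            phi=phi, epsilon=state.epsilon, bias=state.bias, centers=state.centers
        )
        force = smoothed_delta(phi, state.epsilon) * (d1 - d2)
        force += _regularization_force(cur, params)
        step = params.time_step
        accepted = False
        for _ in range(8):  # backtracking halvings
            cand = phi + step * force
            cand_energy = total_energy(cand)
            if cand_energy <= energy + 1e-12 * abs(energy):
                phi, energy = cand, cand_energy
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break  # stationary within line-search resolution
    return LevelSetState(
        phi=phi, epsilon=state.epsilon, bias=state.bias, centers=state.centers
    )


def evolve_level_set(
    image: Image2D,
    state: LevelSetState,
    kernel: Kernel2D,
    params: EnergyParams,
) -> LevelSetState:
    """One alternating outer iteration: centers -> bias -> phi descent.

    Center and bias updates are exact minimizers of the data term, and the
    phi sweep uses a backtracking line search on the total energy, so the
    total energy is non-increasing across the iteration.
    """
    _check_shapes(image, state)
    centers = update_cluster_centers(image, state, kernel)
    state = replace(state, centers=centers)
    bias = update_bias_field(image, state, kernel)
    state = replace(state, bias=bias)
    d1, d2 = _local_fit_residuals(image, state, kernel)
    state = _phi_descent(image, state, kernel, params, d1, d2)
    energy = compute_energy(image, state, kernel, params).total
    return replace(state, energy=energy)


def _signed_distance(region: np.ndarray) -> np.ndarray:
    """Signed distance field, negative inside ``region``."""
    region = region.astype(bool)
    inside = distance_transform_edt(region)
    outside = distance_transform_edt(~region)
    return outside - inside


def initialize_level_set(
    image: Image2D,
    mode: str = "centered-circle",
    roi: tuple[int, int, int, int] | None = None,
    radius: float | None = None,
    epsilon: float = 1.0,
    threshold_method: str = "otsu",
    threshold_classes: int = 2,
    clean: bool = False,
) -> LevelSetState:
    """Build an initial state: signed-distance phi, unit bias, region-mean centers.

    Modes
    -----
    ``centered-circle``
        Circle of ``radius`` (default ``min(h, w) / 4``) at the image center.
    ``threshold``
        ``threshold_method="otsu"`` uses Otsu's threshold (with
        ``threshold_classes > 2``, the lowest multi-Otsu threshold);
        ``"triangle"`` uses the triangle threshold, which separates a
        dominant dark background peak from all brighter anatomy and is
        robust to how many tissue classes the slice contains.  ``clean=True``
        additionally fills holes and drops specks below 16 px.
    ``user-roi``
        Axis-aligned rectangle ``(r0, c0, r1, c1)`` (half-open).
    """
    P = image.pixels
    h, w = P.shape
    if mode == "centered-circle":
        r = radius if radius is not None else min(h, w) / 4.0
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        dist = np.sqrt((rr - (h - 1) / 2.0) ** 2 + (cc - (w - 1) / 2.0) ** 2)
        phi = dist - r
        region = phi <= 0
    elif mode == "threshold":
        if threshold_method == "triangle":
            thr = threshold_triangle(P)
        elif threshold_classes <= 2:
            thr = threshold_otsu(P)
        else:
            thr = threshold_multiotsu(P, classes=threshold_classes)[0]
        region = P > thr
        if clean and region.any():
            from scipy.ndimage import binary_fill_holes

            region = binary_fill_holes(region)
            region = remove_small_objects(region, max_size=15)
        phi = _signed_distance(region)
    elif mode == "user-roi":
        if roi is None:
            raise InvalidParameterError("user-roi mode requires a roi rectangle")
        r0, c0, r1, c1 = roi
        region = np.zeros((h, w), dtype=bool)
        region[r0:r1, c0:c1] = True
        phi = _signed_distance(region)
    else:
        raise InvalidParameterError(f"unknown initialization mode {mode!r}")

    if not region.any():
        raise InitializationError("initial region is empty")
    t1 = float(P[region].mean())
    outside = ~region
    t2 = float(P[outside].mean()) if outside.any() else t1
    return LevelSetState(
        phi=phi.astype(float),
        epsilon=float(epsilon),
        bias=np.ones_like(P),
        centers=(t1, t2),
    )


@dataclass
class IterationRecord:
    iteration: int
    e_data: float
    e_reg: float
    e_total: float


def segment_lgscm(
    image: Image2D,
    params: EnergyParams | None = None,
    init: LevelSetState | None = None,
) -> tuple[np.ndarray, LevelSetState, list[IterationRecord]]:
    """Run the alternating minimization to convergence.

    Returns the binary interior mask (membership >= 0.5), the converged
    state, and the per-iteration energy log.  Convergence: relative total
    energy change below ``params.tol``, or ``params.max_outer_iters``.

    A constant image is degenerate (both clusters coincide); it converges
    immediately with an empty-boundary warning rather than an error.
    """
    import warnings

    image.require_segmentable()
    if params is None:
        params = EnergyParams()
    kernel = params.kernel()
    if init is None:
        init = initialize_level_set(image, mode="centered-circle", epsilon=params.epsilon)
    state = replace(init, epsilon=params.epsilon)

    if np.ptp(image.pixels) == 0:
        warnings.warn(
            "constant image: clusters coincide and the boundary is empty",
            stacklevel=2,
        )
        c = float(image.pixels.flat[0])
        state = replace(state, centers=(c, c))
        state = replace(state, energy=compute_energy(image, state, kernel, params).total)
        return state.interior_mask(), state, [
            IterationRecord(0, 0.0, 0.0, state.energy)
        ]

    log: list[IterationRecord] = []
    breakdown = compute_energy(image, state, kernel, params)
    prev = breakdown.total
    bad_streak = 0
    for it in range(1, params.max_outer_iters + 1):
        state = evolve_level_set(image, state, kernel, params)
        breakdown = compute_energy(image, state, kernel, params)
        total = breakdown.total
        log.append(
            IterationRecord(it, breakdown.data, breakdown.length + breakdown.distreg, total)
        )
        if total > prev + 1e-6 * abs(prev):
            bad_streak += 1
            if bad_streak > 3:
                raise OptimizationFailureError(
                    "energy increased beyond tolerance for more than 3 "
                    "consecutive iterations",
                    trace=[rec.e_total for rec in log],
                )
        else:
            bad_streak = 0
        if abs(prev - total) <= params.tol * max(abs(prev), 1e-30):
            prev = total
            break
        prev = total
    return state.interior_mask(), state, log
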