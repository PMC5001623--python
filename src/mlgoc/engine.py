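"""Multi-layer phase-field state, combined energy, and gradient descent.

The segmentation state is a stack of k independent phase fields on one
pixel grid.  Each layer carries its own gas-of-near-circles geometric
prior; the layers are coupled only through the data term, which compares
the counting field phi_plus = sum_i (1 + phi_i)/2 against the additive
intensity model.  Overlapping nuclei are represented by objects living
in different layers, so no inter-layer repulsion arises.  An optional
inter-layer overlap penalty from the predecessor multi-layer model is
kept with weight 0 by default — the additive data term already prevents
the degenerate duplicated segmentations it was introduced to fix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field, replace

import numpy as np

from ._operators import KernelFFT, forward_gradient, forward_gradient_adjoint
from .goc import GOCParams, InteractionKernel, build_interaction_kernel
from .intensity import (
    ImageFormationParams,
    data_energy,
    data_gradient_wrt_phi_plus,
)

__all__ = [
    "MultiLayerPhaseField",
    "SegmentationConfig",
    "EvolutionDiagnostics",
    "phi_plus",
    "overlap_penalty",
    "overlap_penalty_gradient",
    "total_energy",
    "total_gradient",
    "neutral_init",
    "seeded_init",
    "assign_seeds_to_layers",
    "evolve",
    "segment_image",
]


@dataclass
class MultiLayerPhaseField:
    """k real-valued phase fields on a shared H x W grid."""

    layers: np.ndarray  # (k, H, W)

    def __post_init__(self):
        self.layers = np.asarray(self.layers, dtype=float)
        if self.layers.ndim != 3:
            raise ValueError("layers must be a (k, H, W) array")
        if not np.all(np.isfinite(self.layers)):
            raise ValueError("phase field contains non-finite values")

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.layers.shape[1:]

    def copy(self) -> "MultiLayerPhaseField":
        return MultiLayerPhaseField(self.layers.copy())


@dataclass(frozen=True)
class SegmentationConfig:
    """Run-time knobs of the segmentation engine.

    n_layers: phase-field layers (4 covers dense overlap cliques);
    gamma_d: data-term weight; step_size / max_iter / tol: descent
    controls (tol applies to the relative energy decrease over a
    10-iteration window); init_mode: 'neutral' or 'seeded';
    overlap_weight: inter-layer penalty (0 disables);
    min_area: discard extracted objects smaller than this (pixels;
    default, None, resolves to ceil(pi*(r_hat/4)^2));
    threshold: binarization level (0 = phase midpoint);
    noise_sd / noise_mean: neutral-init Gaussian parameters (mean
    defaults to the potential's interphase equilibrium alpha_f/lambda_f);
    conflict_factor: seeds closer than conflict_factor*r_hat go to
    different layers; seeded_background: field value outside seed disks.
    """

    n_layers: int = 4
    gamma_d: float = 1.0
    step_size: float = 0.1
    max_iter: int = 1000
    tol: float = 1e-6
    init_mode: str = "neutral"
    rng_seed: int = 0
    overlap_weight: float = 0.0
    min_area: int | None = None
    threshold: float = 0.0
    include_log_term: bool = True
    noise_sd: float = 0.15
    noise_mean: float | None = None
    conflict_factor: float = 2.5
    seeded_background: float = 0.0
    convergence_window: int = 10

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.gamma_d <= 0:
            raise ValueError("gamma_d must be > 0")
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.overlap_weight < 0:
            raise ValueError("overlap_weight must be >= 0")
        if self.init_mode not in ("neutral", "seeded"):
            raise ValueError("init_mode must be 'neutral' or 'seeded'")

    def resolved_min_area(self, r_hat: float) -> int:
        if self.min_area is not None:
            return int(self.min_area)
        return int(np.ceil(np.pi * (r_hat / 4.0) ** 2))


def phi_plus(field) -> np.ndarray:
    """Counting field: sum over layers of (1 + phi)/2.

    Approximately the number of objects covering each pixel (0 on
    background, 1 under a single object, 2 where two overlap, ...).
    """
    layers = np.asarray(getattr(field, "layers", field), dtype=float)
    return np.sum(0.5 * (1.0 + layers), axis=0)


def overlap_penalty(field) -> float:
    """Inter-layer overlap term: sum over pixels and layer pairs i<j of
    [(1+phi_i)/2]^2 [(1+phi_j)/2]^2 (the predecessor model's form)."""
    layers = np.asarray(getattr(field, "layers", field), dtype=float)
    q = (0.5 * (1.0 + layers)) ** 2  # (k, H, W)
    s1 = q.sum(axis=0)
    s2 = (q**2).sum(axis=0)
    return float(np.sum(0.5 * (s1**2 - s2)))


def overlap_penalty_gradient(field) -> np.ndarray:
    """d overlap_penalty / d phi_i (exact discrete derivative)."""
    layers = np.asarray(getattr(field, "layers", field), dtype=float)
    p = 0.5 * (1.0 + layers)
    q = p**2
    rest = q.sum(axis=0)[None] - q  # sum over j != i
    return p * rest  # d/dphi_i [p_i^2] * rest / ... = 2 p_i * (1/2) * rest


class _EnergyWorkspace:
    """Caches the kernel FFT for one (kernel, grid) pair."""

    def __init__(self, kernel: InteractionKernel, grid_shape):
        self.kernel = kernel
        self.fft = KernelFFT(kernel.values, tuple(grid_shape))


def _geometric_batch(layers, goc: GOCParams, ws: _EnergyWorkspace):
    """Energy and gradient of the geometric prior for all layers at once."""
    k = layers.shape[0]
    gy = np.zeros_like(layers)
    gx = np.zeros_like(layers)
    gy[:, :-1, :] = layers[:, 1:, :] - layers[:, :-1, :]
    gx[:, :, :-1] = layers[:, :, 1:] - layers[:, :, :-1]
    cy = ws.fft.convolve(gy)
    cx = ws.fft.convolve(gx)
    phi2 = layers * layers
    energy = (
        0.5 * goc.D * np.sum(gy * gy + gx * gx)
        + goc.lambda_f * np.sum(0.25 * phi2 * phi2 - 0.5 * phi2)
        + goc.alpha_f * np.sum(layers - layers * phi2 / 3.0)
        - 0.5 * goc.beta_f * np.sum(gy * cy + gx * cx)
    )
    grad = np.empty_like(layers)
    ay = goc.D * gy - goc.beta_f * cy
    ax = goc.D * gx - goc.beta_f * cx
    for i in range(k):
        grad[i] = forward_gradient_adjoint(ay[i], ax[i])
    grad += goc.lambda_f * (layers * phi2 - layers)
    grad += goc.alpha_f * (1.0 - phi2)
    return float(energy), grad


def _check_grids(layers, image):
    if layers.shape[1:] != np.shape(image):
        raise ValueError(
            f"field grid {layers.shape[1:]} does not match image {np.shape(image)}"
        )


def total_energy(
    field,
    image,
    goc: GOCParams,
    kernel: InteractionKernel,
    imaging: ImageFormationParams,
    config: SegmentationConfig,
    *,
    _ws: _EnergyWorkspace | None = None,
) -> float:
    """Sum of per-layer geometric energies, the data term, and the
    (optionally weighted) inter-layer overlap penalty."""
    layers = np.asarray(getattr(field, "layers", field), dtype=float)
    image = np.asarray(image, dtype=float)
    _check_grids(layers, image)
    ws = _ws or _EnergyWorkspace(kernel, layers.shape[1:])
    e_geom, _ = _geometric_batch(layers, goc, ws)
    e = e_geom + data_energy(
        phi_plus(layers), image, imaging, config.gamma_d, config.include_log_term
    )
    if config.overlap_weight != 0.0:
        e += config.overlap_weight * overlap_penalty(layers)
    return e


def total_gradient(
    field,
    image,
    goc: GOCParams,
    kernel: InteractionKernel,
    imaging: ImageFormationParams,
    config: SegmentationConfig,
    *,
    _ws: _EnergyWorkspace | None = None,
) -> np.ndarray:
    """Per-layer gradient of :func:`total_energy` (exact adjoints)."""
    layers = np.asarray(getattr(field, "layers", field), dtype=float)
    image = np.asarray(image, dtype=float)
    _check_grids(layers, image)
    ws = _ws or _EnergyWorkspace(kernel, layers.shape[1:])
    _, grad = _geometric_batch(layers, goc, ws)
    gd = 0.5 * data_gradient_wrt_phi_plus(
        phi_plus(layers), image, imaging, config.gamma_d, config.include_log_term
    )
    grad += gd[None]
    if config.overlap_weight != 0.0:
        grad += config.overlap_weight * overlap_penalty_gradient(layers)
    return grad


def _energy_and_gradient(layers, image, goc, imaging, config, ws):
    e_geom, grad = _geometric_batch(layers, goc, ws)
    pp = np.sum(0.5 * (1.0 + layers), axis=0)
    e = e_geom + data_energy(pp, image, imaging, config.gamma_d, config.include_log_term)
    grad += 0.5 * data_gradient_wrt_phi_plus(
        pp, image, imaging, config.gamma_d, config.include_log_term
    )[None]
    if config.overlap_weight != 0.0:
        e += config.overlap_weight * overlap_penalty(layers)
        grad += config.overlap_weight * overlap_penalty_gradient(layers)
    return e, grad


def neutral_init(
    grid_shape,
    config: SegmentationConfig,
    goc: GOCParams,
    rng: np.random.Generator | None = None,
) -> MultiLayerPhaseField:
    """Layers of iid Gaussian white noise around the interphase level.

    The mean defaults to alpha_f/lambda_f, the unstable equilibrium of
    the local potential between the two phases, so each pixel can fall
    into either phase under the pull of the data term; the standard
    deviation (default 0.01) seeds the symmetry breaking.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    mean = (
        config.noise_mean
        if config.noise_mean is not None
        else goc.alpha_f / goc.lambda_f
    )
    layers = rng.normal(mean, config.noise_sd, size=(config.n_layers,) + tuple(grid_shape))
    return MultiLayerPhaseField(layers)


def assign_seeds_to_layers(
    seeds, r_hat: float, n_layers: int, *, conflict_factor: float = 2.5
) -> np.ndarray:
    """Distribute seeds among layers, minimising same-layer conflicts.

    Two seeds conflict when closer than conflict_factor * r_hat: within
    one layer, disks whose boundaries fall inside the interaction range
    d + epsilon repel (or merge on contact), so with d = r_hat the
    repulsion extends past one diameter and the default factor is 2.5.  Greedy colouring of
    the conflict graph in decreasing-degree order; when the clique needs
    more colours than layers, surplus seeds join the layer where they
    conflict least and a warning is emitted.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    pts = np.asarray([(float(x), float(y)) for x, y in seeds], dtype=float)
    n = len(pts)
    if n == 0:
        return np.zeros(0, dtype=int)
    dist = np.hypot(
        pts[:, 0][:, None] - pts[:, 0][None, :],
        pts[:, 1][:, None] - pts[:, 1][None, :],
    )
    # +0.5 px margin: disks at exactly the conflict distance (tangent
    # circles) still touch after rasterization and would merge into one
    # connected component within a layer
    conflict = (dist <= conflict_factor * r_hat + 0.5) & ~np.eye(n, dtype=bool)
    order = np.argsort(-conflict.sum(axis=1), kind="stable")
    assignment = np.full(n, -1, dtype=int)
    overflow = False
    for i in order:
        neighbour_layers = {assignment[j] for j in np.nonzero(conflict[i])[0] if assignment[j] >= 0}
        free = [c for c in range(n_layers) if c not in neighbour_layers]
        if free:
            assignment[i] = free[0]
        else:
            overflow = True
            counts = [
                sum(1 for j in np.nonzero(conflict[i])[0] if assignment[j] == c)
                for c in range(n_layers)
            ]
            assignment[i] = int(np.argmin(counts))
    if overflow:
        warnings.warn(
            "more mutually conflicting seeds than layers; overlaps within a layer",
            stacklevel=2,
        )
    return assignment


def seeded_init(
    grid_shape,
    config: SegmentationConfig,
    seeds,
    r_hat: float,
) -> MultiLayerPhaseField:
    """Disks of value 1 (radius r_hat/2) at the seeds, background level
    elsewhere (0 by default), seeds spread over layers to avoid
    same-layer conflicts."""
    h, w = grid_shape
    pts = [(float(x), float(y)) for x, y in seeds]
    for x, y in pts:
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(f"seed ({x}, {y}) outside the {h}x{w} grid")
    assignment = assign_seeds_to_layers(
        pts, r_hat, config.n_layers, conflict_factor=config.conflict_factor
    )
    layers = np.full((config.n_layers, h, w), float(config.seeded_background))
    yy, xx = np.mgrid[0:h, 0:w]
    for (x, y), lab in zip(pts, assignment):
        mask = (xx - x) ** 2 + (yy - y) ** 2 <= (r_hat / 2.0) ** 2
        layers[lab][mask] = 1.0
    return MultiLayerPhaseField(layers)


@dataclass
class EvolutionDiagnostics:
    energy_trace: list = dataclass_field(default_factory=list)
    iterations: int = 0
    converged: bool = False
    step_rejections: int = 0


def evolve(
    field: MultiLayerPhaseField,
    image,
    goc: GOCParams,
    kernel: InteractionKernel,
    imaging: ImageFormationParams,
    config: SegmentationConfig,
) -> tuple[MultiLayerPhaseField, EvolutionDiagnostics]:
    """Explicit gradient descent on the total energy.

    Steps that would increase the energy are retried at half the step
    size (down to 1e-6 of the nominal step) before being accepted, so
    the energy trace is non-increasing at accepted steps.  Terminates
    when the relative energy decrease over a 10-iteration window drops
    below tol, or at max_iter.
    """
    image = np.asarray(image, dtype=float)
    layers = np.array(getattr(field, "layers", field), dtype=float)
    _check_grids(layers, image)
    ws = _EnergyWorkspace(kernel, layers.shape[1:])
    diag = EvolutionDiagnostics()
    energy, grad = _energy_and_gradient(layers, image, goc, imaging, config, ws)
    if not np.isfinite(energy):
        raise FloatingPointError("non-finite energy at initialization")
    diag.energy_trace.append(energy)
    window = max(2, config.convergence_window)
    step = config.step_size
    for it in range(1, config.max_iter + 1):
        # reuse the last accepted step, probing upward once per
        # iteration, so a stiff data term does not force re-halving
        # from the nominal step every time
        step = min(2.0 * step, config.step_size)
        while True:
            candidate = layers - step * grad
            new_energy, new_grad = _energy_and_gradient(
                candidate, image, goc, imaging, config, ws
            )
            if np.isfinite(new_energy) and new_energy <= energy:
                break
            step *= 0.5
            diag.step_rejections += 1
            if step < 1e-6 * config.step_size:
                # locally flat or non-descending direction at machine
                # precision: accept the tiny step and let the window
                # criterion terminate
                break
        if not np.isfinite(new_energy):
            raise FloatingPointError(f"non-finite energy at iteration {it}")
        if new_energy <= energy:
            layers, energy, grad = candidate, new_energy, new_grad
        diag.energy_trace.append(energy)
        diag.iterations = it
        if len(diag.energy_trace) > window:
            e_then = diag.energy_trace[-window - 1]
            e_now = diag.energy_trace[-1]
            denom = max(abs(e_then), abs(e_now), 1e-12)
            if (e_then - e_now) / denom < config.tol:
                diag.converged = True
                break
    return MultiLayerPhaseField(layers), diag


def segment_image(
    image,
    goc: GOCParams,
    imaging: ImageFormationParams,
    config: SegmentationConfig,
    seeds=None,
    kernel: InteractionKernel | None = None,
):
    """Initialize, evolve, and extract object instances.

    Returns (final field, InstanceSet, diagnostics).  With seeded
    initialization and no explicit n_layers pressure, the layer count is
    config.n_layers; seeds must be given in (x, y) pixel coordinates.
    """
    from .extraction import binarize_layers, extract_objects  # local: avoid cycle

    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be single-channel 2-D")
    if kernel is None:
        kernel = build_interaction_kernel(goc.d, goc.epsilon)
    if config.init_mode == "seeded":
        if seeds is None:
            raise ValueError("seeded init_mode requires seeds")
        field = seeded_init(image.shape, config, seeds, goc.r_hat)
    else:
        field = neutral_init(image.shape, config, goc)
    field, diag = evolve(field, image, goc, kernel, imaging, config)
    binary = binarize_layers(field, config.threshold)
    instances = extract_objects(binary, config.resolved_min_area(goc.r_hat))
    return field, instances, diag
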