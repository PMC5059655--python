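"""Synthetic DWI phantoms with known geometry, tensors, noise and warps.

Every pipeline stage is testable without external data: fiber bundles are
parametric centerline curves swept with a tube radius; inside a bundle the
principal eigenvector is the local tangent with prescribed eigenvalues,
outside the medium is isotropic.  Signals follow the single-tensor forward
model ``S = S0 exp(-b g^T D g)`` with Rician corruption
``sqrt((S + n1)^2 + n2^2)`` (n1, n2 i.i.d. zero-mean Gaussians of std
sigma), matching magnitude-MRI physics.  Ground-truth warps are smooth
sums of Gaussian bumps, tapered to zero at the boundary and verified to be
invertible, providing the acceptance surface for registration.

The defaults are the desk-scale study conditions: a 40x40x20 grid at 2 mm,
one straight and one arc bundle with eigenvalues (1.7, 0.3, 0.3)e-3
mm^2/s over an isotropic 0.7e-3 background, S0 = 1000, 15 gradient
directions at b = 1000 s/mm^2 plus one b = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats_io import GradientTable, RoiMask, Volume
from .registration import DeformationField, invert_displacement, warp_scalar, warp_tensor_field
from .tensor_model import TensorField, coeffs_from_tensors, design_matrix

__all__ = [
    "Bundle",
    "PhantomSpec",
    "GroundTruthWarp",
    "straight_bundle",
    "arc_bundle",
    "default_gradient_table",
    "default_phantom_spec",
    "build_tensor_phantom",
    "simulate_dwi",
    "make_ground_truth_warp",
    "warp_phantom",
]


@dataclass
class Bundle:
    """A tube around a parametric centerline curve (voxel coordinates)."""

    curve: object  # callable t in [0,1] -> (3,) voxel coords
    radius: float  # voxels
    eigenvalues: tuple = (1.7e-3, 0.3e-3, 0.3e-3)  # mm^2/s
    name: str = "bundle"
    n_samples: int = 200


def straight_bundle(start, end, radius=4.0, eigenvalues=(1.7e-3, 0.3e-3, 0.3e-3),
                    name="straight") -> Bundle:
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    return Bundle(lambda t: start + t * (end - start), radius, eigenvalues, name)


def arc_bundle(center, arc_radius, theta0, theta1, z, radius=3.0,
               eigenvalues=(1.7e-3, 0.3e-3, 0.3e-3), name="arc") -> Bundle:
    """Circular arc in an axial plane at height ``z`` (voxel coords)."""
    center = np.asarray(center, dtype=float)

    def curve(t):
        th = theta0 + t * (theta1 - theta0)
        return np.array([center[0] + arc_radius * np.cos(th),
                         center[1] + arc_radius * np.sin(th), z])

    return Bundle(curve, radius, eigenvalues, name)


@dataclass
class PhantomSpec:
    grid_shape: tuple = (40, 40, 20)
    voxel_size: tuple = (2.0, 2.0, 2.0)
    bundles: list = field(default_factory=list)
    background_diffusivity: float = 0.7e-3  # mm^2/s isotropic
    s0: float = 1000.0
    noise_sigma: float = 0.0  # Rician sigma, signal units
    seed: int = 0

    def __post_init__(self):
        for b in self.bundles:
            if b.radius <= 0:
                raise ValueError(f"bundle '{b.name}' has non-positive radius")
            if any(ev < 0 for ev in b.eigenvalues):
                raise ValueError(f"bundle '{b.name}' has negative eigenvalues")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


def default_gradient_table(n_dirs: int = 15, b: float = 1000.0) -> GradientTable:
    """One b=0 plus ``n_dirs`` directions spread over the hemisphere.

    Directions follow a Fibonacci spiral on the upper hemisphere — a
    deterministic, well-spread, noncollinear set.
    """
    k = np.arange(n_dirs)
    golden = (1 + np.sqrt(5)) / 2
    z = (k + 0.5) / n_dirs  # upper hemisphere
    theta = 2 * np.pi * k / golden
    r = np.sqrt(1 - z**2)
    dirs = np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)
    bvecs = np.vstack([np.zeros(3), dirs])
    bvals = np.concatenate([[0.0], np.full(n_dirs, b)])
    return GradientTable(bvecs, bvals)


def default_phantom_spec(noise_sigma: float = 0.0, seed: int = 0) -> PhantomSpec:
    """Straight bundle along x plus an arc bundle, on the default grid."""
    # the two tracts carry distinct (realistic) diffusivity profiles so
    # trace varies across the white matter instead of being one constant
    bundles = [
        straight_bundle((2, 20, 10), (37, 20, 10), radius=4.0,
                        eigenvalues=(1.7e-3, 0.3e-3, 0.3e-3)),
        arc_bundle(center=(2, 2), arc_radius=28.0, theta0=np.deg2rad(15),
                   theta1=np.deg2rad(75), z=10.0, radius=3.0,
                   eigenvalues=(2.0e-3, 0.4e-3, 0.4e-3)),
    ]
    return PhantomSpec(bundles=bundles, noise_sigma=noise_sigma, seed=seed)


def _frame_from_tangent(t):
    """Orthonormal (e1, e2, e3) per row with e1 = tangent."""
    t = t / np.linalg.norm(t, axis=-1, keepdims=True)
    ref = np.where(np.abs(t[..., [0]]) < 0.9,
                   np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]))
    e2 = np.cross(t, ref)
    e2 /= np.linalg.norm(e2, axis=-1, keepdims=True)
    e3 = np.cross(t, e2)
    return t, e2, e3


def build_tensor_phantom(spec: PhantomSpec):
    """Rasterize bundle tubes into a tensor field.

    Returns ``(TensorField, e1_truth (X,Y,Z,3), bundle_masks)``.  Overlap
    regions take the first-listed bundle.  A bundle whose centerline
    leaves the grid raises, naming the curve parameter.
    """
    shape = tuple(spec.grid_shape)
    vs = np.asarray(spec.voxel_size, dtype=float)
    affine = np.diag(np.concatenate([vs, [1.0]]))
    iso = spec.background_diffusivity
    D = np.zeros(shape + (3, 3))
    D[..., 0, 0] = D[..., 1, 1] = D[..., 2, 2] = iso
    e1_truth = np.zeros(shape + (3,))
    masks = []
    grid = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                                indexing="ij"), axis=-1)
    flat = grid.reshape(-1, 3)
    claimed = np.zeros(shape, dtype=bool)

    for b in spec.bundles:
        ts = np.linspace(0.0, 1.0, b.n_samples)
        pts = np.stack([np.asarray(b.curve(t), dtype=float) for t in ts])
        out = (pts < 0) | (pts > np.array(shape) - 1)
        if np.any(out):
            bad = ts[np.any(out, axis=1)][0]
            raise ValueError(
                f"bundle '{b.name}' centerline leaves the grid at t={bad:.3f}"
            )
        # distance to the sampled centerline, in voxel units
        d2 = ((flat[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        nearest = np.argmin(d2, axis=1)
        dist = np.sqrt(d2[np.arange(flat.shape[0]), nearest])
        inside = (dist <= b.radius).reshape(shape) & ~claimed
        masks.append(RoiMask(inside, b.name))
        claimed |= inside

        tang_s = np.gradient(pts * vs, axis=0)  # world-space tangents
        tang = tang_s[nearest].reshape(shape + (3,))[inside]
        e1, e2, e3 = _frame_from_tangent(tang)
        l1, l2, l3 = b.eigenvalues
        Din = (l1 * e1[..., :, None] * e1[..., None, :]
               + l2 * e2[..., :, None] * e2[..., None, :]
               + l3 * e3[..., :, None] * e3[..., None, :])
        D[inside] = Din
        e1_truth[inside] = e1

    tf = TensorField(
        coeffs=coeffs_from_tensors(D),
        s0=np.full(shape, spec.s0),
        mask=RoiMask(np.ones(shape, dtype=bool), "phantom"),
        design=np.empty((0, 7)),
        affine=affine,
    )
    return tf, e1_truth, masks


def simulate_dwi(tf: TensorField, gtab: GradientTable, s0: float | None = None,
                 sigma: float = 0.0, seed: int = 0) -> Volume:
    """Forward-model DWI signals with optional Rician noise.

    Noise-free signal is ``S0 exp(-b g^T D g)``; Rician corruption takes
    the magnitude of the signal plus complex Gaussian noise of std
    ``sigma`` per channel.  Deterministic given ``seed``.
    """
    X = design_matrix(gtab)
    s0_map = np.full(tf.shape3, float(s0)) if s0 is not None else tf.s0
    log_s0 = np.log(np.where(s0_map > 0, s0_map, 1.0))
    beta = np.concatenate([tf.coeffs, log_s0[..., None]], axis=-1)
    clean = np.exp(beta @ X.T)
    clean = np.where(s0_map[..., None] > 0, clean, 0.0)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        n1 = rng.normal(0.0, sigma, clean.shape)
        n2 = rng.normal(0.0, sigma, clean.shape)
        data = np.sqrt((clean + n1) ** 2 + n2**2)
    else:
        data = clean
    return Volume(data, tf.affine)


@dataclass
class GroundTruthWarp:
    """Smooth invertible displacement field with known provenance."""

    displacement: np.ndarray  # (X, Y, Z, 3), voxel units
    inverse_displacement: np.ndarray
    max_displacement: float
    control: dict
    seed: int

    def as_deformation(self, affine=None) -> DeformationField:
        return DeformationField(
            self.displacement, self.inverse_displacement,
            np.eye(4) if affine is None else affine,
        )


def make_ground_truth_warp(grid_shape, max_disp: float, seed: int = 0,
                           n_bumps: int = 5, width: float | None = None) -> GroundTruthWarp:
    """Sum-of-Gaussian-bumps displacement, zero at the boundary.

    ``width`` (the bump std, voxels) defaults to ``4 * max_disp`` so the
    field's Jacobian stays safely positive; a width that cannot fit the
    grid raises.  ``max_disp = 0`` returns the identity field.
    """
    shape = tuple(int(s) for s in grid_shape)
    if max_disp < 0:
        raise ValueError("max_disp must be >= 0")
    if width is None:
        width = max(4.0, 4.0 * max_disp)
    if max_disp > 0 and (max_disp > width / 4.0 + 1e-9 or width > max(shape)):
        raise ValueError(
            f"infeasible max_disp={max_disp}: needs bump width >= "
            f"{4 * max_disp} voxels inside a grid of shape {shape}"
        )
    grid = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                                indexing="ij"), axis=-1)
    disp = np.zeros(shape + (3,))
    rng = np.random.default_rng(seed)
    centers = np.array([])
    amps = np.array([])
    if max_disp > 0:
        # bump centers in the central half of the grid: the boundary taper
        # would largely cancel bumps placed near the edges
        lo = 0.25 * np.array(shape)
        hi = 0.75 * np.array(shape)
        centers = rng.uniform(lo, hi, size=(n_bumps, 3))
        amps = rng.normal(0.0, 1.0, size=(n_bumps, 3))
        for c, a in zip(centers, amps):
            r2 = ((grid - c) ** 2).sum(axis=-1)
            disp += np.exp(-r2 / (2.0 * width**2))[..., None] * a
        # cosine taper to zero displacement at the grid boundary
        for ax, s in enumerate(shape):
            x = np.arange(s) / (s - 1)
            win = np.sin(np.pi * x) ** 2
            win[0] = win[-1] = 0.0  # exactly zero on the boundary
            sl = [None] * 3 + [None]
            sl[ax] = slice(None)
            disp *= win[tuple(sl)]
        mx = float(np.max(np.linalg.norm(disp, axis=-1)))
        if mx > 0:
            disp *= max_disp / mx
        # verify diffeomorphism: forward-map Jacobian determinant > 0
        det = _jacobian_det(disp)
        if np.any(det <= 0):
            raise ValueError("generated warp folds (non-positive Jacobian)")
    inv = invert_displacement(disp, n_iter=60, tol=1e-4)
    control = {"centers": centers.tolist() if max_disp > 0 else [],
               "amplitudes": amps.tolist() if max_disp > 0 else [],
               "width": width, "n_bumps": n_bumps}
    return GroundTruthWarp(disp, inv, max_disp, control, seed)


def _jacobian_det(disp: np.ndarray) -> np.ndarray:
    grads = [np.stack(np.gradient(disp[..., c]), axis=-1) for c in range(3)]
    J = np.stack(grads, axis=-2) + np.eye(3)
    return np.linalg.det(J)


def warp_phantom(dwi: Volume, tf: TensorField, warp: GroundTruthWarp):
    """Apply a ground-truth warp to phantom DWI and tensors.

    DWI channels are warped as scalars; the tensor field uses the shared
    finite-strain reorientation.  Returns ``(warped_dwi, warped_tf)``.
    """
    deformation = warp.as_deformation(dwi.affine)
    warped_dwi = warp_scalar(dwi, deformation)
    warped_tf = warp_tensor_field(tf, deformation)
    return warped_dwi, warped_tf
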