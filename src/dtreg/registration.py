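"""Symmetric diffeomorphic registration of fiber visitation maps.

The transform ``phi`` between a moving image I and a fixed image J is
decomposed into two half-paths ``phi1`` (moving -> midpoint) and ``phi2``
(fixed -> midpoint) that meet at the temporal midpoint of the geodesic;
each half is built by integrating its own smooth velocity field, and the
whole construction is inverse-consistent (``phi^-1 o phi = Id``) by
symmetry of the two halves.

Optimization is greedy: at every iteration both images are warped to the
midpoint, the gradient of the similarity (windowed normalized
cross-correlation by default, squared difference as an option) is turned
into a force field, fluid-smoothed, composed into the half displacement
field, and the total field is elastically smoothed.  A Gaussian pyramid
provides multiresolution.  Inverse fields come from fixed-point iteration.

Displacement fields are stored in voxel units with the pull-back
convention: ``warped(x) = image(x + d(x))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .formats_io import Volume
from .tensor_model import TensorField, coeffs_from_tensors, tensors_from_coeffs

__all__ = [
    "RegistrationParams",
    "DeformationField",
    "VelocityField",
    "RegistrationResult",
    "affine_initialize",
    "local_cross_correlation",
    "integrate_velocity",
    "syn_register",
    "warp_scalar",
    "warp_displacement",
    "compose_displacements",
    "invert_displacement",
    "warp_tensor_field",
]


@dataclass
class RegistrationParams:
    """Tunable registration configuration (all lengths in voxels)."""

    metric: str = "cc"  # {"cc", "ssd"}
    cc_radius: int = 2
    levels: int = 3
    iterations: tuple = (100, 70, 40)
    step: float = 0.25  # max update magnitude per iteration, voxels
    sigma_fluid: float = 3.0
    sigma_elastic: float = 1.0
    patience: int = 10
    inverse_iterations: int = 20
    inverse_tol: float = 0.01


@dataclass
class DeformationField:
    """Pull-back displacement field in voxel units, with its inverse."""

    displacement: np.ndarray  # (X, Y, Z, 3)
    inverse_displacement: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def shape3(self):
        return tuple(self.displacement.shape[:3])


@dataclass
class VelocityField:
    """Stationary velocity samples for one half-path."""

    v: np.ndarray  # (X, Y, Z, 3), voxels per unit time
    time_samples: int = 8

    def __post_init__(self):
        if not np.all(np.isfinite(self.v)):
            raise ValueError("velocity field contains non-finite values")


@dataclass
class RegistrationResult:
    phi1: DeformationField  # moving -> midpoint (pull-back from midpoint)
    phi2: DeformationField  # fixed -> midpoint
    full_forward: DeformationField  # resamples moving onto the fixed grid
    similarity_trace: list
    affine_init: np.ndarray = field(default_factory=lambda: np.eye(4))
    diverged: bool = False


# ---------------------------------------------------------------------------
# displacement-field primitives

def _sample_vector(d: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Trilinear sample of a vector field at voxel coordinates (..., 3)."""
    pts = coords.reshape(-1, 3).T
    out = np.stack(
        [ndimage.map_coordinates(d[..., c], pts, order=1, mode="nearest")
         for c in range(3)],
        axis=-1,
    )
    return out.reshape(coords.shape)


def _grid(shape3):
    return np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in shape3], indexing="ij"),
        axis=-1,
    )


def compose_displacements(d_inner: np.ndarray, d_outer: np.ndarray) -> np.ndarray:
    """Displacement of warping first by ``d_outer`` then by ``d_inner``.

    ``w(x) = d_outer(x) + d_inner(x + d_outer(x))`` so that
    ``warp(img, w) == warp(warp(img, d_inner), d_outer)``.
    """
    grid = _grid(d_outer.shape[:3])
    return d_outer + _sample_vector(d_inner, grid + d_outer)


def invert_displacement(d: np.ndarray, n_iter: int = 20, tol: float = 0.01) -> np.ndarray:
    """Fixed-point inverse: ``inv(x) = -d(x + inv(x))``."""
    grid = _grid(d.shape[:3])
    inv = np.zeros_like(d)
    for _ in range(n_iter):
        new = -_sample_vector(d, grid + inv)
        delta = np.max(np.linalg.norm(new - inv, axis=-1))
        inv = new
        if delta < tol:
            break
    return inv


def warp_displacement(vol_data: np.ndarray, d: np.ndarray, order: int = 1,
                      cval: float = 0.0) -> np.ndarray:
    """Pull-back resampling of a 3D array by a voxel displacement field."""
    grid = _grid(d.shape[:3]) + d
    return ndimage.map_coordinates(vol_data, grid.reshape(-1, 3).T, order=order,
                                   mode="constant", cval=cval).reshape(d.shape[:3])


def warp_scalar(vol: Volume, deformation: DeformationField) -> Volume:
    """Warp a 3D (or channel-wise 4D) volume; out-of-bounds reads 0."""
    d = deformation.displacement
    if vol.data.ndim == 3:
        return Volume(warp_displacement(vol.data, d), vol.affine)
    out = np.stack(
        [warp_displacement(vol.data[..., c], d) for c in range(vol.data.shape[3])],
        axis=-1,
    )
    return Volume(out, vol.affine)


# ---------------------------------------------------------------------------
# similarity

def _window_sums(x, radius):
    size = 2 * radius + 1
    return ndimage.uniform_filter(x, size=size, mode="constant") * size**3


def local_cross_correlation(a: Volume | np.ndarray, b: Volume | np.ndarray,
                            radius: int = 2):
    """Windowed normalized cross-correlation and its displacement gradient.

    Returns ``(mean_cc, force)`` where ``force[..., 3]`` is the analytic
    gradient of the local CC with respect to displacing ``a``, i.e. the
    per-voxel ascent direction.  Window statistics use the effective
    (truncated) window size near the boundary.  Zero-variance windows
    contribute 0.
    """
    A = a.data if isinstance(a, Volume) else np.asarray(a, dtype=float)
    B = b.data if isinstance(b, Volume) else np.asarray(b, dtype=float)
    if A.shape != B.shape:
        raise ValueError("local_cross_correlation needs a common grid")
    n = _window_sums(np.ones_like(A), radius)  # effective voxels per window
    sa = _window_sums(A, radius)
    sb = _window_sums(B, radius)
    Ab = A - sa / n
    Bb = B - sb / n
    sab = _window_sums(A * B, radius) - sa * sb / n
    saa = _window_sums(A * A, radius) - sa**2 / n
    sbb = _window_sums(B * B, radius) - sb**2 / n
    eps = 1e-12
    denom = np.sqrt(np.clip(saa * sbb, 0.0, None))
    good = denom > eps
    cc = np.where(good, sab / np.where(good, denom, 1.0), 0.0)
    # d CC / d A(center) = (Bb - (sab/saa) Ab) / sqrt(saa sbb)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(good & (saa > eps),
                     (Bb - (sab / np.where(saa > eps, saa, 1.0)) * Ab)
                     / np.where(good, denom, 1.0),
                     0.0)
    grad_a = np.stack(np.gradient(A), axis=-1)
    force = f[..., None] * grad_a
    return float(cc[good].mean()) if np.any(good) else 0.0, force


def _ssd_force(A, B):
    """Negative squared-difference similarity and its ascent force on A."""
    diff = B - A
    sim = -float(np.mean((A - B) ** 2))
    grad_a = np.stack(np.gradient(A), axis=-1)
    return sim, 2.0 * diff[..., None] * grad_a


# ---------------------------------------------------------------------------
# velocity integration

def integrate_velocity(vf: VelocityField, t0: float = 0.0, t1: float = 1.0) -> DeformationField:
    """Flow of a stationary velocity field by scaling and squaring.

    Zero velocity integrates to the identity; integrating ``-v`` over the
    same interval gives the inverse flow.
    """
    if not (0.0 <= t0 <= 1.0 and 0.0 <= t1 <= 1.0):
        raise ValueError("integration times must lie in [0, 1]")
    total = vf.v * (t1 - t0)
    maxmag = float(np.max(np.linalg.norm(total, axis=-1)))
    # base step small enough that single-step composition error stays far
    # below the 0.05-voxel inverse-consistency budget
    K = 0 if maxmag <= 0.0625 else int(np.ceil(np.log2(maxmag / 0.0625)))
    K = min(max(K, 0), 16)
    d = total / 2**K
    for _ in range(K):
        d = compose_displacements(d, d)
    inv_total = -total
    di = inv_total / 2**K
    for _ in range(K):
        di = compose_displacements(di, di)
    return DeformationField(d, di)


# ---------------------------------------------------------------------------
# affine initialization

def _affine_matrix(params):
    t = params[:3]
    rx, ry, rz = params[3:6]
    scale = np.exp(params[6:9])
    sh = params[9:12]
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    S = np.diag(scale)
    Sh = np.array([[1, sh[0], sh[1]], [0, 1, sh[2]], [0, 0, 1]])
    M = np.eye(4)
    M[:3, :3] = Rz @ Ry @ Rx @ S @ Sh
    M[:3, 3] = t
    return M


def _apply_affine(data, M, center):
    # pull-back about the grid center: x_moving = c + A (x_fixed - c) + t
    A = M[:3, :3]
    t = M[:3, 3]
    offset = center - A @ center + t
    return ndimage.affine_transform(data, A, offset=offset, order=1,
                                    mode="constant", cval=0.0)


def _ncc(a, b):
    am = a - a.mean()
    bm = b - b.mean()
    den = np.sqrt((am**2).sum() * (bm**2).sum())
    return float((am * bm).sum() / den) if den > 0 else 0.0


def affine_initialize(moving: Volume, fixed: Volume) -> np.ndarray:
    """12-parameter affine (voxel space, pull-back about the grid center).

    Translation is seeded by phase correlation, then rotation/scale/shear
    are refined by Powell on global normalized cross-correlation.  Returns
    the identity for identical inputs.
    """
    from scipy.optimize import minimize

    A = np.asarray(moving.data, dtype=float)
    B = np.asarray(fixed.data, dtype=float)
    if A.shape != B.shape:
        raise ValueError("affine_initialize needs a common grid")
    if not (np.any(A) and np.any(B)):
        raise ValueError("empty overlap: one input is identically zero")
    if _ncc(A, B) > 1.0 - 1e-12:
        return np.eye(4)

    shift, _, _ = phase_cross_correlation(B, A, upsample_factor=10,
                                          normalization=None)
    x0 = np.zeros(12)
    x0[:3] = -np.asarray(shift)  # pull-back sign
    center = (np.array(A.shape) - 1) / 2.0

    def cost(p):
        warped = _apply_affine(A, _affine_matrix(p), center)
        return -_ncc(warped, B)

    # staged: rigid (translation + rotation) first, then scale and shear —
    # a joint 12-parameter search lets shear absorb rotation
    rigid = minimize(lambda q: cost(np.concatenate([q, np.zeros(6)])),
                     x0[:6], method="Powell",
                     options={"xtol": 1e-5, "ftol": 1e-10, "maxiter": 20000})
    x0[:6] = rigid.x
    res = minimize(cost, x0, method="Powell",
                   options={"xtol": 1e-5, "ftol": 1e-10, "maxiter": 40000})
    return _affine_matrix(res.x if res.fun <= rigid.fun else x0)


# ---------------------------------------------------------------------------
# SyN-style symmetric registration

def _smooth_field(d, sigma):
    if sigma <= 0:
        return d
    return np.stack(
        [ndimage.gaussian_filter(d[..., c], sigma, mode="nearest")
         for c in range(3)],
        axis=-1,
    )


def _downsample(img, factor):
    if factor == 1:
        return img
    sm = ndimage.gaussian_filter(img, sigma=factor / 2.0, mode="nearest")
    return ndimage.zoom(sm, 1.0 / factor, order=1)


def _upsample_field(d, new_shape):
    factors = [n / o for n, o in zip(new_shape, d.shape[:3])]
    out = np.stack(
        [ndimage.zoom(d[..., c], factors, order=1) * factors[c]
         for c in range(3)],
        axis=-1,
    )
    # zoom may land one voxel off; crop or pad to the exact shape
    pad = [(0, max(0, n - s)) for n, s in zip(new_shape, out.shape[:3])]
    out = np.pad(out, pad + [(0, 0)], mode="edge")
    return out[: new_shape[0], : new_shape[1], : new_shape[2]]


def syn_register(moving: Volume, fixed: Volume,
                 params: RegistrationParams | None = None) -> RegistrationResult:
    """Symmetric diffeomorphic registration of two scalar volumes.

    Both images travel to the temporal midpoint under their own half
    displacement fields, updated in lock-step from the similarity gradient;
    the full forward map is ``phi1 o phi2^-1``.  Swapping the inputs yields
    (within tolerance) the inverse full map.
    """
    p = params or RegistrationParams()
    A = np.asarray(moving.data, dtype=float)
    B = np.asarray(fixed.data, dtype=float)
    if A.shape != B.shape:
        raise ValueError("syn_register needs a common grid")

    factors = [2 ** (p.levels - 1 - k) for k in range(p.levels)]
    iters = list(p.iterations)[-p.levels:]
    while len(iters) < p.levels:
        iters.insert(0, iters[0])

    d1 = d2 = None
    trace = []
    diverged = False
    for level, (factor, n_iter) in enumerate(zip(factors, iters)):
        Al = _downsample(A, factor)
        Bl = _downsample(B, factor)
        shape_l = Al.shape
        if d1 is None:
            d1 = np.zeros(shape_l + (3,))
            d2 = np.zeros(shape_l + (3,))
        else:
            d1 = _upsample_field(d1, shape_l)
            d2 = _upsample_field(d2, shape_l)
        sf = p.sigma_fluid / factor
        se = p.sigma_elastic / factor
        best = -np.inf
        best_fields = None
        prev_sim = -np.inf
        bad = 0
        finest = factor == 1
        for _ in range(n_iter):
            wm = warp_displacement(Al, d1)
            wf = warp_displacement(Bl, d2)
            if p.metric == "cc":
                sim, f1 = local_cross_correlation(wm, wf, p.cc_radius)
                _, f2 = local_cross_correlation(wf, wm, p.cc_radius)
            elif p.metric == "ssd":
                sim, f1 = _ssd_force(wm, wf)
                _, f2 = _ssd_force(wf, wm)
            else:
                raise ValueError("metric must be 'cc' or 'ssd'")
            trace.append(sim)
            if sim > best:
                best = sim
                if finest:
                    best_fields = (d1.copy(), d2.copy())
            if sim < prev_sim - 1e-12:
                bad += 1
                if finest and bad >= p.patience:
                    diverged = True
                    break
            else:
                bad = 0
            prev_sim = sim
            for d, f in ((d1, f1), (d2, f2)):
                u = _smooth_field(f, sf)
                mx = float(np.max(np.linalg.norm(u, axis=-1)))
                if mx > 0:
                    u *= p.step / mx
                d[...] = compose_displacements(d, u)
            d1[...] = _smooth_field(d1, se)
            d2[...] = _smooth_field(d2, se)
        if diverged and best_fields is not None:
            d1, d2 = best_fields

    inv1 = invert_displacement(d1, p.inverse_iterations, p.inverse_tol)
    inv2 = invert_displacement(d2, p.inverse_iterations, p.inverse_tol)
    phi1 = DeformationField(d1, inv1, moving.affine)
    phi2 = DeformationField(d2, inv2, fixed.affine)
    full = compose_displacements(d1, inv2)
    full_inv = compose_displacements(d2, inv1)
    full_forward = DeformationField(full, full_inv, fixed.affine)
    return RegistrationResult(
        phi1=phi1, phi2=phi2, full_forward=full_forward,
        similarity_trace=trace, diverged=diverged,
    )


# ---------------------------------------------------------------------------
# tensor warping with finite-strain reorientation

def _finite_strain_rotations(d: np.ndarray):
    """Per-voxel rotation of the forward map underlying pull-back field d.

    The pull-back Jacobian is ``Jp = I + grad d``; the anatomy's forward
    Jacobian is its inverse, and the finite-strain rotation is the
    orthogonal polar factor of that inverse.  Singular voxels are flagged
    and get the identity.
    """
    grads = [np.stack(np.gradient(d[..., c]), axis=-1) for c in range(3)]
    Jp = np.stack(grads, axis=-2)  # (..., 3row, 3col) = d d_c / d x_k
    Jp = Jp + np.eye(3)
    det = np.linalg.det(Jp)
    singular = np.abs(det) < 1e-8
    Jp_safe = np.where(singular[..., None, None], np.eye(3), Jp)
    F = np.linalg.inv(Jp_safe)
    U, _, Vt = np.linalg.svd(F)
    R = U @ Vt
    # guard against reflections from numerically degenerate Jacobians
    detR = np.linalg.det(R)
    flip = detR < 0
    if np.any(flip):
        U = U.copy()
        U[flip, :, 2] *= -1
        R = U @ Vt
    R = np.where(singular[..., None, None], np.eye(3), R)
    return R, singular


def warp_tensor_field(tf: TensorField, deformation: DeformationField) -> TensorField:
    """Resample a tensor field and reorient by finite strain.

    Tensor components are pulled back through the displacement field, then
    each tensor is conjugated by the rotation part of the local forward
    Jacobian: ``D -> R D R^T``.  Eigenvalues are exactly preserved by the
    conjugation; only orientations change.
    """
    d = deformation.displacement
    coeffs = np.stack(
        [warp_displacement(tf.coeffs[..., c], d) for c in range(6)], axis=-1
    )
    s0 = warp_displacement(tf.s0, d)
    mask_data = warp_displacement(tf.mask.data.astype(float), d) >= 0.5
    R, singular = _finite_strain_rotations(d)
    D = tensors_from_coeffs(coeffs)
    D = R @ D @ np.swapaxes(R, -1, -2)
    from .formats_io import RoiMask

    return TensorField(
        coeffs=coeffs_from_tensors(D), s0=s0,
        mask=RoiMask(mask_data, tf.mask.label), design=tf.design,
        affine=tf.affine, excluded=singular, gtab=tf.gtab,
    )
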