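"""Per-voxel diffusion-tensor estimation and derived scalar maps.

Water displacement over a diffusion time ``t`` is modeled as zero-mean
Gaussian with covariance ``2 t D``, giving the density

    G(x; D, t) = (4 pi t)^(-3/2) det(D)^(-1/2) exp(-x^T D^-1 x / (4 t)).

The measured signal for gradient direction ``g`` and b-value ``b`` is the
single-tensor Stejskal-Tanner attenuation ``S = S0 exp(-b g^T D g)``, which
is linear in log-signal space; the tensor is estimated per voxel by ordinary
least squares on log-signals.  OLS (rather than weighted variants) keeps the
hat-matrix/leverage machinery used by the wild-bootstrap module exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats_io import GradientTable, RoiMask, Volume

__all__ = [
    "TensorField",
    "EigenField",
    "gaussian_profile",
    "design_matrix",
    "fit_tensor",
    "eigendecompose",
    "fa_from_lambdas",
    "fa_map",
    "trace_map",
    "predict_signal",
]

# coefficient order used throughout: Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
_TENSOR_INDEX = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))


def gaussian_profile(D: np.ndarray, x: np.ndarray, t: float) -> float:
    """Gaussian diffusion displacement density at displacement ``x`` (mm).

    Parameters
    ----------
    D : (3, 3) array
        Positive-definite diffusion tensor, mm^2/s.
    x : (3,) array
        Displacement, mm.
    t : float
        Diffusion time, s.  Must be positive.
    """
    D = np.asarray(D, dtype=float)
    x = np.asarray(x, dtype=float).ravel()
    if t <= 0:
        raise ValueError("diffusion time must be positive")
    det = np.linalg.det(D)
    if det <= 0:
        raise np.linalg.LinAlgError("singular or indefinite diffusion tensor")
    quad = x @ np.linalg.solve(D, x)
    return float((4.0 * np.pi * t) ** -1.5 * det**-0.5 * np.exp(-quad / (4.0 * t)))


def design_matrix(gtab: GradientTable) -> np.ndarray:
    """OLS design for the log-linear tensor model.

    Rows are gradients; columns are the 6 tensor terms
    (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) followed by the log-S0 intercept, so that
    ``design @ [D6, log S0] = log S``.
    """
    g = gtab.bvecs
    b = gtab.bvals
    cols = [
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1],
        -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
        np.ones(len(gtab)),
    ]
    return np.stack(cols, axis=1)


@dataclass
class TensorField:
    """Per-voxel diffusion tensors with the retained fitting design.

    ``coeffs`` holds the 6 unique tensor components (mm^2/s) in the order
    Dxx, Dyy, Dzz, Dxy, Dxz, Dyz; ``s0`` the fitted baseline signal;
    ``design`` the (n_gradients, 7) OLS matrix kept for the bootstrap
    module; ``excluded`` flags voxels dropped from the fit because of
    non-positive signals.
    """

    coeffs: np.ndarray  # (X, Y, Z, 6)
    s0: np.ndarray  # (X, Y, Z)
    mask: RoiMask
    design: np.ndarray  # (N, 7)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    excluded: np.ndarray | None = None
    gtab: GradientTable | None = None

    @property
    def shape3(self) -> tuple:
        return tuple(self.coeffs.shape[:3])

    def tensors(self) -> np.ndarray:
        """Full symmetric (..., 3, 3) tensors reconstructed from coeffs."""
        return tensors_from_coeffs(self.coeffs)

    def volume(self) -> Volume:
        return Volume(self.coeffs, self.affine)


def tensors_from_coeffs(coeffs: np.ndarray) -> np.ndarray:
    coeffs = np.asarray(coeffs, dtype=float)
    out = np.zeros(coeffs.shape[:-1] + (3, 3))
    for k, (i, j) in enumerate(_TENSOR_INDEX):
        out[..., i, j] = coeffs[..., k]
        out[..., j, i] = coeffs[..., k]
    return out


def coeffs_from_tensors(tensors: np.ndarray) -> np.ndarray:
    tensors = np.asarray(tensors, dtype=float)
    return np.stack([tensors[..., i, j] for i, j in _TENSOR_INDEX], axis=-1)


def fit_tensor(dwi: Volume, gtab: GradientTable, mask: RoiMask | None = None) -> TensorField:
    """Ordinary least-squares tensor fit on log-signals, per masked voxel.

    Voxels with any non-positive signal are excluded from the fit and
    flagged in ``TensorField.excluded``.
    """
    if dwi.data.ndim != 4:
        raise ValueError("fit_tensor needs a 4D DWI volume")
    if dwi.data.shape[3] != len(gtab):
        raise ValueError("DWI frame count does not match gradient table")
    if int(gtab.dwi_mask.sum()) < 6:
        raise ValueError("tensor fit needs at least 6 nonzero-b directions")
    shape3 = dwi.data.shape[:3]
    if mask is None:
        mask = RoiMask(np.ones(shape3, dtype=bool), "full")
    if mask.data.shape != shape3:
        raise ValueError("mask grid does not match DWI grid")

    X = design_matrix(gtab)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError(
            "rank-deficient tensor design (collinear gradient directions)"
        )
    pinv = np.linalg.pinv(X)

    signals = dwi.data[mask.data]  # (M, N)
    positive = np.all(signals > 0, axis=1)
    excluded3 = np.zeros(shape3, dtype=bool)
    idx = np.argwhere(mask.data)
    bad = idx[~positive]
    excluded3[tuple(bad.T)] = True

    coeffs = np.zeros(shape3 + (6,))
    s0 = np.zeros(shape3)
    if np.any(positive):
        y = np.log(signals[positive])
        beta = y @ pinv.T  # (M+, 7)
        good = idx[positive]
        coeffs[tuple(good.T)] = beta[:, :6]
        s0[tuple(good.T)] = np.exp(beta[:, 6])

    fitted = RoiMask(mask.data & ~excluded3, mask.label or "fit")
    return TensorField(
        coeffs=coeffs, s0=s0, mask=fitted, design=X, affine=dwi.affine,
        excluded=excluded3, gtab=gtab,
    )


@dataclass
class EigenField:
    """Sorted eigenvalues and orthonormal eigenvectors per voxel.

    ``lambdas[..., 0] >= lambdas[..., 1] >= lambdas[..., 2]``;
    ``evecs[..., :, j]`` is the eigenvector paired with ``lambdas[..., j]``.
    ``clamped`` flags voxels where a negative eigenvalue was clipped to 0.
    """

    lambdas: np.ndarray  # (..., 3)
    evecs: np.ndarray  # (..., 3, 3)
    mask: RoiMask | None = None
    clamped: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def e1(self) -> np.ndarray:
        return self.evecs[..., :, 0]


def eigendecompose(tf: TensorField) -> EigenField:
    """Eigen-structure of a fitted field; negatives clamped to 0, flagged."""
    return eigendecompose_tensors(
        tf.tensors(), mask=tf.mask, affine=tf.affine
    )


def eigendecompose_tensors(tensors: np.ndarray, mask: RoiMask | None = None,
                           affine: np.ndarray | None = None) -> EigenField:
    tensors = np.asarray(tensors, dtype=float)
    vals, vecs = np.linalg.eigh(tensors)  # ascending
    vals = vals[..., ::-1]
    vecs = vecs[..., ::-1]
    clamped = np.any(vals < 0, axis=-1)
    vals = np.clip(vals, 0.0, None)
    return EigenField(
        lambdas=vals, evecs=vecs, mask=mask, clamped=clamped,
        affine=np.eye(4) if affine is None else affine,
    )


def fa_from_lambdas(lambdas: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from sorted eigenvalues; 0 where all-zero."""
    lam = np.asarray(lambdas, dtype=float)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sum((lam - mean) ** 2, axis=-1)
    den = np.sum(lam**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


def fa_map(ef: EigenField) -> Volume:
    """FA in [0, 1] per voxel; 0 for isotropic or null tensors."""
    return Volume(fa_from_lambdas(ef.lambdas), ef.affine)


def trace_map(ef: EigenField) -> Volume:
    """Trace (sum of eigenvalues) per voxel, mm^2/s."""
    return Volume(ef.lambdas.sum(axis=-1), ef.affine)


def predict_signal(tf: TensorField, gtab: GradientTable | None = None) -> Volume:
    """Forward model ``S(g, b) = S0 exp(-b g^T D g)`` per voxel and gradient."""
    if gtab is None:
        gtab = tf.gtab
    if gtab is None:
        raise ValueError("predict_signal needs a gradient table")
    X = design_matrix(gtab)
    with np.errstate(divide="ignore"):
        log_s0 = np.where(tf.s0 > 0, np.log(np.where(tf.s0 > 0, tf.s0, 1.0)), 0.0)
    beta = np.concatenate([tf.coeffs, log_s0[..., None]], axis=-1)
    log_sig = beta @ X.T
    sig = np.exp(log_sig)
    sig[~tf.mask.data] = 0.0
    return Volume(sig, tf.affine)
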