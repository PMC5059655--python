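"""Registration-quality metrics for tensor fields.

Three standard criteria quantify how well DTI data align after spatial
normalization:

* dyadic coherence ``kappa`` — inter-subject alignment of principal
  eigenvectors.  Per voxel the mean dyadic tensor ``<e1 e1^T>`` over
  subjects has eigenvalues ``beta1 >= beta2 >= beta3`` and

      kappa = 1 - sqrt((beta2 + beta3) / (2 beta1)),

  which is 1 for identically oriented directions and tends to 0 for
  random ones.  Built from outer products, it is blind to eigenvector
  sign.
* OVL — overlap of eigenvalue-eigenvector pairs between a subject and the
  template: per voxel ``sum_j l_j l'_j (e_j . e'_j)^2 / sum_j l_j l'_j``,
  averaged over the mask; 1 for identical tensors.
* CC — non-centered (cosine) cross-correlation of two scalar maps (FA or
  trace) over white-matter voxels,
  ``sum X1 X2 / sqrt(sum X1^2 sum X2^2)``; in [0, 1] for non-negative
  maps, 1 for proportional maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats_io import RoiMask, Volume
from .tensor_model import EigenField

__all__ = [
    "DyadicTensor",
    "MetricReport",
    "mean_dyadic_tensor",
    "dyadic_coherence",
    "ovl",
    "cross_correlation",
    "empirical_cdf",
    "evaluate_registration",
]

FA_WM_THRESHOLD = 0.2  # template-FA cutoff defining the white-matter mask


@dataclass
class DyadicTensor:
    """Mean outer product of principal eigenvectors with its spectrum."""

    mean_outer: np.ndarray  # (3, 3)
    betas: np.ndarray  # (3,), descending, sum to 1


def mean_dyadic_tensor(e1_vectors: np.ndarray) -> DyadicTensor:
    """Mean dyadic tensor of unit vectors (subjects along the first axis)."""
    e = np.asarray(e1_vectors, dtype=float)
    outer = np.einsum("si,sj->ij", e, e) / e.shape[0]
    betas = np.linalg.eigvalsh(outer)[::-1]
    return DyadicTensor(mean_outer=outer, betas=betas)


def _kappa_from_betas(betas: np.ndarray) -> np.ndarray:
    b1 = betas[..., 0]
    # rank-1 dyadics carry rounding-level beta2/beta3 (possibly negative);
    # the square root amplifies that noise, so snap sub-epsilon mass to 0
    rest = np.clip(betas[..., 1] + betas[..., 2], 0.0, None)
    rest = np.where(rest < 64 * np.finfo(float).eps * b1, 0.0, rest)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = 1.0 - np.sqrt(rest / (2.0 * b1))
    return np.where(b1 > 0, np.clip(k, 0.0, 1.0), np.nan)


def dyadic_coherence(e1_fields: np.ndarray, mask: RoiMask | None = None) -> Volume:
    """Per-voxel dyadic coherence across subjects.

    Parameters
    ----------
    e1_fields : (S, X, Y, Z, 3) array
        Principal eigenvector per subject and voxel (unit or zero vectors).
    mask : RoiMask, optional
        Voxels to evaluate; others (and voxels with any zero input vector)
        are NaN-flagged.
    """
    e = np.asarray(e1_fields, dtype=float)
    if e.ndim != 5 or e.shape[0] < 2:
        raise ValueError("need (subjects, X, Y, Z, 3) with >= 2 subjects")
    norms = np.linalg.norm(e, axis=-1)
    zero_in = np.any(norms < 1e-12, axis=0)
    outer = np.einsum("s...i,s...j->...ij", e, e) / e.shape[0]
    betas = np.linalg.eigvalsh(outer)[..., ::-1]
    kappa = _kappa_from_betas(betas)
    kappa = np.where(zero_in, np.nan, kappa)
    if mask is not None:
        kappa = np.where(mask.data, kappa, np.nan)
    return Volume(kappa)


def ovl(subject: EigenField, template: EigenField, mask: RoiMask | None = None):
    """Eigenvalue-eigenvector overlap; returns ``(scalar, per-voxel map)``.

    Voxels where both tensors are null have an undefined overlap and are
    excluded from the scalar average (their count is reported in the map as
    NaN).
    """
    ls, lt = subject.lambdas, template.lambdas
    if ls.shape != lt.shape:
        raise ValueError("subject and template grids differ")
    dots = np.einsum("...ij,...ij->...j", subject.evecs, template.evecs)
    num = np.sum(ls * lt * dots**2, axis=-1)
    den = np.sum(ls * lt, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vox = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    vox = np.clip(vox, 0.0, 1.0)  # mathematically in [0,1]; trim rounding
    sel = np.isfinite(vox)
    if mask is not None:
        sel &= mask.data
    if not np.any(sel):
        raise ValueError("no voxel with a defined overlap inside the mask")
    return float(vox[sel].mean()), Volume(vox)


def cross_correlation(x1: Volume | np.ndarray, x2: Volume | np.ndarray,
                      mask: RoiMask | None = None, centered: bool = False) -> float:
    """Cosine cross-correlation of two scalar maps over masked voxels.

    The non-centered form ``sum X1 X2 / sqrt(sum X1^2 sum X2^2)`` is the
    default; ``centered=True`` subtracts means first (Pearson form).
    """
    a = (x1.data if isinstance(x1, Volume) else np.asarray(x1, dtype=float)).ravel()
    b = (x2.data if isinstance(x2, Volume) else np.asarray(x2, dtype=float)).ravel()
    if mask is not None:
        m = mask.data.ravel()
        a, b = a[m], b[m]
    if a.size != b.size:
        raise ValueError("maps have different sizes")
    if centered:
        a = a - a.mean()
        b = b - b.mean()
    na = float(a @ a)
    nb = float(b @ b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("all-zero map within the mask")
    return float(a @ b / np.sqrt(na * nb))


def empirical_cdf(values) -> tuple:
    """Empirical CDF ``F(x) = P(X <= x)`` as sorted (value, prob) arrays.

    Duplicated values merge into a single step of accumulated height;
    ``F(max) == 1``.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("empirical_cdf needs at least one finite value")
    uniq, counts = np.unique(v, return_counts=True)
    probs = np.cumsum(counts) / v.size
    return uniq, probs


@dataclass
class MetricReport:
    """Scalar summaries plus per-metric CDF tables."""

    kappa_map: Volume
    kappa_mean: float
    ovl_scalar: float
    ovl_map: Volume
    cc_fa: float
    cc_tr: float
    cdf_tables: dict

    def as_text(self) -> str:
        lines = [
            "metric\tvalue",
            f"kappa_mean\t{self.kappa_mean:.6f}",
            f"ovl\t{self.ovl_scalar:.6f}",
            f"cc_fa\t{self.cc_fa:.6f}",
            f"cc_tr\t{self.cc_tr:.6f}",
        ]
        return "\n".join(lines) + "\n"


def evaluate_registration(subject: EigenField, template: EigenField,
                          subject_fa: Volume, template_fa: Volume,
                          subject_tr: Volume, template_tr: Volume,
                          mask: RoiMask | None = None) -> MetricReport:
    """Full metric report for one subject against a template.

    The white-matter mask defaults to template FA > ``FA_WM_THRESHOLD``.
    Dyadic coherence is computed across the pair (subject, template).
    """
    if mask is None:
        mask = RoiMask(template_fa.data > FA_WM_THRESHOLD, "wm")
    e1 = np.stack([subject.e1, template.e1], axis=0)
    kmap = dyadic_coherence(e1, mask)
    kvals = kmap.data[np.isfinite(kmap.data)]
    ovl_scalar, ovl_map = ovl(subject, template, mask)
    cc_fa = cross_correlation(subject_fa, template_fa, mask)
    cc_tr = cross_correlation(subject_tr, template_tr, mask)
    ovl_vals = ovl_map.data[np.isfinite(ovl_map.data) & mask.data]
    cdf_tables = {
        "kappa": empirical_cdf(kvals) if kvals.size else (np.array([]), np.array([])),
        "ovl": empirical_cdf(ovl_vals),
    }
    return MetricReport(
        kappa_map=kmap, kappa_mean=float(kvals.mean()) if kvals.size else float("nan"),
        ovl_scalar=ovl_scalar, ovl_map=ovl_map,
        cc_fa=cc_fa, cc_tr=cc_tr, cdf_tables=cdf_tables,
    )
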