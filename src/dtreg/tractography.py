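"""Bayesian probabilistic streamline tractography.

At each step the local fiber direction is drawn from a posterior over unit
directions,

    p(v_i | v_{i-1}, data)  prop.to  p(data | v_i, theta) p(v_i | v_{i-1}),

where the likelihood uses a constrained (axially symmetric) Gaussian
diffusion profile with its principal axis fixed at the candidate direction
and the nuisance parameters theta (baseline signal, axial and radial
diffusivities, residual variance) plugged in as point estimates from the
local tensor fit — the Dirac-prior treatment of theta.  The prior is
proportional to cos(angle to the previous direction) on the forward
hemisphere and zero behind it; with no previous direction it is uniform.

Data uncertainty enters through the corrected wild bootstrap: each step
resamples the local DWI signals (module :mod:`dtreg.wild_bootstrap`) before
evaluating the posterior, so the sampled directions reflect the measurement
noise rather than an assumed parametric model.

Region-to-region connectivity is estimated by rejection sampling: many
streamlines are seeded in the source region and the connection probability
is the fraction that reach the target before terminating.

The propagation engine advances whole batches of streamlines in lock-step
with vectorized posterior evaluation, which is what makes thousand-sample
connectivity runs tractable in pure numpy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats_io import GradientTable, RoiMask, Volume
from .sphere import SphereSampling, icosphere
from .tensor_model import design_matrix, fa_from_lambdas, tensors_from_coeffs
from .wild_bootstrap import (
    GAMMA_RELATIVE_TOL,
    SCORE_FUNCTIONS,
    GAMMA_FALLBACK_TOL,
    leverages,
    rescale_factors,
)

__all__ = [
    "TrackingParams",
    "Streamline",
    "ConnectivityEstimate",
    "StreamlineSet",
    "Tracker",
    "direction_posterior",
    "propagate",
    "connectivity",
    "visitation_map",
]

_SIGMA2_FLOOR = 1e-10  # log-signal variance floor for noise-free data


@dataclass
class TrackingParams:
    """Tunable tracking configuration.

    ``step_size`` is in mm; ``None`` selects 0.5 x the smallest voxel
    dimension.  Turning angles beyond 90 degrees are excluded by the
    prior's hemisphere support.
    """

    step_size: float | None = None
    fa_threshold: float = 0.15
    max_steps: int = 2000
    sphere_subdivisions: int = 3  # 642 directions
    multiplier: str = "rademacher"  # {"rademacher", "none"}
    score: str = "identity"
    bidirectional: bool = True


@dataclass
class Streamline:
    """One sampled fiber trajectory in world mm."""

    points: np.ndarray  # (P, 3)
    step_length: float
    terminated_reason: str

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.points.shape[0] < 2:
            raise ValueError("a streamline needs at least 2 points")


@dataclass
class ConnectivityEstimate:
    """Monte-Carlo connection probability between two regions."""

    n_hit: int
    n_total: int

    @property
    def probability(self) -> float:
        return self.n_hit / self.n_total


@dataclass
class StreamlineSet:
    streamlines: list
    visitation: Volume | None = None


def _axial_loglik_terms(beta):
    """Point-estimate nuisance parameters from a per-point tensor fit.

    Returns (log_s0, lam_axial, lam_radial, lambdas) arrays for a batch.
    """
    tensors = tensors_from_coeffs(beta[..., :6])
    lam = np.linalg.eigvalsh(tensors)[..., ::-1]  # descending
    lam = np.clip(lam, 0.0, None)
    l_par = lam[..., 0]
    l_perp = 0.5 * (lam[..., 1] + lam[..., 2])
    return beta[..., 6], l_par, l_perp, lam


def direction_posterior(signals: np.ndarray, gtab: GradientTable,
                        prev_dir: np.ndarray | None,
                        sphere: SphereSampling) -> np.ndarray:
    """Posterior probability over sphere directions at one voxel.

    Returns a vector summing to 1 over ``sphere.points`` (or all zeros when
    no direction is admissible, which signals termination to the caller).
    """
    if len(sphere) < 100:
        raise ValueError("sphere sampling must have at least 100 points")
    signals = np.asarray(signals, dtype=float).ravel()
    X = design_matrix(gtab)
    pinv = np.linalg.pinv(X)
    y = np.log(np.where(signals > 0, signals, 1.0))
    beta = pinv @ y
    resid = y - X @ beta
    dof = max(len(gtab) - X.shape[1], 1)
    sigma2 = max(float(resid @ resid) / dof, _SIGMA2_FLOOR)
    log_s0, l_par, l_perp, _ = _axial_loglik_terms(beta[None])
    b = gtab.bvals
    G2 = (sphere.points @ gtab.bvecs.T) ** 2  # (K, N)
    pred = log_s0[0] - b[None, :] * l_perp[0] - (l_par[0] - l_perp[0]) * b[None, :] * G2
    ll = -0.5 * np.sum((y[None, :] - pred) ** 2, axis=1) / sigma2
    ll -= ll.max()
    like = np.exp(ll)
    prior = _direction_prior(sphere.points, prev_dir)
    post = like * prior
    total = post.sum()
    if total <= 0:
        return np.zeros(len(sphere))
    return post / total


def _direction_prior(points: np.ndarray, prev_dir: np.ndarray | None) -> np.ndarray:
    if prev_dir is None:
        return np.ones(points.shape[0])
    prev = np.asarray(prev_dir, dtype=float)
    prev = prev / np.linalg.norm(prev)
    cos = points @ prev
    return np.where(cos > 0, cos, 0.0)


class Tracker:
    """Batched streamline propagation over one DWI volume.

    Precomputes the tensor design, leverage diagonal and sphere-gradient
    couplings once, then advances all active streamlines together: per step
    each streamline trilinearly interpolates the DWI, refits the tensor,
    draws a corrected wild-bootstrap replicate of its local signals, and
    samples the next direction from the resulting posterior.
    """

    def __init__(self, dwi: Volume, gtab: GradientTable, mask: RoiMask,
                 params: TrackingParams | None = None,
                 target: RoiMask | None = None):
        if dwi.data.ndim != 4:
            raise ValueError("Tracker needs a 4D DWI volume")
        self.dwi = dwi
        self.gtab = gtab
        self.mask = mask
        self.target = target
        self.params = params or TrackingParams()
        p = self.params
        self.step_mm = (p.step_size if p.step_size is not None
                        else 0.5 * float(np.min(dwi.voxel_size)))
        self.sphere = icosphere(p.sphere_subdivisions)
        self.X = design_matrix(gtab)
        self.pinv = np.linalg.pinv(self.X)
        self.h = leverages(self.X)
        self.rescale = rescale_factors(self.h)
        self.psi = SCORE_FUNCTIONS[p.score]
        b = gtab.bvals
        pts = self.sphere.points
        self.bG2 = b[None, :] * (pts @ gtab.bvecs.T) ** 2  # (K, N)
        self.b = b
        self.inv3 = np.linalg.inv(dwi.affine[:3, :3])
        self.A3 = dwi.affine[:3, :3]
        self.origin = dwi.affine[:3, 3]
        self.dof = max(len(gtab) - self.X.shape[1], 1)
        self.shape3 = np.array(dwi.shape3)

    # -- low-level helpers -------------------------------------------------

    def _world_to_voxel(self, xyz):
        return (xyz - self.origin) @ self.inv3.T

    def _interp_signals(self, vox):
        """Trilinear interpolation of all DWI channels at voxel coords.

        Returns (signals (M, N), valid (M,)) — invalid where outside the
        grid or the tracking mask.
        """
        M = vox.shape[0]
        lo = np.floor(vox).astype(int)
        frac = vox - lo
        valid = np.all(lo >= 0, axis=1) & np.all(lo + 1 <= self.shape3 - 1, axis=1)
        lo_c = np.clip(lo, 0, self.shape3 - 2)
        out = np.zeros((M, self.dwi.data.shape[3]))
        for dx in (0, 1):
            wx = frac[:, 0] if dx else 1 - frac[:, 0]
            for dy in (0, 1):
                wy = frac[:, 1] if dy else 1 - frac[:, 1]
                for dz in (0, 1):
                    wz = frac[:, 2] if dz else 1 - frac[:, 2]
                    w = (wx * wy * wz)[:, None]
                    out += w * self.dwi.data[lo_c[:, 0] + dx, lo_c[:, 1] + dy,
                                             lo_c[:, 2] + dz]
        nearest = np.clip(np.rint(vox).astype(int), 0, self.shape3 - 1)
        in_mask = self.mask.data[nearest[:, 0], nearest[:, 1], nearest[:, 2]]
        return out, valid & in_mask

    def _posterior_batch(self, y, prev, rng):
        """Vectorized posterior over the sphere for a batch of points.

        ``y``: (M, N) replicate log-signals; ``prev``: (M, 3) previous unit
        directions or rows of NaN for 'no previous direction'.
        Returns sampled direction indices and a per-point FA and validity.
        """
        beta = y @ self.pinv.T  # (M, 7)
        resid = y - beta @ self.X.T
        sigma2 = np.maximum((resid**2).sum(axis=1) / self.dof, _SIGMA2_FLOOR)
        log_s0, l_par, l_perp, lam = _axial_loglik_terms(beta)
        fa = fa_from_lambdas(lam)
        dlam = np.maximum(l_par - l_perp, 0.0)

        # pred[m,k,i] = a[m,i] - dlam[m]*bG2[k,i]  with a = log_s0 - b*l_perp
        a = log_s0[:, None] - self.b[None, :] * l_perp[:, None]  # (M, N)
        # sum_i (y - pred)^2 expanded into three matmul-reducible terms
        d = y - a  # (M, N)
        t1 = (d**2).sum(axis=1)  # (M,)
        t2 = d @ self.bG2.T  # (M, K)
        t3 = (self.bG2**2).sum(axis=1)  # (K,)
        sq = t1[:, None] + 2.0 * dlam[:, None] * t2 + dlam[:, None] ** 2 * t3[None, :]
        ll = -0.5 * sq / sigma2[:, None]
        ll -= ll.max(axis=1, keepdims=True)
        like = np.exp(ll)

        has_prev = ~np.isnan(prev[:, 0])
        prior = np.ones_like(like)
        if np.any(has_prev):
            cos = prev[has_prev] @ self.sphere.points.T
            prior[has_prev] = np.where(cos > 0, cos, 0.0)
        post = like * prior
        total = post.sum(axis=1)
        ok = total > 0
        cdf = np.cumsum(post, axis=1)
        u = rng.random(y.shape[0]) * total
        idx = (cdf < u[:, None]).sum(axis=1)
        idx = np.clip(idx, 0, len(self.sphere) - 1)
        return idx, fa, ok

    def _replicate(self, y, rng):
        """Corrected wild-bootstrap replicate of per-point log-signals."""
        beta = y @ self.pinv.T
        fitted = beta @ self.X.T
        r = y - fitted
        rt = r * self.rescale[None, :]
        psi_rt = self.psi(rt)
        gamma = psi_rt.mean(axis=1)
        scale = np.abs(psi_rt).mean(axis=1)
        weak = np.abs(gamma) < np.maximum(GAMMA_FALLBACK_TOL,
                                          GAMMA_RELATIVE_TOL * scale)
        gamma = np.where(weak, 1.0, gamma)
        rstar = rt + (self.h[None, :] / gamma[:, None]) * psi_rt
        if self.params.multiplier == "rademacher":
            w = rng.integers(0, 2, size=y.shape) * 2 - 1
        else:
            w = 1
        return fitted + w * rstar

    # -- propagation -------------------------------------------------------

    def run_half(self, seeds_world: np.ndarray, prev_dirs: np.ndarray,
                 rng: np.random.Generator):
        """Advance a batch of half-streamlines until every one terminates.

        ``prev_dirs`` rows may be NaN to request an unconstrained first
        step.  Returns (per-streamline point lists in world mm including
        the seed, termination reasons, first sampled directions, hit flags).
        """
        M = seeds_world.shape[0]
        pos = np.asarray(seeds_world, dtype=float).copy()
        prev = np.asarray(prev_dirs, dtype=float).copy()
        pts = [[pos[m].copy()] for m in range(M)]
        reason = np.array(["max_steps"] * M, dtype=object)
        first_dir = np.full((M, 3), np.nan)
        hit = np.zeros(M, dtype=bool)
        active = np.arange(M)
        if self.target is not None:
            vox0 = np.clip(np.rint(self._world_to_voxel(pos)).astype(int),
                           0, self.shape3 - 1)
            hit |= self.target.data[vox0[:, 0], vox0[:, 1], vox0[:, 2]]

        for step in range(self.params.max_steps):
            if active.size == 0:
                break
            vox = self._world_to_voxel(pos[active])
            sig, valid = self._interp_signals(vox)
            sig_ok = valid & np.all(sig > 0, axis=1)
            reason[active[~sig_ok]] = "left_mask"
            if not np.all(sig_ok):
                active = active[sig_ok]
                sig = sig[sig_ok]
            if active.size == 0:
                break
            y = np.log(sig)
            y_rep = self._replicate(y, rng)
            idx, fa, ok = self._posterior_batch(y_rep, prev[active], rng)

            low_fa = fa < self.params.fa_threshold
            reason[active[low_fa]] = "low_anisotropy"
            dead_post = ~ok & ~low_fa
            reason[active[dead_post]] = "sharp_turn"
            keep = ok & ~low_fa
            active = active[keep]
            idx = idx[keep]
            if active.size == 0:
                break

            dirs = self.sphere.points[idx]
            if step == 0:
                first_dir[active] = dirs
            pos[active] = pos[active] + dirs * self.step_mm
            prev[active] = dirs
            for m, a in enumerate(active):
                pts[a].append(pos[a].copy())

            if self.target is not None:
                voxn = np.clip(np.rint(self._world_to_voxel(pos[active])).astype(int),
                               0, self.shape3 - 1)
                reached = self.target.data[voxn[:, 0], voxn[:, 1], voxn[:, 2]]
                hit[active[reached]] = True
                reason[active[reached]] = "reached_target"
                active = active[~reached]
        return pts, reason, first_dir, hit

    def track(self, seeds_world: np.ndarray, rng_seed: int):
        """Full (optionally bidirectional) tracking from seed points.

        Returns (list of Streamline, hit flags).  Deterministic given
        ``rng_seed``.
        """
        seeds_world = np.atleast_2d(np.asarray(seeds_world, dtype=float))
        rng = np.random.default_rng(rng_seed)
        M = seeds_world.shape[0]
        nan_prev = np.full((M, 3), np.nan)
        pts1, reason1, first_dir, hit1 = self.run_half(seeds_world, nan_prev, rng)
        streamlines = []
        if self.params.bidirectional:
            back = -first_dir
            # halves that never took a step keep an unconstrained back prior
            pts2, reason2, _, hit2 = self.run_half(seeds_world, back, rng)
            hit = hit1 | hit2
            for m in range(M):
                rev = pts2[m][:0:-1]  # drop duplicated seed
                merged = np.asarray(rev + pts1[m])
                reason = reason1[m]
                if reason != "reached_target" and reason2[m] == "reached_target":
                    reason = "reached_target"
                if merged.shape[0] < 2:
                    # degenerate: no admissible step from the seed at all
                    merged = np.vstack([merged[0], merged[0]])
                streamlines.append(Streamline(merged, self.step_mm, reason))
        else:
            hit = hit1
            for m in range(M):
                merged = np.asarray(pts1[m])
                if merged.shape[0] < 2:
                    merged = np.vstack([merged[0], merged[0]])
                streamlines.append(Streamline(merged, self.step_mm, reason1[m]))
        return streamlines, hit


def propagate(seed, dwi: Volume, gtab: GradientTable, mask: RoiMask,
              params: TrackingParams | None = None, rng_seed: int = 0) -> Streamline:
    """Propagate a single streamline from a world-mm seed point."""
    seed = np.asarray(seed, dtype=float).ravel()
    tracker = Tracker(dwi, gtab, mask, params)
    vox = np.clip(np.rint(tracker._world_to_voxel(seed[None])).astype(int),
                  0, tracker.shape3 - 1)[0]
    if not mask.data[tuple(vox)]:
        raise ValueError(f"seed {seed.tolist()} lies outside the tracking mask")
    sls, _ = tracker.track(seed[None], rng_seed)
    return sls[0]


def connectivity(seedA: RoiMask, targetB: RoiMask, dwi: Volume,
                 gtab: GradientTable, mask: RoiMask,
                 params: TrackingParams | None = None,
                 n_samples: int = 1000, rng_seed: int = 0):
    """Rejection-sampling connectivity estimate from region A to region B.

    Launches ``n_samples`` streamlines from uniformly drawn voxels of A and
    counts the fraction that enter B before terminating.  Returns
    ``(ConnectivityEstimate, StreamlineSet)``.
    """
    if seedA.n_voxels == 0 or targetB.n_voxels == 0:
        raise ValueError("seed and target masks must be nonempty")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(rng_seed)
    vox = np.argwhere(seedA.data)
    picks = vox[rng.integers(0, vox.shape[0], size=n_samples)]
    dwi_vol = dwi
    seeds_world = (picks @ dwi_vol.affine[:3, :3].T) + dwi_vol.affine[:3, 3]
    tracker = Tracker(dwi, gtab, mask, params, target=targetB)
    sls, hit = tracker.track(seeds_world, rng_seed=int(rng.integers(2**31)))
    est = ConnectivityEstimate(n_hit=int(hit.sum()), n_total=n_samples)
    sset = StreamlineSet(streamlines=sls)
    sset.visitation = visitation_map(sls, dwi_vol)
    return est, sset


def visitation_map(streamlines, grid: Volume) -> Volume:
    """Per-voxel count of distinct streamlines passing through.

    Each streamline increments a voxel at most once; points outside the
    grid are dropped.
    """
    shape3 = grid.shape3
    counts = np.zeros(shape3, dtype=np.int64)
    inv = np.linalg.inv(grid.affine)
    for s in streamlines:
        pts = s.points if isinstance(s, Streamline) else np.asarray(s)
        vox = np.rint(pts @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        inside = np.all((vox >= 0) & (vox < np.array(shape3)), axis=1)
        vox = vox[inside]
        if vox.size == 0:
            continue
        uniq = np.unique(vox, axis=0)
        counts[uniq[:, 0], uniq[:, 1], uniq[:, 2]] += 1
    return Volume(counts, grid.affine)
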