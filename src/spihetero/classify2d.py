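"""EMC-style 2D classification of sparse photon frames.

Frames with O(100-1000) photons cannot be interpreted individually; an
expectation-maximization scheme with Poisson photon statistics classifies
them into a set of dense class averages while marginalizing over in-plane
rotation and estimating a per-frame incident fluence.  This is the 2D
(classification) variant of the expand-maximize-compress algorithm: the
hidden variables are (class, in-plane rotation), the model parameters are
the class intensities and per-frame fluences, and both are updated from
posterior-weighted sufficient statistics, so the total log-likelihood is
non-decreasing (generalized EM).

A bootstrapping driver repeats the reconstruction on random subsets of the
frames to multiply the number of averages beyond what a single run can
support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .errors import ConfigurationError
from .geometry import DetectorGeometry
from .simulate import PhotonFrameSet

__all__ = [
    "ClassAverage2D",
    "BootstrapEnsemble",
    "emc_classify",
    "assign_frames",
    "bootstrap_classify",
    "EMCResult",
]

log = logging.getLogger(__name__)


@dataclass
class ClassAverage2D:
    """Dense, fluence-normalized class average on the detector grid.

    ``intensity`` is finite everywhere: pixels never observed (persistent
    gaps) are filled from the radial mean and flagged in ``gap_filled``.
    ``occupancy`` is the effective number of member frames (sum of
    posterior responsibilities).
    """

    intensity: np.ndarray = field(repr=False)
    occupancy: float
    gap_filled: np.ndarray | None = field(default=None, repr=False)
    member_frames: np.ndarray | None = field(default=None, repr=False)
    responsibilities: np.ndarray | None = field(default=None, repr=False)
    meta: dict = field(default_factory=dict)


@dataclass
class EMCResult:
    averages: list[ClassAverage2D]
    posterior_summary: dict
    log_likelihood: list[float]


@dataclass
class BootstrapEnsemble:
    """Class averages pooled over several subset runs."""

    averages: list[ClassAverage2D]
    run_index: np.ndarray
    run_seeds: np.ndarray
    subset_fraction: float

    def __len__(self) -> int:
        return len(self.averages)


def _rotation_ops(geometry: DetectorGeometry, n_rot: int):
    """Bilinear rotation stencils between model and frame pixel grids.

    Returns ``(idx, wt)`` of shapes (n_rot, n_pix, 4): under rotation r the
    frame-space model value at pixel p is ``sum_j wt[r,p,j] *
    model[idx[r,p,j]]``.  Sources falling off the detector or on masked
    pixels carry zero weight; weights are renormalized where at least a
    quarter of the stencil mass survives, otherwise the pixel is invalid
    (all-zero weights).  Bilinear (not nearest-neighbour) interpolation is
    essential: the Poisson log-likelihood heavily penalizes photons landing
    on misregistered speckle minima.
    """
    h, w = geometry.shape
    cy, cx = geometry.center
    good = geometry.good.ravel()
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = (yy - cy).ravel(), (xx - cx).ravel()
    n_pix = h * w
    idx = np.zeros((n_rot, n_pix, 4), dtype=np.int64)
    wt = np.zeros((n_rot, n_pix, 4))
    for r, theta in enumerate(np.arange(n_rot) * (2.0 * np.pi / n_rot)):
        ct, st = np.cos(theta), np.sin(theta)
        sy = cy + dy * ct - dx * st
        sx = cx + dy * st + dx * ct
        y0 = np.floor(sy).astype(np.int64)
        x0 = np.floor(sx).astype(np.int64)
        fy, fx = sy - y0, sx - x0
        for j, (oy, ox) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
            yj, xj = y0 + oy, x0 + ox
            inside = (yj >= 0) & (yj < h) & (xj >= 0) & (xj < w)
            flat = np.where(inside, yj * w + xj, 0)
            wj = (fy if oy else 1 - fy) * (fx if ox else 1 - fx)
            wj = np.where(inside & good[flat], wj, 0.0)
            idx[r, :, j] = flat
            wt[r, :, j] = wj
        tot = wt[r].sum(axis=1)
        ok = tot > 0.25
        wt[r, ok] /= tot[ok, None]
        wt[r, ~ok] = 0.0
    return idx, wt


def default_n_rotations(geometry: DetectorGeometry) -> int:
    """pi times the radial bin count, rounded (angular Nyquist heuristic)."""
    return int(round(np.pi * (min(geometry.shape) // 2)))


def _radial_fill(img: np.ndarray, known: np.ndarray, geometry: DetectorGeometry) -> np.ndarray:
    """Fill unknown pixels with the radial mean of the known ones."""
    r = geometry.radius_px.ravel()
    nb = int(r.max()) + 2
    idx = np.minimum(r.astype(int), nb - 1)
    flat = img.ravel()
    kf = known.ravel()
    sums = np.bincount(idx[kf], weights=flat[kf], minlength=nb)
    cnts = np.bincount(idx[kf], minlength=nb)
    prof = sums / np.maximum(cnts, 1)
    out = flat.copy()
    out[~kf] = prof[idx[~kf]]
    return out.reshape(img.shape)


def emc_classify(
    frames: PhotonFrameSet,
    n_classes: int,
    n_inplane_rotations: int | None = None,
    n_iterations: int = 30,
    seed: int = 0,
    tol: float = 1e-3,
    keep_posteriors: bool = False,
    anneal: bool | float = True,
    n_restarts: int = 1,
) -> EMCResult:
    """Classify sparse frames into fluence-normalized class averages.

    Each iteration evaluates the Poisson log-likelihood of every frame
    under every (class, rotation) hypothesis in the log domain (per-frame
    max subtracted), normalizes the posterior, and updates class models and
    per-frame fluences from posterior-weighted sums.  Convergence is
    declared when the mean per-pixel relative model change drops below
    ``tol``.  Ties in the posterior argmax break toward the lowest class
    index.

    ``anneal`` applies deterministic annealing: posteriors are tempered by
    a temperature that decays to 1 over the first half of the iterations,
    preventing the sharp Poisson likelihood from freezing frames into the
    arbitrary initial split.  ``True`` picks the starting temperature from
    the median photon count; a float sets it explicitly; ``False`` runs
    strict (generalized) EM from the first iteration, whose total
    log-likelihood is non-decreasing when rotations are exact grid
    permutations (multiples of 90 degrees).
    """
    if n_classes < 1:
        raise ConfigurationError("n_classes must be >= 1")
    if frames.n_frames == 0:
        raise ConfigurationError("empty frame set")
    if n_restarts > 1:
        runs = [
            emc_classify(
                frames,
                n_classes,
                n_inplane_rotations,
                n_iterations,
                seed=seed + 1000 * i,
                tol=tol,
                keep_posteriors=keep_posteriors,
                anneal=anneal,
            )
            for i in range(n_restarts)
        ]
        return max(runs, key=lambda r: r.log_likelihood[-1])
    geometry = frames.geometry
    if n_inplane_rotations is None:
        n_inplane_rotations = default_n_rotations(geometry)
    n_rot = n_inplane_rotations
    rng = np.random.default_rng(seed)
    n_pix = int(np.prod(geometry.shape))
    good = geometry.good.ravel()
    rot_idx, rot_wt = _rotation_ops(geometry, n_rot)
    # per-rotation weighted pixel coverage of each model pixel
    cover = np.empty((n_rot, n_pix))
    for r in range(n_rot):
        gp = good
        cover[r] = np.bincount(
            rot_idx[r][gp].ravel(), weights=rot_wt[r][gp].ravel(), minlength=n_pix
        )

    counts = frames.counts.tocsr().astype(float)
    n_frames = counts.shape[0]
    photons = np.asarray(counts.sum(axis=1)).ravel()

    # init: smoothed dataset mean with small random perturbations per class.
    # A soft, nearly symmetric start lets classes differentiate gradually;
    # seeding from individual sharp frames hard-freezes the posteriors into
    # arbitrary splits on the first iteration.
    from scipy.ndimage import gaussian_filter

    mean_img = np.asarray(counts.mean(axis=0)).reshape(geometry.shape)
    mean_img = gaussian_filter(mean_img, sigma=1.5)
    w = np.clip(
        mean_img.ravel()[None, :] * (1.0 + 0.1 * rng.standard_normal((n_classes, n_pix))),
        0.0,
        None,
    )
    w *= np.where(good, 1.0, 0.0)[None, :]
    w /= w.sum(axis=1, keepdims=True)

    phi = photons / 1.0  # per-frame fluence; model normalized to unit sum
    loglik_history: list[float] = []
    prev_w = w.copy()
    floor = 1e-12
    if anneal is True:
        t0 = max(1.0, float(np.median(photons)) / 10.0)
    elif anneal is False:
        t0 = 1.0
    else:
        t0 = max(1.0, float(anneal))
    n_anneal = max(1, n_iterations // 2)

    for it in range(n_iterations):
        temp = 1.0 + (t0 - 1.0) * max(0.0, 1.0 - it / n_anneal)
        # expand: rotated log-models, (n_rot * n_classes, n_pix) in frame space
        w_rot = np.empty((n_classes * n_rot, n_pix))
        wsum_rot = np.empty(n_classes * n_rot)
        for r in range(n_rot):
            block = np.einsum("kpj,pj->kp", w[:, rot_idx[r]], rot_wt[r])
            sl = slice(r * n_classes, (r + 1) * n_classes)
            w_rot[sl] = block
            wsum_rot[sl] = block[:, good].sum(axis=1)
        log_w = np.log(np.maximum(w_rot, floor))
        # E-step: log P(frame | k, r) = sum_c c log(phi w) - phi * wsum
        ll = counts @ log_w.T  # (n_frames, K*R), sparse @ dense
        ll = np.asarray(ll)
        ll += photons[:, None] * np.log(np.maximum(phi, floor))[:, None]
        ll -= phi[:, None] * wsum_rot[None, :]
        m = ll.max(axis=1, keepdims=True)
        post = np.exp((ll - m) / temp)
        norm = post.sum(axis=1, keepdims=True)
        post /= norm
        with np.errstate(divide="ignore"):
            log_norm_t1 = np.log(np.exp(ll - m).sum(axis=1))
        total_ll = float((m.ravel() + log_norm_t1 - np.log(n_classes * n_rot)).sum())
        loglik_history.append(total_ll)

        # M-step, fluence: phi_f = N_f / E[wsum]
        exp_wsum = post @ wsum_rot
        phi = photons / np.maximum(exp_wsum, floor)

        # M-step, models: numerator scatter of posterior-weighted photons
        numer = np.zeros((n_classes, n_pix))
        denom = np.zeros((n_classes, n_pix))
        post_kr = post.reshape(n_frames, n_rot, n_classes)
        for r in range(n_rot):
            pw_tot = (post_kr[:, r, :] * phi[:, None]).sum(axis=0)  # (K,)
            a = np.asarray((counts.T @ post_kr[:, r, :]).T)  # (K, n_pix), frame space
            # scatter photons from frame pixels into their bilinear model sources
            for j in range(4):
                np.add.at(numer.T, rot_idx[r, :, j], (a * rot_wt[r, :, j][None, :]).T)
            denom += pw_tot[:, None] * cover[r][None, :]
        w_new = numer / np.maximum(denom, floor)
        covered = denom.sum(axis=0) > 0

        # empty-class rescue: reseed from the worst-explained frame
        occ = post_kr.sum(axis=(0, 1))
        for k in np.nonzero(occ < 1e-6)[0]:
            worst = int(np.argmin(post.max(axis=1)))
            img = np.asarray(counts[worst].todense()).reshape(geometry.shape)
            w_new[k] = gaussian_filter(img, sigma=2.0).ravel()
            log.info("reseeded empty class %d from frame %d", k, worst)
        w_new *= np.where(good, 1.0, 0.0)[None, :]
        sums = w_new.sum(axis=1, keepdims=True)
        w_new /= np.maximum(sums, floor)

        change = np.abs(w_new - prev_w).mean() / max(prev_w.mean(), floor)
        prev_w = w_new.copy()
        w = w_new
        if change < tol and it > 0:
            break

    # final posterior summary with converged model
    occupancy = post_kr.sum(axis=(0, 1))
    flat_best = np.asarray(
        [int(np.argmax(row)) for row in post]
    )  # argmax ties -> lowest flat index = lowest class at rotation 0 first
    best_rot, best_class = np.divmod(flat_best, n_classes)

    averages: list[ClassAverage2D] = []
    gap_fill_mask = ~covered.reshape(geometry.shape)
    for k in range(n_classes):
        img = w[k].reshape(geometry.shape).copy()
        img = _radial_fill(img, covered.reshape(geometry.shape), geometry)
        members = np.nonzero(best_class == k)[0]
        averages.append(
            ClassAverage2D(
                intensity=img,
                occupancy=float(occupancy[k]),
                gap_filled=gap_fill_mask,
                member_frames=members,
                responsibilities=post_kr[:, :, k].sum(axis=1)[members]
                if len(members)
                else None,
                meta={"class_index": k, "seed": seed},
            )
        )
    summary = {
        "map_class": best_class,
        "map_rotation": best_rot,
        "fluence": phi,
        "posterior": post_kr if keep_posteriors else None,
    }
    return EMCResult(averages=averages, posterior_summary=summary, log_likelihood=loglik_history)


def assign_frames(
    frames: PhotonFrameSet,
    averages: list[ClassAverage2D],
    n_inplane_rotations: int | None = None,
) -> dict:
    """Assign frames to fixed class averages (no model update).

    Per frame, the Poisson log-likelihood is profiled over the fluence
    analytically (phi = photons / rotated-model sum) and maximized over
    (class, rotation).  Rescaling all counts of a frame by a constant
    leaves the argmax unchanged and scales the fluence estimate by the
    same constant.
    """
    geometry = frames.geometry
    if n_inplane_rotations is None:
        n_inplane_rotations = default_n_rotations(geometry)
    n_rot = n_inplane_rotations
    n_pix = int(np.prod(geometry.shape))
    good = geometry.good.ravel()
    rot_idx, rot_wt = _rotation_ops(geometry, n_rot)
    w = np.stack([np.clip(a.intensity.ravel(), 0.0, None) for a in averages])
    w *= np.where(good, 1.0, 0.0)[None, :]
    w /= np.maximum(w.sum(axis=1, keepdims=True), 1e-300)
    n_classes = len(averages)
    counts = frames.counts.tocsr().astype(float)
    photons = np.asarray(counts.sum(axis=1)).ravel()
    floor = 1e-12
    ll = np.empty((frames.n_frames, n_rot * n_classes))
    wsum_rot = np.empty(n_rot * n_classes)
    w_rot = np.empty((n_classes, n_pix))
    for r in range(n_rot):
        w_rot = np.einsum("kpj,pj->kp", w[:, rot_idx[r]], rot_wt[r])
        sl = slice(r * n_classes, (r + 1) * n_classes)
        ll[:, sl] = counts @ np.log(np.maximum(w_rot, floor)).T
        wsum_rot[sl] = w_rot[:, good].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll += photons[:, None] * (
            np.log(np.maximum(photons, floor))[:, None]
            - np.log(np.maximum(wsum_rot, floor))[None, :]
            - 1.0
        )
    best = ll.argmax(axis=1)
    rot, cls = np.divmod(best, n_classes)
    phi = photons / np.maximum(wsum_rot[best], floor)
    return {"map_class": cls, "map_rotation": rot, "fluence": phi, "loglik": ll}


def bootstrap_classify(
    frames: PhotonFrameSet,
    n_runs: int,
    n_classes: int,
    subset_fraction: float = 0.8,
    seed: int = 0,
    **emc_kwargs,
) -> BootstrapEnsemble:
    """Repeat EMC classification on random frame subsets and pool averages.

    Each run draws ``subset_fraction`` of the frames without replacement
    with an independently derived seed, yielding ``n_runs * n_classes``
    averages whose member populations differ between runs.
    """
    if not 0.0 < subset_fraction <= 1.0:
        raise ConfigurationError("subset_fraction must lie in (0, 1]")
    n_sub = int(round(subset_fraction * frames.n_frames))
    if n_sub < n_classes:
        raise ConfigurationError(
            f"subset of {n_sub} frames cannot support {n_classes} classes"
        )
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_runs)[:n_runs] % (2**31)
    averages: list[ClassAverage2D] = []
    run_index = []
    for run, run_seed in enumerate(seeds):
        rng = np.random.default_rng(run_seed)
        idx = np.sort(rng.choice(frames.n_frames, size=n_sub, replace=False))
        sub = frames.subset(idx)
        log.info("bootstrap run %d: %d frames, seed %d", run, n_sub, run_seed)
        result = emc_classify(sub, n_classes, seed=int(run_seed), **emc_kwargs)
        for avg in result.averages:
            avg.meta.update({"run": run, "run_seed": int(run_seed)})
            if avg.member_frames is not None:
                avg.member_frames = idx[avg.member_frames]
        averages.extend(result.averages)
        run_index.extend([run] * n_classes)
    return BootstrapEnsemble(
        averages=averages,
        run_index=np.asarray(run_index),
        run_seeds=np.asarray(seeds),
        subset_fraction=subset_fraction,
    )
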