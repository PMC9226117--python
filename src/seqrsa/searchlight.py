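"""Whole-volume searchlight RSA with sign-flip/TFCE group correction.

For every brain voxel, the gray-matter voxels of a sphere of fixed radius
(voxel units) around it are collected; spheres with 25 or fewer gray
voxels are discarded.  Within each sphere the pattern-similarity change is
computed from the voxel patterns and three linear models are fitted
(same-sequence virtual-time slope, different-sequence slope, membership x
virtual-time interaction); each model's focal t is stored at the center.

Group statistics: voxelwise one-sample t over subjects, threshold-free
cluster enhancement (TFCE), and family-wise correction within a
small-volume mask via the max-TFCE null over random sign-flips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .design import zscore, select_pairs
from .exceptions import DesignValidationError
from .rsa import FISHER_CLIP

__all__ = [
    "VolumeGrid",
    "sphere_offsets",
    "sphere_indices",
    "run_searchlight",
    "smooth_map",
    "tfce",
    "group_map_test",
    "peak_roi_from_cluster",
]

GAUSS_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class VolumeGrid:
    """Volume geometry: dimensions, voxel size, brain and gray-matter masks."""

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    brain_mask: np.ndarray = field(repr=False)
    graymatter_mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.brain_mask = np.asarray(self.brain_mask, bool)
        self.graymatter_mask = np.asarray(self.graymatter_mask, bool)
        if self.brain_mask.shape != tuple(self.dims) or \
                self.graymatter_mask.shape != tuple(self.dims):
            raise DesignValidationError("masks must match the volume dimensions")
        if np.any(self.graymatter_mask & ~self.brain_mask):
            raise DesignValidationError("gray-matter mask must nest inside the brain mask")


def sphere_offsets(radius: float) -> np.ndarray:
    """Integer offsets with Euclidean norm <= radius (voxel units)."""
    r = int(np.floor(radius))
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= radius**2
    return np.stack([dx[keep], dy[keep], dz[keep]], axis=1)


def sphere_indices(
    center: tuple[int, int, int], radius: float, grid: VolumeGrid
) -> np.ndarray:
    """Voxel indices (n, 3) of the sphere around ``center`` within the brain mask."""
    center = np.asarray(center, int)
    if np.any(center < 0) or np.any(center >= np.asarray(grid.dims)):
        raise DesignValidationError(f"center {tuple(center)} outside volume {grid.dims}")
    if not grid.brain_mask[tuple(center)]:
        raise DesignValidationError(f"center {tuple(center)} outside the brain mask")
    pts = center[None, :] + sphere_offsets(radius)
    ok = np.all((pts >= 0) & (pts < np.asarray(grid.dims)[None, :]), axis=1)
    pts = pts[ok]
    inside = grid.brain_mask[pts[:, 0], pts[:, 1], pts[:, 2]]
    return pts[inside]


# ---------------------------------------------------------------------------
# searchlight engine
# ---------------------------------------------------------------------------

def _pair_block_indices(n_events: int, n_blocks: int, pairs: pd.DataFrame):
    """Flat indices into the (E*B, E*B) correlation matrix per pair.

    Returns an (n_pairs, n_blocks*(n_blocks-1)) array of flat positions
    covering the ordered cross-block comparisons of each unordered pair.
    """
    P = n_events * n_blocks
    a, b = np.meshgrid(np.arange(n_blocks), np.arange(n_blocks), indexing="ij")
    keep = a.ravel() != b.ravel()
    a, b = a.ravel()[keep], b.ravel()[keep]
    i = pairs["event_i"].to_numpy() - 1
    j = pairs["event_j"].to_numpy() - 1
    rows = i[:, None] * n_blocks + a[None, :]
    cols = j[:, None] * n_blocks + b[None, :]
    return rows * P + cols


def _model_matrices(pairs: pd.DataFrame):
    """Precompute the three searchlight model designs on the pair table.

    Predictor z-scoring follows the ROI convention: within the subset each
    model is fitted on (same rows, different rows, all rows).
    """
    same = pairs["same_sequence"].to_numpy()
    zvd_same = zscore(pairs.loc[same, "virtual_distance"])
    zvd_diff = zscore(pairs.loc[~same, "virtual_distance"])
    zvd_all = zscore(pairs["virtual_distance"])
    mem = np.where(same, 0.5, -0.5)  # deviation-coded membership

    models = []
    # (row-selector, design matrix, focal column)
    X_same = np.column_stack([np.ones(same.sum()), zvd_same])
    models.append(("same", same, X_same, 1))
    X_diff = np.column_stack([np.ones((~same).sum()), zvd_diff])
    models.append(("different", ~same, X_diff, 1))
    X_int = np.column_stack([np.ones(len(pairs)), zvd_all, mem, zvd_all * mem])
    models.append(("interaction", np.ones(len(pairs), bool), X_int, 3))

    prepared = []
    for name, sel, X, focal_col in models:
        xtx_inv = np.linalg.inv(X.T @ X)
        prepared.append({
            "name": name, "sel": sel, "X": X,
            "pinv": xtx_inv @ X.T,
            "inv_jj": xtx_inv[focal_col, focal_col],
            "focal": focal_col,
            "dof": X.shape[0] - X.shape[1],
        })
    return prepared


def run_searchlight(
    patterns_pre: np.ndarray,
    patterns_post: np.ndarray,
    grid: VolumeGrid,
    pairs: pd.DataFrame,
    radius: float = 3.0,
    min_gray_voxels: int = 25,
    chunk: int = 96,
) -> dict[str, np.ndarray]:
    """Per-subject searchlight t-maps for the three similarity-change models.

    ``patterns_pre``/``patterns_post`` have shape (E, B, X, Y, Z).  Centers
    are all brain-mask voxels; spheres not containing more than
    ``min_gray_voxels`` gray-matter voxels are discarded (NaN at those
    centers).
    """
    E, B = patterns_pre.shape[:2]
    if patterns_pre.shape != patterns_post.shape or patterns_pre.shape[2:] != tuple(grid.dims):
        raise DesignValidationError("pattern volumes misaligned with the grid")
    dims = tuple(grid.dims)
    centers = np.argwhere(grid.brain_mask)
    offsets = sphere_offsets(radius)
    gray_flat = grid.graymatter_mask.ravel()
    dims_arr = np.asarray(dims)

    # per-center sphere voxel lists (gray-matter filtered), padded
    pts = centers[:, None, :] + offsets[None, :, :]  # (nc, S, 3)
    inb = np.all((pts >= 0) & (pts < dims_arr[None, None, :]), axis=2)
    flat = (pts[..., 0] * dims[1] + pts[..., 1]) * dims[2] + pts[..., 2]
    flat = np.where(inb, flat, 0)
    valid = inb & gray_flat[flat]
    counts = valid.sum(axis=1)
    keep = counts > min_gray_voxels
    if not np.any(keep):
        raise DesignValidationError("no valid searchlight centers")
    centers, flat, valid, counts = centers[keep], flat[keep], valid[keep], counts[keep]

    data = np.concatenate([
        patterns_pre.reshape(E * B, -1), patterns_post.reshape(E * B, -1)
    ]).astype(np.float32)  # (P, nvox)

    pair_idx = _pair_block_indices(E, B, pairs).ravel()  # flat (npairs * ncross,)
    n_pairs = len(pairs)
    EB = E * B
    models = _model_matrices(pairs)
    maps = {m["name"]: np.full(dims, np.nan) for m in models}

    for start in range(0, len(centers), chunk):
        sl = slice(start, start + chunk)
        f, v, n = flat[sl], valid[sl], counts[sl]
        vf = v[None].astype(np.float32)
        G = data[:, f]                      # (P, c, S)
        G *= vf
        mean = G.sum(axis=2) / n[None]
        G -= mean[:, :, None]
        G *= vf
        ss = np.sqrt(np.einsum("pcs,pcs->pc", G, G))
        if np.any(ss == 0):
            raise DesignValidationError("zero-variance pattern vector in a search sphere")
        G /= ss[:, :, None]
        Gt = np.ascontiguousarray(G.transpose(1, 0, 2))  # (c, P, S)
        change = np.empty((len(n), n_pairs), dtype=np.float64)
        zsum = None
        for phase, sign in ((Gt[:, :EB], -1.0), (Gt[:, EB:], 1.0)):
            corr = phase @ phase.transpose(0, 2, 1)      # (c, EB, EB)
            picked = corr.reshape(len(n), -1)[:, pair_idx]
            z = np.arctanh(np.clip(picked, -1 + FISHER_CLIP, 1 - FISHER_CLIP))
            z = z.reshape(len(n), n_pairs, -1).mean(axis=2)
            zsum = sign * z if zsum is None else zsum + sign * z
        change[:] = zsum                                 # (c, npairs)
        for m in models:
            y = change[:, m["sel"]]                      # (c, rows)
            beta = y @ m["pinv"].T                       # (c, k)
            resid = y - beta @ m["X"].T
            sigma2 = (resid ** 2).sum(axis=1) / m["dof"]
            t = beta[:, m["focal"]] / np.sqrt(sigma2 * m["inv_jj"])
            cs = centers[sl]
            maps[m["name"]][cs[:, 0], cs[:, 1], cs[:, 2]] = t
    return maps


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def smooth_map(volume: np.ndarray, fwhm_mm: float, grid: VolumeGrid) -> np.ndarray:
    """NaN-aware Gaussian smoothing, sigma = FWHM / (2 sqrt(2 ln 2)) per axis."""
    if fwhm_mm <= 0:
        raise DesignValidationError("fwhm must be positive")
    sigma = [fwhm_mm * GAUSS_FWHM_TO_SIGMA / vs for vs in grid.voxel_size]
    valid = np.isfinite(volume)
    filled = np.where(valid, volume, 0.0)
    num = ndimage.gaussian_filter(filled, sigma)
    den = ndimage.gaussian_filter(valid.astype(float), sigma)
    out = np.full_like(num, np.nan)
    ok = den > 1e-12
    out[ok] = num[ok] / den[ok]
    out[~valid] = np.nan
    return out


# ---------------------------------------------------------------------------
# TFCE + group correction
# ---------------------------------------------------------------------------

def tfce(
    stat_map: np.ndarray,
    h: float = 2.0,
    e: float = 0.5,
    n_steps: int = 100,
    dh: float | None = None,
) -> np.ndarray:
    """Threshold-free cluster enhancement of the positive part of a map.

    TFCE(v) = sum over thresholds th of extent(v, th)^E * th^H * dh, with
    26-connectivity clusters; zero wherever the map is <= 0.  The step is
    dh = max/n_steps unless given explicitly.
    """
    m = np.nan_to_num(np.asarray(stat_map, float), nan=0.0)
    pos = np.clip(m, 0.0, None)
    top = pos.max()
    if top <= 0:
        return np.zeros_like(pos)
    step = top / n_steps if dh is None else dh
    out = np.zeros_like(pos)
    thresholds = np.arange(step, top + step / 2, step)
    for th in thresholds:
        mask = pos >= th
        labels, n = ndimage.label(mask, structure=_CONNECTIVITY_26)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())
        contrib = (sizes.astype(float) ** e) * (th ** h) * step
        contrib[0] = 0.0
        out += contrib[labels]
    return out


def group_map_test(
    maps: np.ndarray,
    svc_mask: np.ndarray,
    n_flips: int = 1000,
    seed: int | None = None,
    tfce_h: float = 2.0,
    tfce_e: float = 0.5,
    tfce_steps: int = 100,
) -> dict[str, np.ndarray]:
    """Sign-flip group test with small-volume TFCE correction.

    ``maps`` is (n_subjects, X, Y, Z) of per-subject statistics (NaN
    outside valid centers).  Within ``svc_mask``: voxelwise one-sample t
    over subjects, TFCE of the t-map, and a family-wise corrected p per
    voxel from the max-TFCE null over random sign-flips (add-one
    corrected).  A voxelwise uncorrected two-sided permutation p is also
    returned.  One-sided enhancement: TFCE boosts positive t only; negate
    the maps to test negative effects.
    """
    svc_mask = np.asarray(svc_mask, bool)
    if not svc_mask.any():
        raise DesignValidationError("empty small-volume-correction mask")
    maps = np.asarray(maps, float)
    n_sub = maps.shape[0]
    if n_sub < 8:
        raise DesignValidationError("need at least 8 subjects for the group test")
    dims = maps.shape[1:]

    valid = np.all(np.isfinite(maps), axis=0) & svc_mask
    vox = np.argwhere(valid)
    X = maps[:, valid]  # (n_sub, nvox)
    # everything tested lives inside the svc mask: crop the TFCE working
    # volume to its bounding box (connected components cannot cross it)
    lo = vox.min(axis=0)
    hi = vox.max(axis=0) + 1
    bbox = tuple(slice(a, b) for a, b in zip(lo, hi))
    valid_c = valid[bbox]

    def tmap_of(signed: np.ndarray) -> np.ndarray:
        mean = signed.mean(axis=0)
        sd = signed.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return mean / (sd / np.sqrt(n_sub))

    t_obs = tmap_of(X)
    t_vol = np.zeros(dims)
    t_vol[valid] = t_obs
    scratch = np.zeros(valid_c.shape)
    scratch[valid_c] = t_obs
    tfce_obs_c = tfce(scratch, h=tfce_h, e=tfce_e, n_steps=tfce_steps)
    tfce_obs_vol = np.zeros(dims)
    tfce_obs_vol[bbox] = tfce_obs_c
    tfce_obs = tfce_obs_vol[valid]

    rng = np.random.default_rng(seed)
    max_null = np.empty(n_flips)
    exceed_uncorr = np.zeros(X.shape[1])
    for i in range(n_flips):
        signs = rng.integers(0, 2, size=(n_sub, 1)) * 2.0 - 1.0
        t_null = tmap_of(signs * X)
        exceed_uncorr += np.abs(t_null) >= np.abs(t_obs)
        scratch[:] = 0.0
        scratch[valid_c] = t_null
        max_null[i] = tfce(scratch, h=tfce_h, e=tfce_e,
                           n_steps=tfce_steps)[valid_c].max()
    p_corr = (1.0 + (max_null[None, :] >= tfce_obs[:, None]).sum(axis=1)) / (1.0 + n_flips)
    p_uncorr = (1.0 + exceed_uncorr) / (1.0 + n_flips)

    p_corr_vol = np.full(dims, np.nan)
    p_corr_vol[valid] = p_corr
    p_uncorr_vol = np.full(dims, np.nan)
    p_uncorr_vol[valid] = p_uncorr
    sig = p_corr < 0.05
    sig_peak = tuple(vox[np.argmax(np.where(sig, t_obs, -np.inf))]) if sig.any() else None
    return {
        "t": np.where(valid, t_vol, np.nan),
        "tfce": np.where(valid, tfce_obs_vol, np.nan),
        "p_corrected": p_corr_vol,
        "p_uncorrected": p_uncorr_vol,
        "valid": valid,
        "max_null": max_null,
        # the enhancement is one-sided (positive), so peaks refer to the
        # maximum-t voxel of the tested contrast; sig_peak restricts to
        # voxels surviving the small-volume correction
        "peak": tuple(vox[np.argmax(t_obs)]) if len(vox) else None,
        "sig_peak": sig_peak,
    }


def peak_roi_from_cluster(
    t_map: np.ndarray,
    p_map: np.ndarray,
    threshold_p: float,
    svc_mask: np.ndarray,
) -> np.ndarray:
    """ROI = 26-connected suprathreshold component containing the peak voxel.

    The (uncorrected) p-volume is thresholded at ``threshold_p`` within the
    small-volume mask; the component containing the peak |t| voxel is
    returned as a boolean volume (all-False when nothing survives).
    """
    svc_mask = np.asarray(svc_mask, bool)
    supra = np.asarray(p_map < threshold_p) & svc_mask & np.isfinite(t_map)
    if not supra.any():
        return np.zeros_like(svc_mask)
    labels, _ = ndimage.label(supra, structure=_CONNECTIVITY_26)
    t_abs = np.where(supra, np.abs(t_map), -np.inf)
    peak = np.unravel_index(np.argmax(t_abs), t_map.shape)
    return labels == labels[peak]
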