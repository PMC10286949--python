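"""Searchlight geometry, time-resolved SVR decoding, smoothing, clusters.

A searchlight is the set of voxels within a Euclidean radius of a
gray-matter center (radius 3 voxels holds at most 123 voxels); CSF and
white-matter members are excluded.  A latent variable is decoded per
searchlight and within-trial frame with a linear support-vector regression
(regularization constant 1), features and target z-scored on the training
folds of a leave-one-run-out cross-validation.  Decoded per-trial maps are
smoothed with a 5 mm FWHM Gaussian; passing centers are grouped into
face-adjacent clusters with a minimum-size rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.svm import SVR

from .synth import VolumeSeries

__all__ = [
    "ball_offsets",
    "build_searchlights",
    "decode_searchlight",
    "decode_variable",
    "smooth_maps",
    "cluster_select",
]

GRAY = 1


def ball_offsets(radius: int) -> np.ndarray:
    """Integer offsets with squared norm <= radius**2 (lattice ball)."""
    r = int(radius)
    grid = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1].reshape(3, -1).T
    return grid[(grid**2).sum(axis=1) <= r * r]


def build_searchlights(
    tissue: np.ndarray, radius_vox: int = 3
) -> dict[tuple[int, int, int], np.ndarray]:
    """Member-voxel lists for every gray-matter center.

    Members are voxels within the radius that are inside the grid and not
    CSF/white matter.  Returns ``{center: (n_members, 3) index array}``.
    """
    tissue = np.asarray(tissue)
    centers = np.argwhere(tissue == GRAY)
    if centers.size == 0:
        raise ValueError("no gray-matter voxels in the grid")
    offs = ball_offsets(radius_vox)
    shape = np.array(tissue.shape)
    out = {}
    for c in centers:
        pts = c + offs
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        pts = pts[ok]
        pts = pts[tissue[pts[:, 0], pts[:, 1], pts[:, 2]] == GRAY]
        out[tuple(int(v) for v in c)] = pts
    return out


def _loro_svr(X: np.ndarray, y: np.ndarray, runs: np.ndarray) -> np.ndarray:
    """Leave-one-run-out linear-SVR predictions with per-fold z-scoring."""
    pred = np.empty_like(y, dtype=float)
    for run in np.unique(runs):
        test = runs == run
        train = ~test
        Xtr = X[train]
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        keep = sd > 0
        if not keep.any():
            pred[test] = 0.0
            continue
        if not keep.all():
            import warnings

            warnings.warn("constant feature column dropped in a training fold")
        ym, ys = y[train].mean(), y[train].std()
        svr = SVR(kernel="linear", C=1.0, epsilon=0.1)
        svr.fit((Xtr[:, keep] - mu[keep]) / sd[keep], (y[train] - ym) / ys)
        pred[test] = svr.predict((X[test][:, keep] - mu[keep]) / sd[keep])
    return pred


def decode_searchlight(
    series: VolumeSeries,
    members: np.ndarray,
    target: np.ndarray,
    frame: int,
) -> np.ndarray:
    """Decoded per-trial values of ``target`` from one searchlight at ``frame``."""
    if len(np.unique(series.run_ids)) < 2:
        raise ValueError("need at least 2 runs for leave-one-run-out CV")
    target = np.asarray(target, dtype=float)
    if target.std() == 0:
        raise ValueError("decoding target has zero variance")
    X = series.data[members[:, 0], members[:, 1], members[:, 2], :, frame].T
    return _loro_svr(X, target, series.run_ids)


def decode_variable(
    series: VolumeSeries,
    target: np.ndarray,
    searchlights: dict[tuple[int, int, int], np.ndarray],
    frame: int,
    smooth_fwhm_mm: float = 5.0,
) -> dict[str, np.ndarray]:
    """Decode a latent over a set of searchlights and smooth the trial maps.

    Returns ``maps`` of shape (nx, ny, nz, n_trials) (NaN off-center) plus the
    center mask.  Smoothing uses a unit-sum Gaussian kernel with reflective
    borders on each per-trial 3D map, restricted to the decoded support.
    """
    shape = series.tissue.shape
    maps = np.full(shape + (series.n_trials,), np.nan)
    for center, members in searchlights.items():
        maps[center] = decode_searchlight(series, members, target, frame)
    smoothed = smooth_maps(maps, smooth_fwhm_mm, series.voxel_size_mm)
    return {"maps": smoothed, "raw_maps": maps}


def smooth_maps(
    maps: np.ndarray, fwhm_mm: float, voxel_size_mm: float
) -> np.ndarray:
    """Gaussian smoothing of each per-trial 3D map on its NaN support.

    Mass is renormalised by the smoothed support so values are not diluted at
    the support edge; a full support reduces to plain reflective-border
    Gaussian filtering, which preserves the map mean.
    """
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    support = np.isfinite(maps[..., 0])
    out = np.full_like(maps, np.nan)
    if support.all():
        for t in range(maps.shape[-1]):
            out[..., t] = ndimage.gaussian_filter(maps[..., t], sigma, mode="reflect")
        return out
    m = support.astype(float)
    sm_mask = ndimage.gaussian_filter(m, sigma, mode="reflect")
    for t in range(maps.shape[-1]):
        filled = np.where(support, maps[..., t], 0.0)
        sm = ndimage.gaussian_filter(filled, sigma, mode="reflect")
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = sm / sm_mask
        out[..., t] = np.where(support, vals, np.nan)
    return out


def cluster_select(
    pass_map: np.ndarray, min_size: int = 12
) -> list[np.ndarray]:
    """Face-adjacent (6-connectivity) clusters of passing centers, >= min_size.

    Returns a list of (n, 3) index arrays, one per retained cluster.
    """
    structure = ndimage.generate_binary_structure(3, 1)
    labels, n = ndimage.label(np.asarray(pass_map, dtype=bool), structure=structure)
    clusters = []
    for k in range(1, n + 1):
        idx = np.argwhere(labels == k)
        if len(idx) >= min_size:
            clusters.append(idx)
    return clusters
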