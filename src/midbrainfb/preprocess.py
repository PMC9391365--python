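"""Analysis-side preprocessing: weighted ROI extraction and PCA nuisance.

Spatial preprocessing (despiking, slice timing, normalization, smoothing) is
out of scope — synthetic data are generated in "preprocessed" space.  What
remains analysis-relevant is (i) probability-weighted averaging of voxel
series into a region series and (ii) the physiological-noise model: the
global mean plus the first six temporal principal components of the pooled
CSF/white-matter voxel signal, used as first-level nuisance regressors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

N_PCA_COMPONENTS = 6
N_MOTION = 6
N_INITIAL_VOLUMES = 5  # first TRs of every run modelled as a nuisance


class PreprocessError(ValueError):
    pass


class DegenerateComponentsWarning(UserWarning):
    """Fewer informative PCA components than requested."""


@dataclass
class NuisanceSet:
    """First-level nuisance regressors for one run.

    pca_components: (k, T) orthonormal temporal components (unit norm,
    mutually orthogonal, largest-magnitude loading positive).
    """

    global_mean: np.ndarray
    pca_components: np.ndarray
    motion: np.ndarray
    initial_volumes: np.ndarray
    explained_variance: np.ndarray

    @property
    def n_volumes(self) -> int:
        return self.global_mean.size

    def frame(self) -> pd.DataFrame:
        cols = {"global_mean": self.global_mean,
                "initial_volumes": self.initial_volumes}
        for i, comp in enumerate(self.pca_components, start=1):
            cols[f"pca_{i}"] = comp
        for i, m in enumerate(self.motion):
            cols[f"motion_{i}"] = m
        return pd.DataFrame(cols)


def extract_roi(voxel_series: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Probability-weighted average of voxel series into one region series.

    voxel_series is (voxels, time); weights are non-negative per-voxel mask
    probabilities, normalized internally to sum to one.
    """
    x = np.asarray(voxel_series, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.ndim != 2:
        raise PreprocessError("voxel_series must be a (voxels, time) matrix")
    if w.shape != (x.shape[0],):
        raise PreprocessError("one weight per voxel required")
    if np.any(w < 0):
        raise PreprocessError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise PreprocessError("at least one positive weight required")
    return (w / total) @ x


def pca_nuisance(csf_wm: np.ndarray, k: int = N_PCA_COMPONENTS, *,
                 motion: np.ndarray | None = None,
                 n_initial: int = N_INITIAL_VOLUMES) -> NuisanceSet:
    """Global mean + first ``k`` temporal principal components of the pooled
    CSF/WM voxel matrix.

    Components are computed on temporally centered voxel series, ordered by
    explained variance, unit-normalized, with each component's
    largest-magnitude loading made positive for a reproducible orientation.
    The global mean is the uncentered across-voxel mean series.
    """
    x = np.asarray(csf_wm, dtype=float)
    if x.ndim != 2:
        raise PreprocessError("csf_wm must be a (voxels, time) matrix")
    n_vox, n_time = x.shape
    if n_vox < k:
        raise PreprocessError(f"need at least {k} voxels")
    if n_time <= k:
        raise PreprocessError(f"need more than {k} time points")
    centered = x - x.mean(axis=1, keepdims=True)
    # temporal PCA: right singular vectors are the component time series
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s ** 2
    informative = int(np.sum(s > s[0] * 1e-10)) if s.size and s[0] > 0 else 0
    if informative < k:
        warnings.warn(
            f"only {informative} informative components (requested {k})",
            DegenerateComponentsWarning, stacklevel=2)
    comps = vt[:k].copy()
    for row in comps:
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            row *= -1.0
    if motion is None:
        motion = np.zeros((N_MOTION, n_time))
    motion = np.asarray(motion, dtype=float)
    if motion.shape != (N_MOTION, n_time):
        raise PreprocessError(f"motion must be ({N_MOTION}, {n_time})")
    initial = np.zeros(n_time)
    initial[:n_initial] = 1.0
    return NuisanceSet(global_mean=x.mean(axis=0), pca_components=comps,
                       motion=motion, initial_volumes=initial,
                       explained_variance=var[:k] / var.sum())


def nuisance_for_run(dataset, run_type: str) -> NuisanceSet:
    """Build the NuisanceSet for one run of a simulated subject dataset."""
    motion = dataset.motion[run_type].to_numpy(float).T
    return pca_nuisance(dataset.csf_wm[run_type], motion=motion)


def load_voxels_nifti(image_path, mask_path=None):
    """Load a 4D NIfTI into a (voxels, time) matrix.

    With a mask image, only voxels with positive mask value are kept and the
    mask values are returned as extraction weights; otherwise all voxels are
    kept with unit weights.
    """
    import nibabel as nib

    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise PreprocessError("expected a 4D NIfTI image")
    flat = data.reshape(-1, data.shape[-1])
    if mask_path is None:
        return flat, np.ones(flat.shape[0])
    mask = np.asarray(nib.load(str(mask_path)).dataobj, dtype=float).reshape(-1)
    if mask.shape[0] != flat.shape[0]:
        raise PreprocessError("mask and image grids differ")
    keep = mask > 0
    return flat[keep], mask[keep]
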