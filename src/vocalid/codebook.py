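"""Unsupervised spherical k-means feature learning on spectrogram patches.

Short multi-frame windows ("patches") of the noise-reduced mel spectrogram are
mean-centred, PCA-whitened and clustered on the unit sphere by dot-product
similarity.  The resulting centroid matrix defines a linear projection of
whitened patch space: re-representing a spectrogram as its per-patch centroid
responses captures fine temporal structure (frequency-modulation shapes spread
over a few frames) that raw band energies miss.  The codebook is learned from
training data only, ignoring labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import MelSpectrogram

logger = logging.getLogger(__name__)

DEFAULT_K = 256
DEFAULT_PATCH_WIDTH = 4
WHITEN_EPS = 1e-8
MAX_ITER = 100
REL_TOL = 1e-6

_FORMAT_VERSION = 1


@dataclass
class Codebook:
    """Learned patch projection: whitening transform plus unit-norm centroids."""

    centroids: np.ndarray  # (k, w*B), rows unit norm
    mean: np.ndarray  # (w*B,) patch mean prior to whitening
    whiten: np.ndarray  # (w*B, w*B) whitening matrix (applied on the right as x @ W.T)
    patch_width: int
    seed: int
    # summed-similarity objective per iteration, for convergence diagnostics
    objective_history: list = field(default_factory=list, repr=False)

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @property
    def patch_dim(self) -> int:
        return self.centroids.shape[1]

    def save(self, path: str | Path) -> Path:
        np.savez(
            path,
            version=np.array([_FORMAT_VERSION]),
            centroids=self.centroids,
            mean=self.mean,
            whiten=self.whiten,
            patch_width=np.array([self.patch_width]),
            seed=np.array([self.seed]),
        )
        return Path(path)

    @classmethod
    def load(cls, path: str | Path) -> "Codebook":
        with np.load(path) as z:
            if int(z["version"][0]) != _FORMAT_VERSION:
                raise ValueError(f"unsupported codebook version {z['version'][0]}")
            return cls(
                centroids=z["centroids"],
                mean=z["mean"],
                whiten=z["whiten"],
                patch_width=int(z["patch_width"][0]),
                seed=int(z["seed"][0]),
            )


def extract_patches(spec: MelSpectrogram, w: int = DEFAULT_PATCH_WIDTH) -> np.ndarray:
    """All T-w+1 overlapping w-frame windows, flattened band-major.

    Returns an array of shape (T-w+1, w*B); empty (0, w*B) when the
    spectrogram is shorter than one patch.
    """
    T, B = spec.values.shape
    if T < w:
        logger.info("spectrogram with %d frames shorter than patch width %d", T, w)
        return np.empty((0, w * B))
    from numpy.lib.stride_tricks import sliding_window_view

    windows = sliding_window_view(spec.values, (w, B))[:, 0]  # (T-w+1, w, B)
    return windows.transpose(0, 2, 1).reshape(T - w + 1, w * B)  # band-major


def _whiten_fit(patches: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = patches.mean(axis=0)
    X = patches - mean
    cov = (X.T @ X) / X.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    W = (evecs / np.sqrt(evals + WHITEN_EPS)) @ evecs.T  # ZCA: symmetric, invertible
    return mean, W


def _unit_rows(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return X / norms


def learn_codebook(
    training_specs: list[MelSpectrogram],
    k: int = DEFAULT_K,
    w: int = DEFAULT_PATCH_WIDTH,
    seed: int = 0,
    max_patches: int | None = 100_000,
) -> Codebook:
    """Fit whitening and spherical k-means centroids on training spectrograms.

    Patches are mean-centred, PCA-whitened (eigenvalue regularization 1e-8)
    and normalized to the unit sphere.  Assignment maximizes the dot product;
    each centroid update is the renormalized mean of its assigned patches,
    with empty clusters reseeded from a random patch.  Iteration stops at
    convergence of the summed similarity objective (relative change < 1e-6)
    or after 100 rounds.  ``max_patches`` caps the patch sample for speed;
    the subsample is drawn under ``seed``.
    """
    rng = np.random.default_rng(seed)
    pools = [extract_patches(s, w) for s in training_specs]
    patches = np.vstack([p for p in pools if p.size]) if pools else np.empty((0, 0))
    if patches.shape[0] < k:
        raise ValueError(
            f"only {patches.shape[0]} patches available for k={k}; use a smaller k"
        )
    if max_patches is not None and patches.shape[0] > max_patches:
        idx = rng.choice(patches.shape[0], size=max_patches, replace=False)
        patches = patches[idx]

    mean, W = _whiten_fit(patches)
    Xw = _unit_rows((patches - mean) @ W.T)

    init_idx = rng.choice(Xw.shape[0], size=k, replace=False)
    centroids = _unit_rows(Xw[init_idx].copy())

    history: list[float] = []
    prev_obj = -np.inf
    for _ in range(MAX_ITER):
        sims = Xw @ centroids.T
        assign = sims.argmax(axis=1)
        obj = float(sims[np.arange(Xw.shape[0]), assign].sum())
        history.append(obj)
        if prev_obj > -np.inf and abs(obj - prev_obj) <= REL_TOL * abs(prev_obj):
            break
        prev_obj = obj
        for j in range(k):
            members = Xw[assign == j]
            if members.shape[0] == 0:
                centroids[j] = Xw[int(rng.integers(Xw.shape[0]))]
            else:
                centroids[j] = members.mean(axis=0)
        centroids = _unit_rows(centroids)

    return Codebook(
        centroids=centroids,
        mean=mean,
        whiten=W,
        patch_width=w,
        seed=seed,
        objective_history=history,
    )


def project_spectrogram(
    spec: MelSpectrogram, cb: Codebook, rectify: bool = False
) -> np.ndarray:
    """Centroid responses of every patch: a (T-w+1) x k matrix.

    Each patch is centred, whitened with the stored transform, and mapped to
    its k dot products with the centroids — a linear map on whitened patch
    space.  ``rectify`` half-wave rectifies the responses (some codebook
    feature pipelines use the rectified variant).
    """
    patches = extract_patches(spec, cb.patch_width)
    if patches.shape[1] != cb.patch_dim:
        raise ValueError(
            f"patch dimension {patches.shape[1]} does not match codebook "
            f"dimension {cb.patch_dim}"
        )
    proj = ((patches - cb.mean) @ cb.whiten.T) @ cb.centroids.T
    if rectify:
        proj = np.maximum(proj, 0.0)
    return proj
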