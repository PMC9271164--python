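"""Candidate models of face dissimilarity.

Every candidate model is a (representation, projection, metric) recipe that
maps a face pair to one predicted dissimilarity.  Latent-space models operate
directly on the face-space coordinates, optionally after a projection: the
full-space Euclidean model, the cosine ("angle about the average face")
model, shape-only / texture-only subspaces, leading-principal-component
subsets, and a 4-D person-attribute projection.  Feature-space models first
map each face to a derived representation — a 3-D mesh, keypoint landmarks
and their configural statistics, or a rendered image with an optional
Eigenface (PCA) basis — and take Euclidean distances there.

All models are symmetric in pair order and return zero for identical faces.
Cosine distance is undefined when a (projected) face vector is zero; such
pairs are flagged with NaN in the returned distance vector so downstream
statistics can exclude them explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .facespace import FacePairStimulus, cosine_distance, euclidean_distance

__all__ = [
    "CandidateModel",
    "EigenfaceSpace",
    "latent_model_predict",
    "person_attribute_projection",
    "configural_features",
    "mesh_model_predict",
    "pixel_model_predict",
    "eigenface_fit",
    "eigenface_predict",
    "default_latent_zoo",
    "predict_zoo",
]


@dataclass
class CandidateModel:
    """A named dissimilarity recipe.

    ``source`` is one of {"latent", "mesh", "landmarks", "image"};
    ``projection`` is None (identity), a 1-D integer index array (coordinate
    subset), or a 2-D (q, D) matrix whose unit-normalized rows are projection
    directions; ``metric`` is "euclidean" or "cosine".  For non-latent
    sources an ``order`` field selects the configural statistic.
    """

    name: str
    source: str = "latent"
    metric: str = "euclidean"
    projection: np.ndarray | None = None
    order: int | None = None

    def project(self, coords: np.ndarray) -> np.ndarray:
        if self.projection is None:
            return coords
        p = np.asarray(self.projection)
        if p.ndim == 1:
            return coords[p.astype(int)]
        dirs = p / np.linalg.norm(p, axis=1, keepdims=True)
        return dirs @ coords


def _metric(metric: str, x: np.ndarray, y: np.ndarray, on_zero: str) -> float:
    if metric == "euclidean":
        return float(np.linalg.norm(x - y))
    if metric == "cosine":
        if np.linalg.norm(x) == 0.0 or np.linalg.norm(y) == 0.0:
            if on_zero == "nan":
                return float("nan")
            raise ValueError("cosine distance undefined for a zero vector")
        return cosine_distance(x, y)
    raise ValueError(f"unknown metric {metric!r}")


def latent_model_predict(
    model: CandidateModel,
    stimuli: Sequence[FacePairStimulus],
    on_zero: str = "nan",
) -> pd.Series:
    """Predicted dissimilarity per pair for a latent-space model.

    Pairs whose (projected) vectors make the cosine metric undefined are
    flagged with NaN when ``on_zero='nan'`` (the default), or raise when
    ``on_zero='raise'``.
    """
    if model.source != "latent":
        raise ValueError("latent_model_predict requires a latent-source model")
    vals, ids = [], []
    for s in stimuli:
        x = model.project(s.v1.coords)
        y = model.project(s.v2.coords)
        vals.append(_metric(model.metric, x, y, on_zero))
        ids.append(s.pair_id)
    return pd.Series(vals, index=pd.Index(ids, name="pair_id"), name=model.name)


def person_attribute_projection(latents, attribute_directions) -> np.ndarray:
    """Project latent vectors onto unit-normalized person-attribute axes.

    The four directions stand for the face-space axes capturing most
    variance in height, weight, age, and gender; they must be linearly
    independent.  Returns the (n, 4) coordinate array of inner products.
    """
    dirs = np.asarray(attribute_directions, dtype=float)
    if dirs.ndim != 2:
        raise ValueError("attribute_directions must be a 2-D array")
    if np.linalg.matrix_rank(dirs) < dirs.shape[0]:
        raise ValueError("attribute directions are rank deficient")
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    x = np.atleast_2d(np.asarray(latents, dtype=float))
    out = x @ dirs.T
    return out[0] if np.asarray(latents).ndim == 1 else out


def configural_features(landmarks: np.ndarray, order: int) -> np.ndarray:
    """Configural description of a face's keypoint arrangement.

    order 0: the raw 3N keypoint coordinates; order 1: the N(N-1)/2 pairwise
    Euclidean distances between keypoints; order 2: those distances divided
    by their geometric mean — dimensionless ratios invariant to uniform
    scaling as well as to the rigid motions that already leave order 1
    invariant.
    """
    lm = np.asarray(landmarks, dtype=float)
    if lm.ndim != 2 or lm.shape[0] < 3:
        raise ValueError("landmarks must be an (N >= 3, 3) array")
    if not np.all(np.isfinite(lm)):
        raise ValueError("landmarks must be finite")
    if order == 0:
        return lm.ravel().copy()
    d = pdist(lm)
    if order == 1:
        return d
    if order == 2:
        if np.any(d == 0):
            raise ValueError("coincident landmarks: distance ratios undefined")
        return d / np.exp(np.mean(np.log(d)))
    raise ValueError("order must be 0, 1 or 2")


def mesh_model_predict(mesh1, mesh2) -> float:
    """Euclidean distance between flattened 3-D mesh coordinate arrays."""
    a, b = np.asarray(mesh1, dtype=float), np.asarray(mesh2, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"mesh shape mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a.ravel() - b.ravel()))


def pixel_model_predict(img1, img2) -> float:
    """Euclidean distance between flattened image arrays."""
    a, b = np.asarray(img1, dtype=float), np.asarray(img2, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image shape mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a.ravel() - b.ravel()))


@dataclass
class EigenfaceSpace:
    """A mean image plus an orthonormal PCA basis with component variances."""

    mean: np.ndarray
    components: np.ndarray  # (k, d), orthonormal rows
    variances: np.ndarray  # (k,), descending

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def transform(self, imgs: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(imgs, dtype=float))
        w = (x - self.mean) @ self.components.T
        return w[0] if np.asarray(imgs).ndim == 1 else w


def eigenface_fit(training_images, var_tol: float = 1e-10) -> EigenfaceSpace:
    """Mean-centered PCA of a training image set, keeping every component
    with nonzero variance.

    Components are "nonzero" when their variance exceeds ``var_tol`` times
    the leading variance; n mean-centered samples give at most n-1 such
    components.  When the image dimension exceeds the sample count the
    decomposition runs through the n x n Gram matrix, which is much cheaper
    than a direct SVD of the wide data matrix.
    """
    X = np.asarray(training_images, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 training images")
    n, d = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    if d > n:
        G = Xc @ Xc.T
        w, U = np.linalg.eigh(G)
        order = np.argsort(w)[::-1]
        w, U = np.clip(w[order], 0.0, None), U[:, order]
        keep = w > var_tol * w[0]
        comps = (Xc.T @ U[:, keep]) / np.sqrt(w[keep])
        components = comps.T
        variances = w[keep] / (n - 1)
    else:
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        w = s**2
        keep = w > var_tol * (w[0] if w.size else 1.0)
        components = Vt[keep]
        variances = w[keep] / (n - 1)
    return EigenfaceSpace(mean=mean, components=components, variances=variances)


def eigenface_predict(space: EigenfaceSpace, img1, img2) -> float:
    """Euclidean distance between PCA weight vectors of two images."""
    a = np.asarray(img1, dtype=float).ravel()
    b = np.asarray(img2, dtype=float).ravel()
    if a.size != space.mean.size or b.size != space.mean.size:
        raise ValueError("image dimension does not match the Eigenface space")
    return float(np.linalg.norm(space.transform(a) - space.transform(b)))


# ---------------------------------------------------------------------------
# Zoo assembly


def default_latent_zoo(
    dim: int,
    top_k: int = 50,
    attribute_directions: np.ndarray | None = None,
    seed=None,
) -> list[CandidateModel]:
    """The latent-space members of the model zoo for a given dimension.

    If no person-attribute directions are supplied, four reproducible random
    directions are drawn from ``seed`` as synthetic stand-ins for the
    height/weight/age/gender axes.
    """
    half = dim // 2
    if attribute_directions is None:
        rng = np.random.default_rng(0 if seed is None else seed)
        attribute_directions = rng.standard_normal((4, dim))
    models = [
        CandidateModel("bfm_euclidean", "latent", "euclidean"),
        CandidateModel("bfm_angle", "latent", "cosine"),
        CandidateModel("bfm_shape", "latent", "euclidean", projection=np.arange(half)),
        CandidateModel("bfm_texture", "latent", "euclidean", projection=np.arange(half, dim)),
        CandidateModel(
            "bfm_attributes", "latent", "euclidean", projection=np.asarray(attribute_directions)
        ),
        CandidateModel(
            f"bfm_top{top_k}", "latent", "euclidean", projection=np.arange(min(top_k, dim))
        ),
    ]
    return models


def predict_zoo(
    stimuli: Sequence[FacePairStimulus],
    gen_map=None,
    eigen_space: EigenfaceSpace | None = None,
    latent_models: Sequence[CandidateModel] | None = None,
    include_feature_models: bool = True,
) -> pd.DataFrame:
    """Predicted distances for the full zoo, one column per model.

    ``gen_map`` supplies the synthetic rendering pipeline (``mesh``,
    ``landmarks`` and ``image`` callables on latent coordinates) required by
    the feature-space models; when it is None only latent models run.
    """
    if not stimuli:
        raise ValueError("no stimuli supplied")
    dim = stimuli[0].v1.dim
    if latent_models is None:
        latent_models = default_latent_zoo(dim)
    cols = {m.name: latent_model_predict(m, stimuli) for m in latent_models}

    if include_feature_models and gen_map is not None:
        ids = [s.pair_id for s in stimuli]
        mesh1 = [gen_map.mesh(s.v1.coords) for s in stimuli]
        mesh2 = [gen_map.mesh(s.v2.coords) for s in stimuli]
        img1 = [gen_map.image(s.v1.coords) for s in stimuli]
        img2 = [gen_map.image(s.v2.coords) for s in stimuli]
        lm1 = [gen_map.landmarks(s.v1.coords) for s in stimuli]
        lm2 = [gen_map.landmarks(s.v2.coords) for s in stimuli]
        idx = pd.Index(ids, name="pair_id")
        cols["mesh"] = pd.Series(
            [mesh_model_predict(a, b) for a, b in zip(mesh1, mesh2)], index=idx
        )
        cols["pixel"] = pd.Series(
            [pixel_model_predict(a, b) for a, b in zip(img1, img2)], index=idx
        )
        if eigen_space is not None:
            cols["eigenfaces"] = pd.Series(
                [eigenface_predict(eigen_space, a, b) for a, b in zip(img1, img2)], index=idx
            )
        for order in (0, 1, 2):
            cols[f"configural_{order}"] = pd.Series(
                [
                    float(
                        np.linalg.norm(
                            configural_features(a, order) - configural_features(b, order)
                        )
                    )
                    for a, b in zip(lm1, lm2)
                ],
                index=idx,
            )
    out = pd.DataFrame(cols)
    out.index.name = "pair_id"
    return out
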