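"""Quantified transition pathways in observable space.

The evolution of a chromosome-scale observable profile (insulation scores,
or the flattened upper triangle of the enhanced-contact map) is embedded by
PCA: the model is fitted on a chosen set of profiles, every time point of a
transition is projected onto the first two components, and the simulated
pathway is compared against the null pathway obtained by linearly
interpolating the contact maps of the two endpoint stages and passing each
interpolate through the same observable.  A deviation score of 0 means the
simulation relaxes along the interpolation; large values flag nonlinear
reorganization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .contact_maps import ContactMap, enhanced_contacts, insulation_profile

__all__ = [
    "ProfileSeries",
    "ProfilePCA",
    "PathwayProjection",
    "fit_profile_pca",
    "project_series",
    "linear_interpolation_path",
    "path_deviation",
    "insulation_observable",
    "enhanced_observable",
]


@dataclass
class ProfileSeries:
    """Time-ordered observable profiles with a shared feature mask."""

    times: np.ndarray        # tau, or interpolation fractions
    profiles: np.ndarray     # (T, F), NaN where undefined
    maps: list | None = None  # interpolated ContactMaps, when derived from them

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.ndim != 2 or self.profiles.shape[0] != self.times.size:
            raise ValueError("need one profile per time point")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")


@dataclass
class ProfilePCA:
    """Mean + top-2 orthonormal axes over the defined feature subspace."""

    mean: np.ndarray
    components: np.ndarray           # (2, F_kept)
    explained_variance_ratio: np.ndarray
    feature_indices: np.ndarray      # columns of the full profile kept
    fitting_set_size: int


@dataclass
class PathwayProjection:
    """Per-time (PC1, PC2) coordinates of a profile series."""

    times: np.ndarray
    coords: np.ndarray               # (T, 2)
    explained_variance_ratio: np.ndarray
    provenance: str = ""


def _valid_features(profiles: np.ndarray) -> np.ndarray:
    """Features finite in every profile; masked features are dropped, not imputed."""
    return np.flatnonzero(np.all(np.isfinite(profiles), axis=0))


def fit_profile_pca(fitting_set, n_components: int = 2) -> ProfilePCA:
    """Mean-centred PCA of a set of observable profiles.

    Features undefined in any fitting profile are excluded globally.  The
    sign of each axis is fixed deterministically: the largest-magnitude
    loading is positive.  Rank below ``n_components`` is an error.
    """
    X_full = np.asarray(list(fitting_set), dtype=float)
    if X_full.ndim != 2 or X_full.shape[0] < 3:
        raise ValueError("need at least 3 profiles to fit")
    keep = _valid_features(X_full)
    if keep.size < n_components:
        raise ValueError("not enough defined features")
    X = X_full[:, keep]
    pca = PCA(n_components=n_components)
    pca.fit(X)
    if pca.explained_variance_[0] <= 1e-24:
        raise ValueError("fitting set has no variance; PCA axes undefined")
    components = pca.components_.copy()
    for k in range(components.shape[0]):
        if components[k, np.argmax(np.abs(components[k]))] < 0:
            components[k] = -components[k]
    return ProfilePCA(pca.mean_, components, pca.explained_variance_ratio_,
                      keep, X.shape[0])


def project_series(model: ProfilePCA, series: ProfileSeries,
                   provenance: str = "") -> PathwayProjection:
    """Project every time point of a series onto the fitted axes."""
    X = series.profiles
    if X.shape[1] <= model.feature_indices.max():
        raise ValueError(
            f"profile length {X.shape[1]} does not cover the model's features"
        )
    Xk = X[:, model.feature_indices]
    if np.any(~np.isfinite(Xk)):
        raise ValueError("series has undefined values on the model's features")
    coords = (Xk - model.mean) @ model.components.T
    return PathwayProjection(series.times, coords,
                             model.explained_variance_ratio, provenance)


def insulation_observable(window_kb: float = 500.0):
    """Observable: per-locus insulation profile (NaN on masked loci)."""
    def _obs(cmap: ContactMap) -> np.ndarray:
        return insulation_profile(cmap, window_kb).scores
    return _obs


def enhanced_observable(coarse_resolution_kb: float = 1000.0):
    """Observable: flattened upper triangle of the enhanced-contact map."""
    def _obs(cmap: ContactMap) -> np.ndarray:
        emap = enhanced_contacts(cmap, coarse_resolution_kb)
        iu = np.triu_indices(emap.n_bins)
        return emap.matrix[iu]
    return _obs


def linear_interpolation_path(map_A: ContactMap, map_B: ContactMap,
                              n_steps: int, observable) -> ProfileSeries:
    """Observable profiles along the straight line between two contact maps.

    P(s) = (1 - s) P_A + s P_B at ``n_steps`` evenly spaced s in [0, 1]; the
    endpoints reproduce the inputs bit-exactly and the unit adjacent band is
    closed under the convex combination.  Each interpolate is passed through
    the same ``observable`` used for the simulated series.
    """
    if map_A.region != map_B.region:
        raise ValueError("endpoint maps cover different regions")
    if n_steps < 2:
        raise ValueError("need at least 2 interpolation steps")
    s_values = np.linspace(0.0, 1.0, n_steps)
    maps, profiles = [], []
    for s in s_values:
        P = (1.0 - s) * map_A.P + s * map_B.P
        cmap = ContactMap(map_A.region, P)
        maps.append(cmap)
        profiles.append(observable(cmap))
    return ProfileSeries(s_values, np.asarray(profiles), maps=maps)


def path_deviation(simulated: PathwayProjection,
                   interpolated: PathwayProjection) -> float:
    """Mean distance from the simulated path to the interpolated polyline.

    Averaged over simulated time points and normalized by the separation of
    the interpolated path's endpoints, so the score is invariant under
    rotation and uniform scaling of the PC plane.
    """
    poly = interpolated.coords
    L = float(np.linalg.norm(poly[-1] - poly[0]))
    if L < 1e-12:
        raise ValueError("interpolated path endpoints coincide; score undefined")
    dists = [min(_point_segment_distance(p, poly[k], poly[k + 1])
                 for k in range(len(poly) - 1))
             for p in simulated.coords]
    return float(np.mean(dists)) / L


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-24:
        return float(np.linalg.norm(p - a))
    t = np.clip(float((p - a) @ ab) / denom, 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))
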