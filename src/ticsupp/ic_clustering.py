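"""Spatial clustering of independent-component equivalent dipoles.

Each brain IC carries a single equivalent current dipole (mm, RAS-oriented
Talairach-like space).  ICs are grouped across subjects with k-means on the
dipole coordinates; the number of clusters is chosen by the mean silhouette
index.  Smoothed dipole densities (isotropic Gaussian, FWHM 20 mm) summarise
each cluster's spatial footprint, and a small packaged lookup table provides
decorative anatomical labels.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "ICClusterSet",
    "DensityGrid",
    "DensityVolume",
    "LowSeparationWarning",
    "select_k_silhouette",
    "cluster_dipoles",
    "dipole_density",
    "fwhm_to_sigma",
    "label_lookup",
    "load_atlas",
]

#: silhouette below this is reported as weakly clusterable (Rousseeuw's
#: rule of thumb: under 0.5 the structure is weak and could be artificial)
_LOW_SILHOUETTE = 0.5


class LowSeparationWarning(UserWarning):
    """The best silhouette score is low; the data may not be clusterable."""


@dataclass(frozen=True)
class ICClusterSet:
    """A k-means partition of dipoles: labels, centroids, and fit diagnostics."""

    k: int
    labels: np.ndarray  # (n,) cluster index per dipole
    centroids: np.ndarray  # (k, 3) mm
    inertia: float
    mean_silhouette: float | None = None

    def member_counts(self, groups=None) -> pd.DataFrame:
        """Cluster sizes, optionally split by a per-dipole group label."""
        df = pd.DataFrame({"cluster": self.labels})
        if groups is None:
            return df.value_counts("cluster").rename("n_ics").reset_index()
        df["group"] = np.asarray(groups)
        out = df.value_counts(["cluster", "group"]).rename("n_ics").reset_index()
        return out.sort_values(["cluster", "group"]).reset_index(drop=True)


def _as_positions(dipoles) -> np.ndarray:
    xyz = np.asarray(dipoles, dtype=float)
    if xyz.ndim != 2 or xyz.shape[1] != 3:
        raise ValueError("dipole positions must be an (n, 3) array of mm coordinates")
    if not np.all(np.isfinite(xyz)):
        raise ValueError("dipole positions contain non-finite coordinates")
    return xyz


def cluster_dipoles(
    dipoles,
    k: int,
    seed: int = 0,
    n_init: int = 20,
    compute_silhouette: bool = False,
) -> ICClusterSet:
    """Partition dipoles into ``k`` spatial clusters.

    Lloyd's algorithm with k-means++ initialisation and ``n_init`` restarts;
    the lowest-inertia solution is kept.  Deterministic for a fixed seed.
    """
    xyz = _as_positions(dipoles)
    n = xyz.shape[0]
    if k < 2:
        raise ValueError("k must be at least 2")
    if n <= k:
        raise ValueError(f"need more dipoles ({n}) than clusters ({k})")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(xyz)
    sil = float(silhouette_score(xyz, km.labels_)) if compute_silhouette else None
    return ICClusterSet(
        k=k,
        labels=km.labels_.astype(int),
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        mean_silhouette=sil,
    )


def select_k_silhouette(
    dipoles,
    k_range=range(2, 31),
    seed: int = 0,
    n_init: int = 20,
) -> tuple[int, dict[int, float]]:
    """Pick the number of spatial clusters by the mean silhouette index.

    Runs k-means for every ``k`` in ``k_range`` (Euclidean distance in mm,
    matching the clustering metric) and returns the argmax of the mean
    silhouette together with all scores.  Emits :class:`LowSeparationWarning`
    when even the best score is low.
    """
    xyz = _as_positions(dipoles)
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    if ks[0] < 2 or ks[-1] > xyz.shape[0] - 1:
        raise ValueError(f"k_range must lie within [2, {xyz.shape[0] - 1}]")
    if np.unique(xyz, axis=0).shape[0] <= ks[-1]:
        raise ValueError("too many duplicate dipole positions for the requested k_range")
    scores: dict[int, float] = {}
    for k in ks:
        cs = cluster_dipoles(xyz, k, seed=seed, n_init=n_init, compute_silhouette=True)
        scores[k] = cs.mean_silhouette  # type: ignore[assignment]
    best_k = max(scores, key=lambda k: (scores[k], -k))
    if scores[best_k] < _LOW_SILHOUETTE:
        warnings.warn(
            f"best mean silhouette is only {scores[best_k]:.3f}; the dipole cloud "
            "may not have separable spatial clusters",
            LowSeparationWarning,
            stacklevel=2,
        )
    return best_k, scores


# ---------------------------------------------------------------------------
# dipole density


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian standard deviation for a given full width at half maximum."""
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class DensityGrid:
    """Axis-aligned voxel grid: origin (mm), isotropic spacing (mm), dims."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[i] + self.spacing * np.arange(self.dims[i]) for i in range(3)
        )  # type: ignore[return-value]

    @classmethod
    def around(cls, positions, margin: float, spacing: float) -> "DensityGrid":
        """Smallest grid covering ``positions`` with the given margin on all sides."""
        xyz = _as_positions(positions)
        lo = xyz.min(axis=0) - margin
        hi = xyz.max(axis=0) + margin
        dims = tuple(int(np.ceil((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
        return cls(origin=tuple(lo), spacing=spacing, dims=dims)  # type: ignore[arg-type]


@dataclass(frozen=True)
class DensityVolume:
    grid: DensityGrid
    values: np.ndarray  # (nx, ny, nz), summed normalised kernels

    def integral(self) -> float:
        """Numeric integral of the density over the grid (kernel mass units)."""
        return float(self.values.sum() * self.grid.spacing**3)


def dipole_density(dipoles, grid: DensityGrid, fwhm_mm: float = 20.0) -> DensityVolume:
    """Sum of normalised isotropic 3-D Gaussians (FWHM ``fwhm_mm``) per dipole.

    The kernel is separable, so each dipole contributes an outer product of
    three 1-D Gaussians; the volume integral of each contribution is ~1.
    """
    xyz = _as_positions(dipoles)
    sigma = fwhm_to_sigma(fwhm_mm)
    ax = grid.axes()
    margin = 2.0 * fwhm_mm
    for i in range(3):
        if np.any(xyz[:, i] < ax[i][0] + margin) or np.any(xyz[:, i] > ax[i][-1] - margin):
            raise ValueError(
                f"dipole outside the grid margin (need >= {margin} mm on every side)"
            )
    norm = (2.0 * np.pi * sigma**2) ** -1.5
    values = np.zeros(grid.dims, dtype=float)
    for pos in xyz:
        g = [np.exp(-0.5 * ((ax[i] - pos[i]) / sigma) ** 2) for i in range(3)]
        values += norm * np.einsum("i,j,k->ijk", g[0], g[1], g[2])
    return DensityVolume(grid=grid, values=values)


# ---------------------------------------------------------------------------
# anatomical labels


def load_atlas() -> pd.DataFrame:
    """Packaged synthetic macro-region lookup table.

    A simplified stand-in for a stereotaxic atlas: ~70 macro-regions with
    hand-placed representative Talairach-like coordinates, constructed for
    report decoration only; it carries no statistical role and is not a real
    atlas.
    """
    ref = importlib.resources.files("ticsupp.data") / "atlas_synthetic.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def label_lookup(
    position,
    atlas_table: pd.DataFrame,
    n_labels: int = 3,
) -> list[tuple[str, float]]:
    """The ``n_labels`` nearest atlas regions to a position, closest first.

    Returns ``(label, distance_mm)`` pairs sorted by distance; exact distance
    ties are broken lexicographically by label.  A smaller atlas returns
    fewer entries.
    """
    if atlas_table is None or len(atlas_table) == 0:
        raise ValueError("atlas table is empty")
    pos = np.asarray(position, dtype=float)
    if pos.shape != (3,):
        raise ValueError("position must be a 3-vector of mm coordinates")
    coords = atlas_table[["x", "y", "z"]].to_numpy(dtype=float)
    dists = np.linalg.norm(coords - pos, axis=1)
    order = sorted(range(len(dists)), key=lambda i: (dists[i], str(atlas_table["label"].iat[i])))
    return [(str(atlas_table["label"].iat[i]), float(dists[i])) for i in order[:n_labels]]
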