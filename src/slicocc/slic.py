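"""SLIC-Occ: localized k-means supervoxel segmentation of occupancy series.

Classic SLIC clusters pixels by a weighted combination of color and spatial
distance inside a restricted search window. Here the "color" is the V-vector
of occupancy values across plasma concentrations, so voxels sharing one
supervoxel share a dose-response curve. The distance minimized per voxel is

    D = sqrt(d_feature^2 + (d_spatial / S)^2 * m^2)

with d_feature the Euclidean distance across the V occupancy channels,
d_spatial the 3D Euclidean voxel distance, S = cbrt(N/K) the seed-grid
spacing (N in-mask voxels, K requested clusters), and m the compactness
weight. Each iteration scans a 2S x 2S x 2S window around every cluster
center, assigns each in-mask voxel to the argmin-D center among those whose
windows reach it, then recomputes centers as member means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, ClusterMixin

from .phantom import OccupancySeries

__all__ = [
    "ClusterCenter",
    "ClusterLabeling",
    "SLICOcc",
    "grid_spacing",
    "spatial_distance",
    "feature_distance",
    "total_distance",
    "initialize_centers",
    "run_slic_occ",
    "cluster_mean_curves",
]


@dataclass
class ClusterCenter:
    spatial: np.ndarray  # (3,) float voxel coordinates
    feature: np.ndarray  # (V,) occupancy per concentration
    member_count: int = 0


@dataclass
class ClusterLabeling:
    """Supervoxel partition of the brain mask.

    label_image is 0 outside the mask and 1..K_final inside; every label has
    at least one member voxel.
    """

    label_image: np.ndarray
    centers: list[ClusterCenter]
    K_initial: int
    K_final: int
    m: float
    S: float
    n_iterations: int
    converged: bool
    params: dict = field(default_factory=dict)


def grid_spacing(N: int, K: int) -> float:
    """Seed-grid spacing S = (N/K)^(1/3) for N in-mask voxels, K clusters."""
    if K < 1 or N < K:
        raise ValueError("need 1 <= K <= N")
    return float(np.cbrt(N / K))


def spatial_distance(center_xyz, voxel_xyz) -> float:
    """Euclidean distance between a cluster center and a voxel, voxel units."""
    c = np.asarray(center_xyz, dtype=float)
    v = np.asarray(voxel_xyz, dtype=float)
    return float(np.sqrt(((c - v) ** 2).sum()))


def feature_distance(center_features, voxel_features) -> float:
    """Euclidean distance across the V occupancy channels (unnormalized)."""
    c = np.asarray(center_features, dtype=float)
    v = np.asarray(voxel_features, dtype=float)
    if c.shape != v.shape:
        raise ValueError("feature vectors must have equal length")
    return float(np.sqrt(((c - v) ** 2).sum()))


def total_distance(d_feature: float, d_spatial: float, S: float, m: float) -> float:
    """Combined SLIC distance D = sqrt(d_feature^2 + (d_spatial/S)^2 * m^2)."""
    if S <= 0:
        raise ValueError("S must be positive")
    return float(np.sqrt(d_feature**2 + (d_spatial / S) ** 2 * m**2))


def _interp_features(data: np.ndarray, mask: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of the (V, ...) series at float positions.

    Outside-mask voxels contribute 0; symmetric under grid flips, which keeps
    seeding orientation-equivariant.
    """
    filled = np.where(mask, data, 0.0)
    V = data.shape[0]
    out = np.empty((pos.shape[0], V))
    coords = pos.T  # (3, n)
    for v in range(V):
        out[:, v] = ndimage.map_coordinates(
            filled[v], coords, order=1, mode="nearest"
        )
    return out


def initialize_centers(series: OccupancySeries, K: int) -> list[ClusterCenter]:
    """Seed cluster centers on a regular grid over the mask's bounding box.

    Grid spacing is S = cbrt(N/K) per axis (axis counts rounded to cover the
    bounding box); centers keep fractional positions and are dropped when the
    surrounding voxel cell lies entirely outside the mask. Features are
    initialized by trilinear interpolation of the occupancy series.
    """
    mask = series.brain_mask
    N = int(mask.sum())
    if N == 0:
        raise ValueError("empty mask")
    if K < 1 or K > N:
        raise ValueError("need 1 <= K <= number of in-mask voxels")
    S = grid_spacing(N, K)
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    extent = hi - lo + 1
    counts = [max(1, int(round(extent[a] / S))) for a in range(3)]
    # guarantee at least K grid points (per-axis rounding can undershoot for
    # small K): widen the axis currently holding the coarsest spacing
    while counts[0] * counts[1] * counts[2] < K:
        a = int(np.argmax([extent[i] / counts[i] for i in range(3)]))
        counts[a] += 1
    # spacing exactly S, centered on the bounding box, so the seed density is
    # 1/S^3 = K/N and the expected cluster volume is N/K
    mid = [(lo[a] + hi[a]) / 2 for a in range(3)]
    axes = [
        mid[a] + (np.arange(counts[a]) - (counts[a] - 1) / 2) * S for a in range(3)
    ]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pos = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    # keep a seed iff its position lies inside the mask: trilinear mask
    # fraction > 1/2 (exact under axis flips/permutations, unlike rounding)
    frac = ndimage.map_coordinates(
        mask.astype(float), pos.T, order=1, mode="nearest"
    )
    kept = pos[frac > 0.5]
    if kept.shape[0] == 0:
        # degenerate masks (or K=1 off-center): snap seeds to the nearest
        # in-mask voxel instead of dropping them
        from scipy.spatial import cKDTree

        tree = cKDTree(idx)
        _, nearest = tree.query(pos)
        kept = np.unique(idx[nearest], axis=0).astype(float)
    pos = kept
    feats = _interp_features(series.data, mask, pos)
    return [ClusterCenter(spatial=p, feature=f) for p, f in zip(pos, feats)]


class SLICOcc(BaseEstimator, ClusterMixin):
    """SLIC supervoxel clustering of a 4D occupancy series.

    Parameters
    ----------
    n_clusters : int
        Requested number of clusters K; the expected cluster volume is N/K
        voxels and the seed spacing S = cbrt(N/K).
    compactness : float
        Spatial weight m. Small m follows occupancy boundaries; large m gives
        regular, nearly-Voronoi supervoxels.
    max_iter : int
        Assignment/update iterations.
    tol : float
        Convergence threshold on the mean center displacement (voxels).
    enforce_connectivity : bool
        Optionally reassign disconnected label fragments to the dominant
        neighboring cluster after convergence (off by default).

    Attributes
    ----------
    labels_ : (nx, ny, nz) int array, 0 outside the mask, 1..n_clusters_ inside.
    centers_ : list of ClusterCenter (member-mean position and curve).
    n_clusters_ : number of non-empty clusters (K_final).
    grid_spacing_ : S actually used.
    n_iter_ : iterations run; converged_ : whether tol was reached.
    """

    def __init__(
        self,
        n_clusters: int = 400,
        compactness: float = 0.5,
        max_iter: int = 10,
        tol: float = 0.1,
        enforce_connectivity: bool = False,
    ):
        self.n_clusters = n_clusters
        self.compactness = compactness
        self.max_iter = max_iter
        self.tol = tol
        self.enforce_connectivity = enforce_connectivity

    def fit(self, X: OccupancySeries, y=None) -> "SLICOcc":
        series = X
        mask = series.brain_mask
        if not mask.any():
            raise ValueError("empty mask")
        curves = series.masked_curves()
        if not np.all(np.isfinite(curves)):
            raise ValueError("non-finite occupancy values inside the mask")
        N = curves.shape[0]
        m = float(self.compactness)
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        S = grid_spacing(N, self.n_clusters)
        centers = initialize_centers(series, self.n_clusters)
        K0 = len(centers)
        cpos = np.array([c.spatial for c in centers])
        cfeat = np.array([c.feature for c in centers])

        coords = np.argwhere(mask).astype(float)
        index_vol = np.full(mask.shape, -1, dtype=np.int64)
        index_vol[mask] = np.arange(N)
        shape = np.array(mask.shape)
        w = m * m / (S * S)

        assign = np.full(N, -1, dtype=np.int64)
        n_iter = 0
        converged = False
        for n_iter in range(1, self.max_iter + 1):
            best = np.full(N, np.inf)
            assign[:] = -1
            for k in range(K0):
                lo = np.maximum(np.ceil(cpos[k] - S).astype(int), 0)
                hi = np.minimum(np.floor(cpos[k] + S).astype(int), shape - 1)
                if np.any(hi < lo):
                    continue
                sub = index_vol[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
                idx = sub[sub >= 0]
                if idx.size == 0:
                    continue
                df2 = ((curves[idx] - cfeat[k]) ** 2).sum(axis=1)
                ds2 = ((coords[idx] - cpos[k]) ** 2).sum(axis=1)
                d2 = df2 + ds2 * w
                upd = d2 < best[idx]
                ii = idx[upd]
                best[ii] = d2[upd]
                assign[ii] = k
            unc = np.flatnonzero(assign < 0)
            if unc.size:
                # masked voxels outside every window: global argmin of D
                df2 = ((curves[unc, None, :] - cfeat[None, :, :]) ** 2).sum(axis=2)
                ds2 = ((coords[unc, None, :] - cpos[None, :, :]) ** 2).sum(axis=2)
                assign[unc] = np.argmin(df2 + ds2 * w, axis=1)

            counts = np.bincount(assign, minlength=K0)
            newpos = cpos.copy()
            newfeat = cfeat.copy()
            nz = counts > 0
            for a in range(3):
                s = np.bincount(assign, weights=coords[:, a], minlength=K0)
                newpos[nz, a] = s[nz] / counts[nz]
            for v in range(curves.shape[1]):
                s = np.bincount(assign, weights=curves[:, v], minlength=K0)
                newfeat[nz, v] = s[nz] / counts[nz]
            disp = np.sqrt(((newpos[nz] - cpos[nz]) ** 2).sum(axis=1)).mean()
            cpos, cfeat = newpos, newfeat
            if disp < self.tol:
                converged = True
                break

        # drop empty clusters, compact labels to 1..K_final in center order
        counts = np.bincount(assign, minlength=K0)
        nz = np.flatnonzero(counts > 0)
        remap = np.full(K0, -1, dtype=np.int64)
        remap[nz] = np.arange(1, nz.size + 1)
        labels = np.zeros(mask.shape, dtype=np.int32)
        labels[mask] = remap[assign]
        if self.enforce_connectivity:
            labels = _relabel_fragments(labels, mask)
            nz_labels = np.unique(labels[mask])
            lut = np.zeros(labels.max() + 1, dtype=np.int32)
            lut[nz_labels] = np.arange(1, nz_labels.size + 1)
            labels = lut[labels]

        self.labels_ = labels
        self.grid_spacing_ = S
        self.n_iter_ = n_iter
        self.converged_ = converged
        self._finalize_centers(labels, coords, curves, index_vol)
        self.K_initial_ = K0
        self.n_clusters_ = len(self.centers_)
        return self

    def _finalize_centers(self, labels, coords, curves, index_vol):
        # labels[mask] flattens in the same C order as np.argwhere(mask)
        mask_order_labels = labels[index_vol >= 0].astype(np.int64)
        Kf = int(mask_order_labels.max())
        counts = np.bincount(mask_order_labels, minlength=Kf + 1)
        centers: list[ClusterCenter] = []
        for k in range(1, Kf + 1):
            sel = mask_order_labels == k
            centers.append(
                ClusterCenter(
                    spatial=coords[sel].mean(axis=0),
                    feature=curves[sel].mean(axis=0),
                    member_count=int(counts[k]),
                )
            )
        self.centers_ = centers

    def labeling_(self) -> ClusterLabeling:
        """Package the fitted attributes as a ClusterLabeling record."""
        return ClusterLabeling(
            label_image=self.labels_,
            centers=self.centers_,
            K_initial=self.K_initial_,
            K_final=self.n_clusters_,
            m=self.compactness,
            S=self.grid_spacing_,
            n_iterations=self.n_iter_,
            converged=self.converged_,
            params=self.get_params(),
        )


def _relabel_fragments(labels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Reassign all but the largest connected fragment of each cluster to the
    most common neighboring cluster."""
    out = labels.copy()
    structure = ndimage.generate_binary_structure(3, 1)
    for k in np.unique(labels[mask]):
        comp, ncomp = ndimage.label(out == k, structure=structure)
        if ncomp <= 1:
            continue
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, np.arange(1, ncomp + 1))
        main = int(np.argmax(sizes)) + 1
        for c in range(1, ncomp + 1):
            if c == main:
                continue
            frag = comp == c
            ring = ndimage.binary_dilation(frag, structure) & ~frag & mask
            neigh = out[ring]
            neigh = neigh[neigh != k]
            if neigh.size:
                out[frag] = np.bincount(neigh).argmax()
    return out


def run_slic_occ(
    series: OccupancySeries,
    K: int,
    m: float,
    max_iter: int = 10,
    tol: float = 0.1,
    enforce_connectivity: bool = False,
) -> ClusterLabeling:
    """Functional wrapper over :class:`SLICOcc`."""
    est = SLICOcc(
        n_clusters=K,
        compactness=m,
        max_iter=max_iter,
        tol=tol,
        enforce_connectivity=enforce_connectivity,
    )
    est.fit(series)
    return est.labeling_()


def cluster_mean_curves(
    labeling: ClusterLabeling, series: OccupancySeries
) -> tuple[np.ndarray, np.ndarray]:
    """Mean occupancy curve per cluster: (K_final, V) array and member counts."""
    if labeling.label_image.shape != series.brain_mask.shape:
        raise ValueError("labeling and series grids differ")
    mask = series.brain_mask
    lab = labeling.label_image[mask]
    curves = series.masked_curves()
    Kf = labeling.K_final
    counts = np.bincount(lab, minlength=Kf + 1)[1:]
    if np.any(counts == 0):
        raise RuntimeError("cluster without members after compaction")
    out = np.empty((Kf, curves.shape[1]))
    for v in range(curves.shape[1]):
        s = np.bincount(lab, weights=curves[:, v], minlength=Kf + 1)[1:]
        out[:, v] = s / counts
    return out, counts
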