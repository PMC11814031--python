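"""Mass-univariate SUVR association mapping with cluster-extent FWE control.

Each in-mask voxel gets a simple-regression t statistic (intercept plus one
scalar regressor across subjects).  Suprathreshold voxels at a parametric
cluster-forming threshold (one-tailed, p < 0.001 by default; p < 0.01 for
exploratory maps) are grouped into connected clusters, and cluster-level
family-wise error p-values come from the permutation null distribution of
the *maximum* cluster extent obtained by relabeling the regressor across
subjects (Freedman-Lane with an intercept-only nuisance model, i.e. simple
relabeling).  Random-field theory is deliberately not used.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import ImageVolume
from .group_stats import DesignError
from .pet_suvr import SUVRVolume

DEFAULT_CLUSTER_FORMING_P = 0.001
DEFAULT_CONNECTIVITY = 18       # SPM-style edge connectivity
_PERM_CHUNK = 256


def _connectivity_structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}.get(connectivity)
    if rank is None:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, rank)


def _as_array(image) -> np.ndarray:
    if isinstance(image, SUVRVolume):
        return image.data
    if isinstance(image, ImageVolume):
        return image.data
    return np.asarray(image, dtype=float)


def _stack(images, mask: np.ndarray) -> np.ndarray:
    arrays = [_as_array(im) for im in images]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("images are not on a common grid")
    if mask.shape != shape:
        raise ValueError("analysis mask grid does not match images")
    return np.stack([a[mask] for a in arrays])     # (n_subjects, n_voxels)


@dataclass
class StatisticMap:
    """Per-voxel t map for a single-regressor GLM."""

    t: np.ndarray                 # 3-D, NaN outside the analysis mask
    df: int
    mask: np.ndarray
    regressor_name: str = "regressor"
    perfect_fit: np.ndarray | None = None   # voxels with zero residual (|t| -> inf)


def _t_vector(data: np.ndarray, x: np.ndarray, df: int) -> np.ndarray:
    """t statistics for one regressor across all voxels; data (n, V)."""
    xc = x - x.mean()
    sxx = float(xc @ xc)
    yc = data - data.mean(axis=0, keepdims=True)
    syy = np.einsum("ij,ij->j", yc, yc)
    slope = (xc @ yc) / sxx
    rss = np.maximum(syy - slope**2 * sxx, 0.0)
    eps = 1e-12 * (syy + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope * np.sqrt(df * sxx / rss)
        return np.where(rss <= eps, np.sign(slope) * np.inf, t)


def _t_matrix(data: np.ndarray, X: np.ndarray, df: int) -> np.ndarray:
    """t statistics for many permuted regressors at once; X (m, n), data (n, V)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    sxx = float(np.einsum("ij,ij->i", Xc, Xc)[0])   # permutation-invariant
    yc = data - data.mean(axis=0, keepdims=True)
    syy = np.einsum("ij,ij->j", yc, yc)
    slopes = (Xc @ yc) / sxx                        # (m, V)
    rss = np.maximum(syy[None, :] - slopes**2 * sxx, 0.0)
    eps = 1e-12 * (syy[None, :] + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slopes * np.sqrt(df * sxx / rss)
        return np.where(rss <= eps, np.sign(slopes) * np.inf, t)


def voxelwise_glm(images, regressor, mask: np.ndarray, regressor_name: str = "regressor") -> StatisticMap:
    """Per-voxel slope t statistic for one scalar regressor (with intercept).

    Voxels fitted perfectly (zero residual) are flagged and carry ``±inf``.
    """
    mask = np.asarray(mask, dtype=bool)
    x = np.asarray(regressor, dtype=float)
    data = _stack(images, mask)
    n = data.shape[0]
    if len(x) != n:
        raise ValueError("regressor length does not match number of images")
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(x) == 0:
        raise DesignError("regressor is constant across subjects")
    df = n - 2
    tvec = _t_vector(data, x, df)
    tmap = np.full(mask.shape, np.nan)
    tmap[mask] = tvec
    perfect = np.zeros(mask.shape, dtype=bool)
    perfect[mask] = np.isinf(tvec)
    return StatisticMap(t=tmap, df=df, mask=mask, regressor_name=regressor_name, perfect_fit=perfect)


def threshold_and_label(
    stat_map: StatisticMap,
    cluster_forming_p: float = DEFAULT_CLUSTER_FORMING_P,
    connectivity: int = DEFAULT_CONNECTIVITY,
    direction: str = "positive",
) -> tuple[np.ndarray, np.ndarray, float]:
    """Threshold a t map one-tailed and label connected clusters.

    Returns ``(labels, sizes, t_crit)``: an integer label volume (0 =
    sub-threshold), the voxel count per cluster (``sizes[i]`` for label
    ``i+1``), and the critical t.  An empty suprathreshold set yields zero
    clusters, not an error.
    """
    if not 0 < cluster_forming_p < 1:
        raise ValueError("cluster_forming_p must be in (0, 1)")
    t_crit = float(stats.t.isf(cluster_forming_p, df=stat_map.df))
    with np.errstate(invalid="ignore"):
        if direction == "positive":
            supra = stat_map.t >= t_crit
        elif direction == "negative":
            supra = stat_map.t <= -t_crit
        else:
            raise ValueError("direction must be 'positive' or 'negative'")
    supra &= stat_map.mask
    labels, n_clusters = ndimage.label(supra, structure=_connectivity_structure(connectivity))
    sizes = np.bincount(labels.ravel(), minlength=n_clusters + 1)[1:]
    return labels, sizes, t_crit


@dataclass
class ClusterResult:
    """Cluster-level FWE inference output."""

    table: pd.DataFrame           # one row per observed cluster
    labels: np.ndarray            # cluster-label volume
    t_map: StatisticMap
    t_crit: float
    n_perm: int
    exhaustive: bool
    seed: int | None
    null_max_extent: np.ndarray = field(repr=False, default=None)

    @property
    def min_p_fwe(self) -> float:
        return float(self.table["p_fwe"].min()) if len(self.table) else 1.0


def _max_extent(binary: np.ndarray, structure: np.ndarray) -> int:
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def cluster_fwe(
    images,
    regressor,
    mask: np.ndarray,
    cluster_forming_p: float = DEFAULT_CLUSTER_FORMING_P,
    n_perm: int = 1000,
    seed: int | None = 0,
    connectivity: int = DEFAULT_CONNECTIVITY,
    direction: str = "positive",
    affine: np.ndarray | None = None,
    regressor_name: str = "regressor",
) -> ClusterResult:
    """Cluster-extent FWE-corrected association map.

    Builds the permutation null of the maximum suprathreshold cluster
    extent by relabeling the regressor across subjects and assigns each
    observed cluster ``p_fwe = (1 + #{max_extent >= size}) / (1 + n_perm)``
    (exact fraction when the relabeling space is enumerated exhaustively).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for cluster-level inference")
    mask = np.asarray(mask, dtype=bool)
    x = np.asarray(regressor, dtype=float)
    obs_map = voxelwise_glm(images, x, mask, regressor_name=regressor_name)
    labels, sizes, t_crit = threshold_and_label(obs_map, cluster_forming_p, connectivity, direction)
    structure = _connectivity_structure(connectivity)

    data = _stack(images, mask)
    n = data.shape[0]
    df = n - 2
    sign = 1.0 if direction == "positive" else -1.0

    if math.factorial(n) <= n_perm:
        perms = np.array(list(itertools.permutations(range(n))))
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        exhaustive = False

    null_max = np.empty(len(perms), dtype=int)
    for start in range(0, len(perms), _PERM_CHUNK):
        chunk = perms[start:start + _PERM_CHUNK]
        T = _t_matrix(data, x[chunk], df)
        supra = sign * T >= t_crit
        for i, row in enumerate(supra):
            vol = np.zeros(mask.shape, dtype=bool)
            vol[mask] = row
            null_max[start + i] = _max_extent(vol, structure)

    rows = []
    ids = np.argsort(sizes)[::-1]
    for rank, idx in enumerate(ids, start=1):
        size = int(sizes[idx])
        in_cluster = labels == idx + 1
        tvals = np.where(in_cluster, obs_map.t, -np.inf)
        peak = np.unravel_index(np.nanargmax(sign * np.where(np.isnan(tvals), -np.inf, tvals)), tvals.shape)
        b = int(np.sum(null_max >= size))
        p_fwe = b / len(perms) if exhaustive else (1 + b) / (1 + len(perms))
        peak_mm = (np.asarray(affine) @ np.array([*peak, 1.0]))[:3] if affine is not None else np.asarray(peak, float)
        rows.append({
            "cluster_id": rank, "n_voxels": size,
            "peak_t": float(obs_map.t[peak]),
            "peak_i": int(peak[0]), "peak_j": int(peak[1]), "peak_k": int(peak[2]),
            "peak_x_mm": float(peak_mm[0]), "peak_y_mm": float(peak_mm[1]), "peak_z_mm": float(peak_mm[2]),
            "p_fwe": float(p_fwe),
        })
    table = pd.DataFrame(rows, columns=[
        "cluster_id", "n_voxels", "peak_t", "peak_i", "peak_j", "peak_k",
        "peak_x_mm", "peak_y_mm", "peak_z_mm", "p_fwe",
    ])

    # renumber label volume to match table ordering (1 = largest cluster)
    relabeled = np.zeros_like(labels)
    for rank, idx in enumerate(ids, start=1):
        relabeled[labels == idx + 1] = rank

    return ClusterResult(
        table=table, labels=relabeled, t_map=obs_map, t_crit=t_crit,
        n_perm=len(perms), exhaustive=exhaustive, seed=seed, null_max_extent=null_max,
    )
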