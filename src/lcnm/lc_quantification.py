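"""Sub-regional locus coeruleus neuromelanin contrast extraction.

The measurement chain per subject:

1. slice-to-slice intensity normalization against a brain mask
   (:func:`normalize_slices`);
2. tri-section of each LC search ROI into rostral / middle / caudal
   axial blocks (:func:`trisect_roi`);
3. per block and side, the mean intensity of the five brightest
   *connected* voxels (:func:`extract_brightest_connected`);
4. the neuromelanin contrast ratio against the pontine background ROI
   (:func:`compute_nm_contrast`), averaged over left and right.

The connected-subset extraction is the numerically delicate step: it is
solved exactly (branch-and-bound maximization of the subset mean over
connected k-subsets) with a greedy variant available for very large ROIs
or for comparison.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .core import AXIAL_AXIS, GridError, ImageVolume, ROISet

logger = logging.getLogger(__name__)

SUBREGIONS = ("rostral", "middle", "caudal")
SIDES = ("left", "right")

DEFAULT_K = 5
DEFAULT_CONNECTIVITY = 26
#: ROI size above which the exact branch-and-bound search falls back to greedy.
GREEDY_FALLBACK_SIZE = 4000


# ---------------------------------------------------------------------------
# slice normalization
# ---------------------------------------------------------------------------

def normalize_slices(volume: ImageVolume, brain_mask: np.ndarray, axis: int = AXIAL_AXIS) -> ImageVolume:
    """Rescale each axial slice to the global in-mask mean intensity.

    Every slice is multiplied by ``global_mean / slice_mean`` where both
    means are taken over ``brain_mask``, undoing multiplicative per-slice
    gain while preserving the overall intensity scale.  Slices without any
    mask voxels are left unscaled (and logged).
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != volume.shape:
        raise GridError("brain_mask grid does not match volume")
    if not brain_mask.any():
        raise ValueError("brain mask is empty; cannot normalize slices")

    data = volume.data
    global_mean = float(data[brain_mask].mean())
    out = data.copy()
    skipped = []
    for k in range(data.shape[axis]):
        sl = [slice(None)] * 3
        sl[axis] = k
        sl = tuple(sl)
        m = brain_mask[sl]
        if not m.any():
            skipped.append(k)
            continue
        slice_mean = float(data[sl][m].mean())
        if slice_mean <= 0:
            skipped.append(k)
            continue
        out[sl] = data[sl] * (global_mean / slice_mean)
    if skipped:
        logger.warning("normalize_slices: %d slice(s) left unscaled (empty mask or non-positive mean): %s",
                       len(skipped), skipped)
    return volume.with_data(out)


# ---------------------------------------------------------------------------
# tri-section
# ---------------------------------------------------------------------------

def split_axial_thirds(slice_indices: np.ndarray) -> dict[str, np.ndarray]:
    """Partition sorted axial slice indices into rostral/middle/caudal blocks.

    The rostral block is the most superior (highest slice index).  When the
    slice count is not divisible by three the remainder is assigned
    rostral-first, e.g. 8 slices -> (rostral 3, middle 3, caudal 2).
    """
    s = np.sort(np.unique(np.asarray(slice_indices, dtype=int)))
    n = len(s)
    if n < 3:
        raise GridError(f"need at least 3 axial slices for tri-section, got {n}")
    base, rem = divmod(n, 3)
    n_rostral = base + (1 if rem >= 1 else 0)
    n_middle = base + (1 if rem == 2 else 0)
    n_caudal = base
    return {
        "rostral": s[n_caudal + n_middle:],
        "middle": s[n_caudal:n_caudal + n_middle],
        "caudal": s[:n_caudal],
    }


def trisect_roi(search_roi: np.ndarray, axis: int = AXIAL_AXIS) -> dict[str, np.ndarray]:
    """Split a search ROI into rostral/middle/caudal sub-masks by axial slice.

    Returns a dict of three masks that partition the input (pairwise
    disjoint, union equal to the input mask).
    """
    search_roi = np.asarray(search_roi, dtype=bool)
    occupied = np.unique(np.nonzero(search_roi)[axis])
    blocks = split_axial_thirds(occupied)
    out: dict[str, np.ndarray] = {}
    slice_axis_index = np.arange(search_roi.shape[axis])
    for name, slices in blocks.items():
        in_block = np.isin(slice_axis_index, slices)
        shape = [1, 1, 1]
        shape[axis] = search_roi.shape[axis]
        out[name] = search_roi & in_block.reshape(shape)
    return out


# ---------------------------------------------------------------------------
# brightest connected k-subset
# ---------------------------------------------------------------------------

def _neighbor_offsets(connectivity: int) -> np.ndarray:
    offs = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        order = sum(abs(x) for x in d)
        if connectivity == 6 and order > 1:
            continue
        if connectivity == 18 and order > 2:
            continue
        offs.append(d)
    return np.array(offs, dtype=int)


def _roi_adjacency(coords: np.ndarray, connectivity: int) -> list[np.ndarray]:
    """Adjacency lists among ROI voxels under the given 3-D connectivity."""
    index = {tuple(c): i for i, c in enumerate(coords)}
    offsets = _neighbor_offsets(connectivity)
    adj: list[list[int]] = [[] for _ in range(len(coords))]
    for i, c in enumerate(coords):
        for off in offsets:
            j = index.get((c[0] + off[0], c[1] + off[1], c[2] + off[2]))
            if j is not None:
                adj[i].append(j)
    return [np.array(a, dtype=int) for a in adj]


def _greedy_from_seed(values: np.ndarray, adj: list[np.ndarray], seed: int, k: int) -> tuple[list[int], float]:
    members = [seed]
    total = float(values[seed])
    in_set = {seed}
    frontier = set(adj[seed].tolist())
    while len(members) < k and frontier:
        best = max(frontier, key=lambda v: (values[v], -v))
        members.append(best)
        total += float(values[best])
        in_set.add(best)
        frontier.discard(best)
        frontier.update(v for v in adj[best].tolist() if v not in in_set)
    return members, total


def _greedy_best(values: np.ndarray, adj: list[np.ndarray], k: int, n_seeds: int) -> tuple[list[int], float]:
    order = np.argsort(values, kind="stable")[::-1]
    best_set: list[int] = []
    best_sum = -np.inf
    for s in order[:n_seeds]:
        members, total = _greedy_from_seed(values, adj, int(s), k)
        if len(members) == k and total > best_sum:
            best_sum, best_set = total, members
    if not best_set:  # ROI has no connected k-subset from any seed (fragmented)
        members, total = _greedy_from_seed(values, adj, int(order[0]), k)
        best_set, best_sum = members, total
    return best_set, best_sum


def _exact_best(values: np.ndarray, adj: list[np.ndarray], k: int, n_seeds: int) -> tuple[list[int], float]:
    """Exact maximizer of the sum over connected k-subsets (branch & bound).

    Voxels are relabeled in decreasing value order; connected subsets are
    enumerated canonically by their minimum label (their brightest member)
    so each subset is visited once.  Two prunes keep this fast: roots whose
    value cannot beat the incumbent mean are skipped entirely, and partial
    subsets whose optimistic completion ``sum + (k-|S|)*value[root]`` cannot
    beat the incumbent are abandoned.
    """
    n = len(values)
    order = np.argsort(values, kind="stable")[::-1]
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    vals = values[order]
    radj = [np.sort(rank[adj[int(o)]]) for o in order]

    best_set, best_sum = _greedy_best(values, adj, k, n_seeds)
    best_sum_ranked = best_sum
    best_ranked = [int(rank[v]) for v in best_set]
    eps = 1e-12 * (1.0 + float(np.max(np.abs(vals))))

    def recurse(members: list[int], total: float, ext: list[int], blocked: set[int], root: int) -> None:
        nonlocal best_sum_ranked, best_ranked
        if len(members) == k:
            if total > best_sum_ranked + eps:
                best_sum_ranked = total
                best_ranked = list(members)
            return
        if total + (k - len(members)) * vals[root] <= best_sum_ranked + eps:
            return
        for i, u in enumerate(ext):
            new_nb = [int(w) for w in radj[u] if w > root and w not in blocked]
            blocked.update(new_nb)
            recurse(members + [u], total + float(vals[u]), ext[i + 1:] + new_nb, blocked, root)
            blocked.difference_update(new_nb)

    for root in range(n):
        if k * vals[root] <= best_sum_ranked + eps:
            break  # no subset rooted here (all members dimmer) can win
        nb = [int(w) for w in radj[root] if w > root]
        recurse([root], float(vals[root]), nb, set(nb) | {root}, root)

    return [int(order[r]) for r in best_ranked], best_sum_ranked


@dataclass
class ExtractionResult:
    """Brightest-connected-subset extraction output for one sub-ROI."""

    voxels: np.ndarray          # (m, 3) voxel indices of the selected subset
    mean_intensity: float
    k_requested: int
    flag: str = ""              # "" or "undersized"
    method: str = "exact"


def extract_brightest_connected(
    volume: ImageVolume | np.ndarray,
    roi: np.ndarray,
    k: int = DEFAULT_K,
    connectivity: int = DEFAULT_CONNECTIVITY,
    method: str = "exact",
    n_seeds: int = 10,
) -> ExtractionResult:
    """Find the connected ``k``-voxel subset of ``roi`` with maximal mean.

    Parameters
    ----------
    volume:
        Intensity volume (or raw 3-D array).
    roi:
        Boolean mask restricting the search.
    k:
        Subset size (5 in the standard pipeline).
    connectivity:
        6, 18 or 26 neighborhood.
    method:
        ``"exact"`` (default; exhaustive branch-and-bound, greedy fallback
        beyond :data:`GREEDY_FALLBACK_SIZE` voxels) or ``"greedy"``
        (multi-seed brightest-neighbor growth).
    """
    data = volume.data if isinstance(volume, ImageVolume) else np.asarray(volume, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != data.shape:
        raise GridError("ROI grid does not match volume")
    if k < 1:
        raise ValueError("k must be >= 1")
    if connectivity not in (6, 18, 26):
        raise ValueError("connectivity must be 6, 18 or 26")
    coords = np.argwhere(roi)
    if len(coords) == 0:
        raise ValueError("ROI is empty")
    values = data[tuple(coords.T)]

    if len(coords) <= k:
        return ExtractionResult(
            voxels=coords, mean_intensity=float(values.mean()), k_requested=k,
            flag="undersized", method=method,
        )

    adj = _roi_adjacency(coords, connectivity)
    if method == "greedy" or (method == "exact" and len(coords) > GREEDY_FALLBACK_SIZE):
        members, total = _greedy_best(values, adj, k, n_seeds)
        used = "greedy"
    elif method == "exact":
        members, total = _exact_best(values, adj, k, n_seeds)
        used = "exact"
    else:
        raise ValueError(f"unknown method '{method}'")

    flag = "" if len(members) == k else "undersized"
    return ExtractionResult(
        voxels=coords[members], mean_intensity=float(total / len(members)),
        k_requested=k, flag=flag, method=used,
    )


# ---------------------------------------------------------------------------
# contrast
# ---------------------------------------------------------------------------

def compute_nm_contrast(roi_mean: float, background_mean: float) -> float:
    """Neuromelanin contrast ratio ``(roi_mean - background_mean) / background_mean``."""
    if background_mean <= 0:
        raise ValueError(f"background mean must be positive, got {background_mean}")
    return (float(roi_mean) - float(background_mean)) / float(background_mean)


@dataclass
class SubregionMeasure:
    side: str
    subregion: str
    roi_mean: float
    background_mean: float      # the background value this contrast was ratioed against
    contrast: float
    voxels: np.ndarray
    flag: str = ""


@dataclass
class LCContrastResult:
    """Per-subject sub-regional LC neuromelanin contrast."""

    background_mean: float      # whole-background reference measurement
    measures: dict[tuple[str, str], SubregionMeasure] = field(default_factory=dict)
    background_voxels: np.ndarray | None = None
    background_method: str = "brightest"
    background_extent: str = "per-subregion"

    @property
    def averaged(self) -> dict[str, float]:
        """Left/right-averaged contrast per subregion."""
        return {
            sub: 0.5 * (self.measures[("left", sub)].contrast + self.measures[("right", sub)].contrast)
            for sub in SUBREGIONS
        }

    def to_records(self, subject_id: str = "") -> list[dict]:
        rows = []
        for (side, sub), m in self.measures.items():
            rows.append({
                "subject_id": subject_id, "side": side, "subregion": sub,
                "roi_mean": m.roi_mean, "background_mean": m.background_mean,
                "contrast": m.contrast, "flag": m.flag,
            })
        return rows

    def audit(self) -> dict:
        """Selected voxel coordinates per side/subregion (for JSON audit)."""
        return {
            f"{side}_{sub}": m.voxels.tolist()
            for (side, sub), m in self.measures.items()
        }


def quantify_subject(
    volume: ImageVolume,
    rois: ROISet,
    k: int = DEFAULT_K,
    connectivity: int = DEFAULT_CONNECTIVITY,
    method: str = "exact",
    normalize: bool = True,
    background_method: str = "brightest",
    background_extent: str = "per-subregion",
) -> LCContrastResult:
    """Full single-subject LC contrast measurement.

    Applies slice normalization, measures the background reference
    intensity, and for each side and rostral/middle/caudal block extracts
    the five brightest connected voxels and their contrast against the
    background.

    ``background_method="brightest"`` (default) applies the same
    five-brightest-connected-voxel extraction to the background ROI as to
    the LC sub-ROIs; ``"mean"`` uses the plain mean over the background
    voxels instead.  ``background_extent="per-subregion"`` (default)
    restricts the background ROI to the axial slices of the sub-ROI being
    measured, giving numerator and denominator identically shaped
    extraction pools so the maximum-mean selection bias cancels in the
    ratio; ``"whole"`` uses the full background ROI for every subregion.
    """
    if background_method not in ("brightest", "mean"):
        raise ValueError(f"unknown background_method '{background_method}'")
    if background_extent not in ("per-subregion", "whole"):
        raise ValueError(f"unknown background_extent '{background_extent}'")
    problems = rois.validate(volume.shape)
    if problems:
        raise GridError("; ".join(problems))
    vol = normalize_slices(volume, rois.brain_mask) if normalize else volume

    def measure_background(region: np.ndarray) -> tuple[float, np.ndarray | None]:
        if background_method == "brightest":
            ext = extract_brightest_connected(vol, region, k=k,
                                              connectivity=connectivity, method=method)
            return ext.mean_intensity, ext.voxels
        return float(vol.data[region].mean()), None

    whole_mean, whole_voxels = measure_background(rois.background_roi)
    result = LCContrastResult(
        background_mean=whole_mean, background_voxels=whole_voxels,
        background_method=background_method, background_extent=background_extent,
    )

    nz = vol.shape[AXIAL_AXIS]
    bg_cache: dict[tuple[int, ...], float] = {}
    for side in SIDES:
        roi = getattr(rois, f"search_roi_{side}")
        for sub, block in trisect_roi(roi).items():
            if background_extent == "per-subregion":
                slices = tuple(np.unique(np.nonzero(block)[AXIAL_AXIS]).tolist())
                if slices not in bg_cache:
                    in_block = np.isin(np.arange(nz), slices).reshape(1, 1, nz)
                    region = rois.background_roi & in_block
                    bg_cache[slices] = measure_background(region)[0] if region.any() else whole_mean
                bg_mean = bg_cache[slices]
            else:
                bg_mean = whole_mean
            ext = extract_brightest_connected(vol, block, k=k, connectivity=connectivity, method=method)
            result.measures[(side, sub)] = SubregionMeasure(
                side=side, subregion=sub, roi_mean=ext.mean_intensity,
                background_mean=bg_mean,
                contrast=compute_nm_contrast(ext.mean_intensity, bg_mean),
                voxels=ext.voxels, flag=ext.flag,
            )
    return result
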