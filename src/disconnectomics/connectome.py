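"""Building ROI-to-ROI streamline-count connectomes.

The connectome of a tractogram with respect to a parcellation counts, for
every pair of grey-matter regions, the streamlines connecting them. Because
tracking terminates at the grey/white matter interface rather than inside the
parcellation labels, each streamline endpoint is assigned by a radial search:
if the endpoint voxel itself is unlabeled, the nearest labeled voxel centre
within a fixed radius (default 2 mm) claims it. Streamlines that traverse
three or more distinct ROIs (endpoints included) are treated as tracking
artefacts and discarded before counting. Counts are raw streamline numbers —
deliberately not scaled by ROI volume or inverse streamline length.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataContractError
from .parcellation import Parcellation
from .tractogram import Streamline, Streamlines, densify

DEFAULT_RADIUS_MM = 2.0
DEFAULT_MAX_ROIS = 2


@dataclass
class ConnectomeMatrix:
    """Symmetric nonnegative streamline-count matrix over ROI labels."""

    counts: np.ndarray
    roi_order: list[int]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n = len(self.roi_order)
        if self.counts.shape != (n, n):
            raise DataContractError("counts shape does not match roi_order")
        if not np.array_equal(self.counts, self.counts.T):
            raise DataContractError("connectome matrix must be symmetric")
        if np.any(np.diag(self.counts) != 0):
            raise DataContractError("connectome matrix must have a zero diagonal")
        if np.any(self.counts < 0):
            raise DataContractError("connectome counts must be nonnegative")
        self._index = {lab: i for i, lab in enumerate(self.roi_order)}

    def get(self, a: int, b: int) -> int:
        return int(self.counts[self._index[a], self._index[b]])

    def total(self) -> int:
        """Number of counted streamlines (each contributes to one link)."""
        return int(self.counts.sum() // 2)

    def subtract(self, other: "ConnectomeMatrix") -> "ConnectomeMatrix":
        """Entrywise ``self - other``; negative results violate the contract."""
        if self.roi_order != other.roi_order:
            raise DataContractError("ROI orders differ; matrices are not comparable")
        diff = self.counts - other.counts
        if np.any(diff < 0):
            raise DataContractError(
                "negative disconnection count: the spared matrix was not derived "
                "from this normative connectome"
            )
        return ConnectomeMatrix(diff, list(self.roi_order))

    def to_dataframe(self, names: dict[int, str] | None = None) -> pd.DataFrame:
        idx = [names[l] if names else l for l in self.roi_order]
        return pd.DataFrame(self.counts, index=idx, columns=idx)

    def save_csv(self, path: str | Path, names: dict[int, str] | None = None) -> None:
        self.to_dataframe(names).to_csv(path)


# ---------------------------------------------------------------------------
# Point / endpoint / traversal primitives
# ---------------------------------------------------------------------------

def label_at_point(parcellation: Parcellation, point_mm: np.ndarray) -> int | None:
    """Label of the voxel containing ``point_mm``; None if background/out of bounds."""
    ijk = np.round(parcellation.mm_to_voxel(point_mm)[0]).astype(int)
    if np.any(ijk < 0) or np.any(ijk >= np.array(parcellation.shape)):
        return None
    lab = int(parcellation.labels[tuple(ijk)])
    return lab if lab != 0 else None


def assign_endpoint(
    parcellation: Parcellation,
    endpoint_mm: np.ndarray,
    radius_mm: float = DEFAULT_RADIUS_MM,
) -> int | None:
    """Assign a streamline endpoint to an ROI by radial search.

    A direct hit (the endpoint's own voxel is labeled) short-circuits the
    search. Otherwise the labeled voxel whose *centre* is nearest to the
    endpoint in mm wins, provided that distance is <= ``radius_mm``;
    equidistant candidates are broken towards the smallest label.
    """
    direct = label_at_point(parcellation, endpoint_mm)
    if direct is not None:
        return direct
    if radius_mm < 0:
        raise DataContractError("radius_mm must be >= 0")
    point = np.asarray(endpoint_mm, dtype=float).reshape(3)
    c = parcellation.mm_to_voxel(point)[0]
    vs = parcellation.voxel_size
    shape = np.array(parcellation.shape)
    lo = np.maximum(np.ceil(c - radius_mm / vs).astype(int), 0)
    hi = np.minimum(np.floor(c + radius_mm / vs).astype(int), shape - 1)
    if np.any(lo > hi):
        return None
    ranges = [np.arange(lo[k], hi[k] + 1) for k in range(3)]
    cand = np.array(list(product(*ranges)), dtype=int)
    labs = parcellation.labels[cand[:, 0], cand[:, 1], cand[:, 2]]
    labeled = labs != 0
    if not labeled.any():
        return None
    cand, labs = cand[labeled], labs[labeled]
    centres = parcellation.voxel_to_mm(cand)
    d = np.linalg.norm(centres - point, axis=1)
    within = d <= radius_mm
    if not within.any():
        return None
    d, labs = d[within], labs[within]
    dmin = d.min()
    # ties at the minimal distance resolve to the smallest label
    return int(labs[np.isclose(d, dmin)].min())


def _exact_voxel_samples(v: np.ndarray) -> np.ndarray:
    """Sample points covering every voxel a polyline passes through.

    ``v`` is the polyline in continuous voxel coordinates with segments no
    longer than half a voxel per axis (voxel *i* spans [i-0.5, i+0.5), so a
    segment then crosses at most one boundary plane per axis). The returned
    samples are the vertices plus one interior point for every region the
    boundary crossings cut each segment into — rounding them enumerates the
    visited voxels exactly, with no step-size tunnelling at corner clips.
    """
    if len(v) < 2:
        return v
    p, q = v[:-1], v[1:]
    d = q - p
    rp, rq = np.round(p), np.round(q)
    crosses = rp != rq
    boundary = np.maximum(rp, rq) - 0.5
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(crosses, (boundary - p) / d, np.inf)
    # per segment: sorted crossing parameters bracketed by the endpoints
    ts = np.concatenate(
        [np.zeros((len(p), 1)), np.sort(t, axis=1), np.ones((len(p), 1))], axis=1
    )
    mids = 0.5 * (ts[:, :-1] + ts[:, 1:])
    finite = np.isfinite(mids) & (mids > 0.0) & (mids < 1.0)
    seg_idx, mid_idx = np.nonzero(finite)
    interior = p[seg_idx] + mids[seg_idx, mid_idx, None] * d[seg_idx]
    return np.vstack([v, interior])


def polyline_voxel_points(
    parcellation: Parcellation, streamline: Streamline
) -> np.ndarray:
    """Voxel-coordinate sample points visiting every voxel on the path."""
    sl = np.asarray(streamline, dtype=float)
    step = 0.5 * float(parcellation.voxel_size.min())
    v = parcellation.mm_to_voxel(densify(sl, step))
    return _exact_voxel_samples(v)


def traversed_rois(
    parcellation: Parcellation,
    streamline: Streamline,
    radius_mm: float = DEFAULT_RADIUS_MM,
) -> set[int]:
    """Distinct ROIs a streamline runs through, endpoint assignments included.

    The polyline is densified to at most half the smallest voxel dimension
    between samples and voxel-boundary crossings are added analytically, so
    the label set is exact — thin regions cannot be tunnelled through.
    """
    sl = np.asarray(streamline, dtype=float)
    ijk = np.round(polyline_voxel_points(parcellation, sl)).astype(int)
    shape = np.array(parcellation.shape)
    ok = np.all((ijk >= 0) & (ijk < shape), axis=1)
    sel = ijk[ok]
    labs = parcellation.labels[sel[:, 0], sel[:, 1], sel[:, 2]]
    hit = set(int(l) for l in np.unique(labs) if l != 0)
    for endpoint in (sl[0], sl[-1]):
        lab = assign_endpoint(parcellation, endpoint, radius_mm)
        if lab is not None:
            hit.add(lab)
    return hit


def streamline_links(
    parcellation: Parcellation,
    streamlines: Streamlines,
    radius_mm: float = DEFAULT_RADIUS_MM,
    max_rois: int = DEFAULT_MAX_ROIS,
) -> list[tuple[int, int] | None]:
    """Per-streamline link assignment under the endpoint and traversal rules.

    Returns, for each streamline, the unordered ROI pair ``(a, b)`` with
    ``a < b`` it connects, or None if the streamline is excluded (unassigned
    endpoint, identical endpoint labels, or more than ``max_rois`` distinct
    ROIs traversed). The assignment of one streamline never depends on any
    other, which is what makes lesion-spared counting a pure subset count.
    """
    out: list[tuple[int, int] | None] = []
    for sl in streamlines:
        sl = np.asarray(sl, dtype=float)
        a = assign_endpoint(parcellation, sl[0], radius_mm)
        b = assign_endpoint(parcellation, sl[-1], radius_mm)
        if a is None or b is None or a == b:
            out.append(None)
            continue
        if len(traversed_rois(parcellation, sl, radius_mm)) > max_rois:
            out.append(None)
            continue
        out.append((min(a, b), max(a, b)))
    return out


def counts_from_links(
    links: list[tuple[int, int] | None], roi_order: list[int]
) -> ConnectomeMatrix:
    """Aggregate per-streamline link assignments into a symmetric count matrix."""
    index = {lab: i for i, lab in enumerate(roi_order)}
    n = len(roi_order)
    counts = np.zeros((n, n), dtype=np.int64)
    for link in links:
        if link is None:
            continue
        i, j = index[link[0]], index[link[1]]
        counts[i, j] += 1
        counts[j, i] += 1
    return ConnectomeMatrix(counts, list(roi_order))


def build_connectome(
    parcellation: Parcellation,
    streamlines: Streamlines,
    radius_mm: float = DEFAULT_RADIUS_MM,
    max_rois: int = DEFAULT_MAX_ROIS,
) -> ConnectomeMatrix:
    """Symmetric ROI x ROI streamline-count matrix.

    A streamline contributes +1 to link (A, B) iff its endpoints assign to two
    distinct ROIs and it traverses at most ``max_rois`` distinct ROIs in
    total. Counts are raw; an empty tractogram yields an all-zero matrix.
    """
    links = streamline_links(parcellation, streamlines, radius_mm, max_rois)
    return counts_from_links(links, parcellation.roi_labels)
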