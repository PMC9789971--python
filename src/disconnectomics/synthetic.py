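"""Synthetic cohorts with known ground-truth critical links.

Real lesion-symptom datasets are protected clinical data, so every stage of
the pipeline is exercised on a fully synthetic, seeded cohort instead: a toy
block parcellation, bundle-structured streamlines routed through white-matter
corridors, ellipsoidal "stroke" lesions confined to right/midline territory,
and behavioural scores generated as a noisy linear function of the
disconnection *fraction* of a designated set of critical links. Because the
generative model is known exactly, downstream inference can be scored for
ground-truth recovery and type-I error.

Geometry. ROIs are solid cubic blocks on a lattice, separated by unlabeled
gap corridors; each hemisphere occupies its own slab of x columns, so any
plane through a gap band is guaranteed background. Streamline bundles run
from a start ROI down into the gap band beneath it, across gap planes via a
central interhemispheric shaft, and up into the end ROI — so with zero
wobble a bundle traverses exactly its two endpoint ROIs and the connectome
reproduces the bundle specification exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .behavior import BehaviorRecord, CancellationSheet, record_from_sheets
from .connectome import ConnectomeMatrix
from .disconnectome import CohortDisconnectomePipeline, LesionMask
from .errors import ConfigurationError, DataContractError, EmptyLesionError
from .parcellation import Parcellation
from .tractogram import Streamlines, densify, save_tck

Link = tuple[int, int]


@dataclass
class GroundTruth:
    """The generative model behind a synthetic cohort's behaviour.

    The raw severity of patient *i* is ``sum_link w_link * fraction_i,link``
    plus Gaussian noise, clipped to [0, 1] — the premise under test being
    that network damage, not focal damage per se, predicts severity.
    """

    critical_links: set[Link]
    effect_weights: dict[Link, float]
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        self.critical_links = {(min(a, b), max(a, b)) for a, b in self.critical_links}
        self.effect_weights = {
            (min(a, b), max(a, b)): float(w) for (a, b), w in self.effect_weights.items()
        }
        if set(self.effect_weights) != self.critical_links:
            raise ConfigurationError("effect_weights keys must equal critical_links")
        if any(w <= 0 for w in self.effect_weights.values()):
            raise ConfigurationError("effect weights must be strictly positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    def to_json(self) -> dict:
        return {
            "critical_links": sorted(map(list, self.critical_links)),
            "effect_weights": {f"{a}-{b}": w for (a, b), w in sorted(self.effect_weights.items())},
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "GroundTruth":
        weights = {
            tuple(int(x) for x in k.split("-")): float(v)
            for k, v in obj["effect_weights"].items()
        }
        return cls(
            critical_links={tuple(l) for l in obj["critical_links"]},
            effect_weights=weights,
            noise_sd=float(obj["noise_sd"]),
            seed=int(obj["seed"]),
        )


# ---------------------------------------------------------------------------
# Parcellation
# ---------------------------------------------------------------------------

def make_parcellation(
    n_right_rois: int,
    n_left_rois: int,
    voxel_size_mm: float = 2.0,
    seed: int = 0,
    shape: tuple[int, int, int] | None = None,
    block: int = 3,
    gap: int = 3,
) -> Parcellation:
    """Toy parcellation: cubic ROI blocks on a lattice with gap corridors.

    Right-hemisphere ROIs occupy the high-x columns, left the low-x columns;
    label 0 is background / white matter. The default (``shape=None``) layout
    is a single z layer of blocks — every block then borders the same two
    global gap planes, through which the streamline router draws its
    corridors. If ``shape`` is given, an unpackable request raises a
    configuration error. The affine is diagonal, with x = 0 mm on the
    interhemispheric midline (the gap between the two hemisphere slabs).
    """
    if n_right_rois < 4 or n_left_rois < 2:
        raise ConfigurationError("need n_right_rois >= 4 and n_left_rois >= 2")
    if voxel_size_mm <= 0:
        raise ConfigurationError("voxel_size_mm must be positive")
    pitch = block + gap
    if shape is None:
        ny = int(np.ceil(np.sqrt(max(n_right_rois, n_left_rois))))
        cx_left = int(np.ceil(n_left_rois / ny))
        cx_right = int(np.ceil(n_right_rois / ny))
        nz = 1
        shape = (
            gap + (cx_left + cx_right) * pitch,
            gap + ny * pitch,
            gap + nz * pitch,
        )
        left_cols = list(range(cx_left))
        right_cols = list(range(cx_left, cx_left + cx_right))
        nx = cx_left + cx_right
    else:
        ncols = [(shape[k] - gap) // pitch for k in range(3)]
        if min(ncols) < 1 or ncols[0] < 2:
            raise ConfigurationError(f"volume {shape} too small for two hemispheres")
        nx, ny, nz = ncols
        left_cols = list(range(nx // 2))
        right_cols = list(range(nx // 2, nx))
        if len(left_cols) * ny * nz < n_left_rois or len(right_cols) * ny * nz < n_right_rois:
            raise ConfigurationError(
                f"cannot pack {n_left_rois} left + {n_right_rois} right ROIs "
                f"into a {shape} volume with block {block}, gap {gap}"
            )
    col_starts = [gap + k * pitch for k in range(nx)]
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=np.int64)
    names: dict[int, str] = {}
    hemisphere: dict[int, str] = {}

    def sites(cols: list[int]) -> list[tuple[int, int, int]]:
        out = [
            (col_starts[cx], gap + iy * pitch, gap + iz * pitch)
            for cx in cols
            for iy in range(ny)
            for iz in range(nz)
        ]
        order = rng.permutation(len(out))
        return [out[i] for i in order]

    next_label = 1
    for hemi, count, cols, prefix in (
        ("right", n_right_rois, right_cols, "R"),
        ("left", n_left_rois, left_cols, "L"),
    ):
        for k, (x0, y0, z0) in enumerate(sites(cols)[:count]):
            labels[x0 : x0 + block, y0 : y0 + block, z0 : z0 + block] = next_label
            names[next_label] = f"{prefix}{k + 1:02d}"
            hemisphere[next_label] = hemi
            next_label += 1
    vs = float(voxel_size_mm)
    affine = np.diag([vs, vs, vs, 1.0])
    # midline (x = 0) sits in the gap between the hemisphere slabs
    midline_idx = col_starts[len(left_cols)] - 0.5 * gap
    affine[0, 3] = -midline_idx * vs
    affine[1:3, 3] = -0.5 * (np.array(shape[1:]) - 1) * vs
    return Parcellation(labels=labels, affine=affine, names=names, hemisphere=hemisphere)


# ---------------------------------------------------------------------------
# Tractogram
# ---------------------------------------------------------------------------

def _empty_bands(labels: np.ndarray, axis: int) -> list[tuple[int, int]]:
    """Index ranges [start, stop) along ``axis`` where the volume is all background."""
    axes = tuple(k for k in range(3) if k != axis)
    occupied = labels.any(axis=axes)
    bands = []
    start = None
    for i, occ in enumerate(occupied):
        if not occ and start is None:
            start = i
        elif occ and start is not None:
            bands.append((start, i))
            start = None
    if start is not None:
        bands.append((start, len(occupied)))
    return bands


def _gap_below(bands: list[tuple[int, int]], lo: int, hi: int) -> float:
    """Centre of the empty band adjacent below [lo, hi]; above as fallback."""
    below = [b for b in bands if b[1] <= lo]
    if below:
        s, t = max(below, key=lambda b: b[1])
    else:
        above = [b for b in bands if b[0] > hi]
        if not above:
            raise ConfigurationError("no background corridor next to ROI block")
        s, t = min(above, key=lambda b: b[0])
    return 0.5 * (s + t - 1)


def _adjacent_gaps(
    bands: list[tuple[int, int]], lo: int, hi: int
) -> list[float]:
    """Centres of the empty bands adjacent below and above [lo, hi] (1-2 values)."""
    out = []
    below = [b for b in bands if b[1] <= lo]
    if below:
        s, t = max(below, key=lambda b: b[1])
        out.append(0.5 * (s + t - 1))
    above = [b for b in bands if b[0] > hi]
    if above:
        s, t = min(above, key=lambda b: b[0])
        out.append(0.5 * (s + t - 1))
    if not out:
        raise ConfigurationError("no background corridor next to ROI block")
    return out


def make_tractogram(
    parcellation: Parcellation,
    bundle_spec: dict[Link, int],
    wobble_sd_mm: float = 0.5,
    seed: int = 0,
) -> Streamlines:
    """Bundle-structured streamlines connecting specified ROI pairs.

    Each bundle (A, B) descends from A into one of the empty gap planes
    adjacent to the blocks (below or above, chosen per bundle so bundles
    sharing an ROI fan out over distinct corridors), runs as a straight
    chord through that all-background plane to beneath B, and ascends into
    B. Planes through a gap band are background at every (x, y) by
    construction, so with zero wobble a streamline traverses exactly its
    two endpoint ROIs; if A and B sit next to different gap planes the chord
    transfers between them through the interhemispheric x-gap shaft, which
    is likewise all background.

    Streamline endpoints are random voxel centres inside the ROIs; the
    corridor waypoints are canonical per bundle and jittered per streamline
    by ``wobble_sd_mm`` (keep it small relative to the half-gap, ~3 mm at
    defaults, so streamlines do not stray into third ROIs). Vertex spacing
    after densification is at most half the smallest voxel dimension.
    """
    if wobble_sd_mm < 0:
        raise ConfigurationError("wobble_sd_mm must be >= 0")
    labels = parcellation.labels
    present = set(parcellation.roi_labels)
    for a, b in bundle_spec:
        if a not in present or b not in present:
            raise ConfigurationError(f"bundle pair ({a}, {b}) not in the parcellation")
    rng = np.random.default_rng(seed)
    x_bands = _empty_bands(labels, axis=0)
    z_bands = _empty_bands(labels, axis=2)
    centre_x = 0.5 * (labels.shape[0] - 1)
    if not x_bands:
        raise ConfigurationError("no interhemispheric shaft in the parcellation")
    xs = min(
        (0.5 * (s + t - 1) for s, t in x_bands), key=lambda c: abs(c - centre_x)
    )
    # per-ROI geometry: voxel list, block centre, adjacent gap planes
    geo: dict[int, tuple[np.ndarray, np.ndarray, list[float]]] = {}
    for lab in present:
        vox = np.argwhere(labels == lab)
        centre = vox.mean(axis=0)
        gaps = _adjacent_gaps(z_bands, int(vox[:, 2].min()), int(vox[:, 2].max()))
        geo[lab] = (vox, centre, gaps)
    step_mm = 0.4 * float(parcellation.voxel_size.min())
    streamlines: Streamlines = []
    for (a, b), count in sorted(bundle_spec.items()):
        if count < 0:
            raise ConfigurationError("bundle counts must be >= 0")
        vox_a, ca, gaps_a = geo[a]
        vox_b, cb, gaps_b = geo[b]
        side = int(rng.integers(2))  # below or above, per bundle
        zga = gaps_a[side % len(gaps_a)]
        zgb = gaps_b[side % len(gaps_b)]
        if zga == zgb:
            waypoints = np.array(
                [[ca[0], ca[1], zga], [cb[0], cb[1], zgb]]
            )
        else:  # transfer between gap planes through the x-gap shaft
            waypoints = np.array(
                [
                    [ca[0], ca[1], zga],
                    [xs, ca[1], zga],
                    [xs, cb[1], zgb],
                    [cb[0], cb[1], zgb],
                ]
            )
        for _ in range(count):
            p0 = vox_a[rng.integers(len(vox_a))].astype(float)
            p1 = vox_b[rng.integers(len(vox_b))].astype(float)
            wp = waypoints.copy()
            if wobble_sd_mm > 0:
                wp += rng.normal(
                    0.0, wobble_sd_mm / parcellation.voxel_size, size=wp.shape
                )
            path_vox = np.vstack([p0, wp, p1])
            path_mm = parcellation.voxel_to_mm(path_vox)
            streamlines.append(densify(path_mm, step_mm))
    return streamlines


# ---------------------------------------------------------------------------
# Lesions
# ---------------------------------------------------------------------------

def make_lesion(
    parcellation: Parcellation,
    center_mm: np.ndarray,
    radii_mm: np.ndarray,
    seed: int = 0,
    roughen_sd: float = 0.0,
    patient_id: str = "lesion",
    right_only: bool = False,
) -> LesionMask:
    """Ellipsoidal binary lesion on the parcellation grid.

    A voxel is lesioned when its centre lies inside the ellipsoid
    ``sum(((p - center) / radii)^2) <= 1`` (optionally surface-roughened by
    Gaussian noise on that quadratic form). ``right_only`` additionally clips
    the mask to x >= 0 mm, the right/midline territory. An empty result
    raises ``EmptyLesionError``.
    """
    center = np.asarray(center_mm, dtype=float).reshape(3)
    radii = np.asarray(radii_mm, dtype=float).reshape(3)
    if np.any(radii <= 0):
        raise ConfigurationError("lesion radii must be positive")
    shape = parcellation.shape
    idx = np.indices(shape).reshape(3, -1).T
    centres = parcellation.voxel_to_mm(idx)
    q = np.sum(((centres - center) / radii) ** 2, axis=1)
    if roughen_sd > 0:
        rng = np.random.default_rng(seed)
        q = q + rng.normal(0.0, roughen_sd, size=q.shape)
    inside = q <= 1.0
    if right_only:
        inside &= centres[:, 0] >= 0.0
    mask = inside.reshape(shape)
    if not mask.any():
        raise EmptyLesionError(
            f"lesion at {center.tolist()} with radii {radii.tolist()} covers no voxel"
        )
    return LesionMask(mask=mask, affine=parcellation.affine, patient_id=patient_id)


# ---------------------------------------------------------------------------
# Behaviour
# ---------------------------------------------------------------------------

def _sheets_for_score(
    severity: float, rng: np.random.Generator
) -> list[CancellationSheet]:
    """Expand a severity score into plausible letter + bells response sheets.

    Detection probability falls off for targets left of a severity-dependent
    attentional border (a logistic in normalised horizontal position), so a
    severity of 0 detects everything and high severities cancel only the
    right of the sheet. The sheet CoC is monotone in, but not identical to,
    the generating severity.
    """
    sheets = []
    for task, n in (("letter", 60), ("bells", 35)):
        x = np.linspace(-90.0, 90.0, n)
        y = rng.uniform(-130.0, 130.0, size=n)
        u = -1.0 + 2.0 * (x - x.min()) / (x.max() - x.min())
        # attentional border slides rightward with severity; the -1.4 offset
        # puts it left of the sheet at severity 0 so everything is detected
        border = 2.4 * severity - 1.4
        p_detect = 1.0 / (1.0 + np.exp(-(u - border) / 0.12))
        detected = rng.random(n) < p_detect
        if not detected.any():
            detected[np.argmax(u)] = True  # severely biased patients still mark the rightmost target
        sheets.append(CancellationSheet(task, x, y, detected))
    return sheets


def simulate_behaviour(
    disconnectome_fractions: list[dict[Link, float]],
    ground_truth: GroundTruth,
    expand_sheets: bool = False,
) -> list[BehaviorRecord]:
    """Generate behavioural records from critical-link disconnection fractions.

    Patient *i*'s raw severity is ``sum_link w_link * fraction_i,link`` plus
    ``Normal(0, noise_sd^2)`` noise, clipped to [0, 1] and stored as the
    compound CoC (identically as both per-task scores). With
    ``expand_sheets`` the severity is instead expanded into synthetic
    cancellation sheets which are then scored through the CoC machinery.
    """
    rng = np.random.default_rng(ground_truth.seed)
    records = []
    for i, fractions in enumerate(disconnectome_fractions):
        for link in ground_truth.critical_links:
            if link not in fractions:
                raise DataContractError(f"patient {i}: missing fraction for link {link}")
        for link, f in fractions.items():
            if not 0.0 <= f <= 1.0:
                raise DataContractError(
                    f"patient {i}: fraction {f} for link {link} outside [0, 1]"
                )
        signal = sum(
            ground_truth.effect_weights[link] * fractions[link]
            for link in sorted(ground_truth.critical_links)
        )
        noise = rng.normal(0.0, ground_truth.noise_sd) if ground_truth.noise_sd else 0.0
        score = float(np.clip(signal + noise, 0.0, 1.0))
        pid = f"patient_{i:03d}"
        if expand_sheets:
            records.append(record_from_sheets(pid, _sheets_for_score(score, rng)))
        else:
            records.append(BehaviorRecord.from_task_scores(pid, score, score))
    return records


# ---------------------------------------------------------------------------
# Whole cohorts
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """A complete synthetic study: anatomy, tractogram, lesions, behaviour."""

    parcellation: Parcellation
    streamlines: Streamlines
    lesions: list[LesionMask]
    behaviour: list[BehaviorRecord]
    ground_truth: GroundTruth
    bundle_spec: dict[Link, int] = field(default_factory=dict)
    normative: ConnectomeMatrix | None = None
    disconnectomes: list[ConnectomeMatrix] | None = None

    def __post_init__(self) -> None:
        if len(self.lesions) != len(self.behaviour):
            raise DataContractError("one behaviour record per lesion is required")

    @property
    def n_patients(self) -> int:
        return len(self.lesions)


def _derive_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31))


def make_cohort(
    n_patients: int = 50,
    n_right_rois: int = 12,
    n_left_rois: int = 6,
    voxel_size_mm: float = 2.0,
    n_links: int = 30,
    streamlines_per_bundle: tuple[int, int] = (30, 60),
    n_critical_links: int = 4,
    effect_weight_total: float = 1.2,
    noise_sd: float | None = None,
    target_r2: float = 0.5,
    wobble_sd_mm: float = 0.3,
    lesion_radii_mm: tuple[float, float] = (2.0, 4.0),
    blobs_per_lesion: tuple[int, int] = (2, 4),
    allow_left_lesions: bool = False,
    null_behaviour: bool = False,
    expand_sheets: bool = False,
    block: int = 3,
    gap: int = 4,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate a seeded end-to-end cohort with recoverable critical links.

    Bundles connect ``n_links`` random right-right and interhemispheric ROI
    pairs. Each patient's lesion is multifocal — ``blobs_per_lesion`` small
    ellipsoids centred on mid-corridor points of randomly chosen bundles
    (embolic-shower style), clipped to right/midline territory — so the
    links a lesion disconnects vary nearly independently across bundles and
    the cohort design matrix is well conditioned. Lesion placement never
    looks at the ground truth.

    ``n_critical_links`` right-right links are then designated critical by
    an identifiability screen: links disconnected in enough patients, ranked
    by the share of their disconnection variance not explained by the other
    candidate links, taken node-disjoint so no single lesion confounds two
    critical links. Their effect weights equalise per-link variance
    contributions and sum to ``effect_weight_total`` (default 1.2: a patient
    with the whole critical set destroyed saturates the CoC scale).
    Behavioural severity is the weighted sum of critical disconnection
    fractions plus Gaussian noise, clipped to [0, 1]. If ``noise_sd`` is
    omitted it is set from ``target_r2``, the fraction of score variance the
    critical links explain under the generative model. ``null_behaviour``
    severs the link between anatomy and behaviour (scores are pure noise
    around the cohort signal mean) for type-I-error studies.

    The cohort is a pure function of ``seed`` and the parameters.
    """
    if n_patients < 1:
        raise ConfigurationError("n_patients must be >= 1")
    master = np.random.default_rng(_derive_seed(seed, 0))
    parcellation = make_parcellation(
        n_right_rois, n_left_rois, voxel_size_mm, seed=_derive_seed(seed, 1),
        block=block, gap=gap,
    )
    right = [l for l, h in parcellation.hemisphere.items() if h == "right"]
    left = [l for l, h in parcellation.hemisphere.items() if h == "left"]
    rr_pairs = [
        (a, b) for i, a in enumerate(sorted(right)) for b in sorted(right)[i + 1 :]
    ]
    rl_pairs = [(min(a, b), max(a, b)) for a in right for b in left]
    candidates = rr_pairs + rl_pairs
    if n_links > len(candidates):
        raise ConfigurationError(
            f"requested {n_links} links but only {len(candidates)} ROI pairs exist"
        )
    # right-right pairs first in the candidate list: sample criticals from them
    chosen_idx = master.choice(len(candidates), size=n_links, replace=False)
    chosen = [candidates[i] for i in sorted(chosen_idx)]
    chosen_rr = [p for p in chosen if p in set(rr_pairs)]
    if len(chosen_rr) < n_critical_links:
        raise ConfigurationError(
            "not enough right-right bundles to host the critical links; "
            "increase n_links or n_right_rois"
        )
    lo, hi = streamlines_per_bundle
    bundle_spec = {
        pair: int(master.integers(lo, hi + 1)) for pair in chosen
    }
    streamlines = make_tractogram(
        parcellation, bundle_spec, wobble_sd_mm=wobble_sd_mm, seed=_derive_seed(seed, 2)
    )
    # lesions: ellipsoids centred on random streamline points in right territory
    lesion_rng = np.random.default_rng(_derive_seed(seed, 3))
    lesions = []
    # candidate centres: mid-corridor streamline points (deep white matter,
    # where bundles are spatially separated) in right territory, grouped per
    # bundle so every link gets comparable lesion exposure. Lesions are placed
    # before and independently of the critical-link designation.
    per_bundle: dict[Link, np.ndarray] = {}
    offset = 0
    for pair in sorted(bundle_spec):
        mids = []
        for sl in streamlines[offset : offset + bundle_spec[pair]]:
            lo, hi = int(0.25 * len(sl)), int(0.75 * len(sl))
            mids.append(sl[lo:hi:5])
        offset += bundle_spec[pair]
        pts = np.vstack(mids) if mids else np.zeros((0, 3))
        pts = pts[pts[:, 0] > 2.0]  # clear of the midline
        if len(pts):
            per_bundle[pair] = pts
    if not per_bundle:
        raise ConfigurationError("no right-territory streamline points to seed lesions")
    all_bundles = sorted(per_bundle)
    blob_lo, blob_hi = blobs_per_lesion
    if not 1 <= blob_lo <= blob_hi:
        raise ConfigurationError("blobs_per_lesion must satisfy 1 <= lo <= hi")
    for i in range(n_patients):
        n_blobs = int(lesion_rng.integers(blob_lo, blob_hi + 1))
        mask = np.zeros(parcellation.shape, dtype=bool)
        placed = 0
        for attempt in range(20 * n_blobs):
            if placed == n_blobs:
                break
            pair = all_bundles[lesion_rng.integers(len(all_bundles))]
            pts = per_bundle[pair]
            centre = pts[lesion_rng.integers(len(pts))]
            radii = lesion_rng.uniform(lesion_radii_mm[0], lesion_radii_mm[1], size=3)
            try:
                blob = make_lesion(
                    parcellation,
                    centre,
                    radii,
                    seed=_derive_seed(seed, 100 + i),
                    patient_id=f"patient_{i:03d}",
                    right_only=not allow_left_lesions,
                )
            except EmptyLesionError:
                continue
            mask |= blob.mask
            placed += 1
        if placed == 0:  # pragma: no cover - geometrically unreachable at sane radii
            raise ConfigurationError(f"could not place a lesion for patient {i}")
        lesions.append(
            LesionMask(mask=mask, affine=parcellation.affine, patient_id=f"patient_{i:03d}")
        )
    pipeline = CohortDisconnectomePipeline(parcellation, streamlines)
    disconnectomes = pipeline.cohort_disconnectomes(lesions)
    # --- critical-link designation -------------------------------------
    # The module's contract is a cohort whose ground truth is *recoverable*:
    # critical links must carry statistically identifiable variation. Since
    # lesions are placed independently of the designation, links can be
    # scored after the fact: a link qualifies if it was disconnected in
    # enough patients, and is ranked by how much of its disconnection
    # variance is unique to it (residual sd after regressing its fraction on
    # every other candidate link). The designated set is node-disjoint and
    # greedily takes the most identifiable links.
    counts = np.array(
        [[d.get(*pair) for pair in chosen] for d in disconnectomes], dtype=float
    )
    norm_counts = np.array([pipeline.normative.get(*p) for p in chosen], dtype=float)
    frac_all = counts / np.where(norm_counts == 0, 1.0, norm_counts)
    min_hits = max(5, int(0.05 * n_patients))
    scores: list[tuple[float, Link]] = []
    for j, pair in enumerate(chosen):
        if pair not in set(rr_pairs):
            continue
        f = frac_all[:, j]
        if (f > 0).sum() < min_hits or f.std() == 0:
            continue
        others = np.delete(counts, j, axis=1)
        design = np.column_stack([np.ones(len(f)), others])
        resid = f - design @ np.linalg.lstsq(design, f, rcond=None)[0]
        scores.append((float(resid.std() / f.std()), pair))
    scores.sort(key=lambda sp: (-sp[0], sp[1]))
    critical: list[Link] = []
    used_nodes: set[int] = set()
    for ratio, pair in scores:
        if pair[0] in used_nodes or pair[1] in used_nodes:
            continue
        critical.append(pair)
        used_nodes.update(pair)
        if len(critical) == n_critical_links:
            break
    for ratio, pair in scores:  # relax node-disjointness if it ran out
        if len(critical) == n_critical_links:
            break
        if pair not in critical:
            critical.append(pair)
    if len(critical) < n_critical_links:
        raise ConfigurationError(
            "fewer identifiable right-right links than requested critical links; "
            "increase n_patients, n_links or lesion sizes"
        )
    critical = sorted(critical)
    fractions = [
        {
            link: d.get(*link) / pipeline.normative.get(*link)
            for link in critical
        }
        for d in disconnectomes
    ]
    # variance-equalised weights: each critical link contributes the same
    # share of severity variance, so no link is statistically privileged.
    # Weight ratios are capped at 3:1 to keep per-link effects plausible.
    F = np.array([[f[link] for link in critical] for f in fractions])
    raw_w = 1.0 / F.std(axis=0)
    raw_w = np.minimum(raw_w, 3.0 * raw_w.min())
    weights = effect_weight_total * raw_w / raw_w.sum()
    signal = np.array(
        [
            sum(w * f[link] for w, link in zip(weights, critical))
            for f in fractions
        ]
    )
    if noise_sd is None:
        sd_sig = float(signal.std())
        if sd_sig == 0.0 or not 0.0 < target_r2 < 1.0:
            noise_sd = 0.05
        else:
            noise_sd = sd_sig * float(np.sqrt((1.0 - target_r2) / target_r2))
    if null_behaviour:
        # behaviour independent of disconnection: same marginal location/scale
        fractions = [
            {link: float(signal.mean() / weights.sum()) for link in critical}
            for _ in fractions
        ]
    ground_truth = GroundTruth(
        critical_links=set(critical),
        effect_weights={link: float(w) for link, w in zip(critical, weights)},
        noise_sd=float(noise_sd),
        seed=_derive_seed(seed, 5),
    )
    behaviour = simulate_behaviour(fractions, ground_truth, expand_sheets=expand_sheets)
    return SyntheticCohort(
        parcellation=parcellation,
        streamlines=streamlines,
        lesions=lesions,
        behaviour=behaviour,
        ground_truth=ground_truth,
        bundle_spec=bundle_spec,
        normative=pipeline.normative,
        disconnectomes=disconnectomes,
    )


# ---------------------------------------------------------------------------
# Cohort I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write every cohort artifact; returns the manifest path.

    Parcellation and lesions go out as NIfTI (uncompressed, so reruns are
    byte-identical), the tractogram as TCK, behaviour as CSV, the ground
    truth as a JSON sidecar, and a manifest listing all relative paths.
    """
    from .behavior import write_records_csv

    out = Path(out_dir)
    (out / "lesions").mkdir(parents=True, exist_ok=True)
    cohort.parcellation.save(out / "parcellation.nii", out / "parcellation_labels.csv")
    save_tck(cohort.streamlines, out / "tractogram.tck")
    lesion_paths = []
    for lesion in cohort.lesions:
        rel = f"lesions/{lesion.patient_id}.nii"
        lesion.save(out / rel)
        lesion_paths.append(rel)
    write_records_csv(cohort.behaviour, out / "behaviour.csv")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(cohort.ground_truth.to_json(), fh, indent=2, sort_keys=True)
    manifest = {
        "parcellation": "parcellation.nii",
        "parcellation_labels": "parcellation_labels.csv",
        "tractogram": "tractogram.tck",
        "lesions": lesion_paths,
        "behaviour": "behaviour.csv",
        "ground_truth": "ground_truth.json",
        "n_patients": cohort.n_patients,
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest_path


def load_cohort(manifest_path: str | Path) -> SyntheticCohort:
    """Reload a cohort from its manifest (inverse of ``write_cohort``)."""
    from .behavior import read_records_csv
    from .tractogram import load_tck

    root = Path(manifest_path).parent
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    parcellation = Parcellation.load(
        root / manifest["parcellation"], root / manifest["parcellation_labels"]
    )
    streamlines = load_tck(root / manifest["tractogram"])
    lesions = [
        LesionMask.load(root / rel, Path(rel).stem) for rel in manifest["lesions"]
    ]
    behaviour = read_records_csv(root / manifest["behaviour"])
    with open(root / manifest["ground_truth"]) as fh:
        ground_truth = GroundTruth.from_json(json.load(fh))
    return SyntheticCohort(
        parcellation=parcellation,
        streamlines=streamlines,
        lesions=lesions,
        behaviour=behaviour,
        ground_truth=ground_truth,
    )
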