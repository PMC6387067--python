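"""Three-stage repair-focus counting on 3D confocal stacks.

Stages
------
1. **Nucleus segmentation** — global Otsu threshold on the Gaussian-smoothed
   chromatin channel, hole filling, small-object removal, then splitting of
   touching nuclei by a watershed on the (anisotropy-aware) Euclidean
   distance transform. The segmenter is pluggable: any callable returning a
   label map can replace the default threshold-based one.
2. **Focus detection** — per-slice maximally stable extremal regions (MSER)
   inside each nucleus bounding box, tuned for high recall, with z-linking
   of slice regions whose footprints overlap into 3D candidates.
3. **Classification** — a maximum-margin linear rule on scale-invariant
   candidate features, with a user-adjustable bias shift controlling
   sensitivity.

Colocalized γH2AX/53BP1 focus pairs (one-to-one greedy matching by centroid
distance, or by overlap fraction) are scored as double-strand breaks.

All intensity criteria are relative (quantile/contrast based), so counting is
invariant to a positive rescaling of the whole stack.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from focirad.datatypes import (
    FOCUS_CHANNELS,
    ConfocalStack,
    DsbCall,
    FocusCall,
    FocusCandidate,
    NucleusLabelMap,
    make_count_record,
)

FEATURE_NAMES = (
    "rel_mean_intensity",   # candidate mean / nucleus median (scale-free)
    "rel_peak_intensity",   # candidate max / nucleus median
    "contrast",             # (mean - local background) / local background
    "log_volume_voxels",
    "log_area_pixels",
    "stability",            # MSER variation (lower = more stable)
)


# ---------------------------------------------------------------------------
# Nucleus segmentation
# ---------------------------------------------------------------------------

def segment_nuclei(
    stack: ConfocalStack,
    min_volume_um3: float = 30.0,
    *,
    smooth_sigma_um: float = 0.5,
    min_separation_um: float = 3.0,
    rng: np.random.Generator | None = None,
) -> NucleusLabelMap:
    """Segment nuclei from the chromatin channel and split touching ones.

    An empty foreground yields an empty label map (no error). ``rng`` is
    accepted for interface symmetry; the default segmenter is deterministic.
    """
    chromatin = stack.require("chromatin").astype(np.float64)
    dz, dy, dx = stack.voxel_size_um
    sigma = (smooth_sigma_um / dz, smooth_sigma_um / dy, smooth_sigma_um / dx)
    smoothed = ndi.gaussian_filter(chromatin, sigma)
    if smoothed.max() <= smoothed.min():
        return NucleusLabelMap(np.zeros(stack.shape, dtype=np.int32), {})
    thr = threshold_otsu(smoothed)
    mask = smoothed > thr
    mask = ndi.binary_fill_holes(mask)

    voxel_vol = dz * dy * dx
    min_vox = max(int(min_volume_um3 / voxel_vol), 1)
    lab, _ = ndi.label(mask)
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_vox
    keep[0] = False
    mask = keep[lab]
    if not mask.any():
        return NucleusLabelMap(np.zeros(stack.shape, dtype=np.int32), {})

    edt = ndi.distance_transform_edt(mask, sampling=(dz, dy, dx))
    edt_s = ndi.gaussian_filter(edt, sigma)
    min_dist_px = max(int(min_separation_um / dx), 1)
    peaks = peak_local_max(
        edt_s, min_distance=min_dist_px, labels=mask, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    markers, _ = ndi.label(markers > 0)
    labels = watershed(-edt_s, markers, mask=mask).astype(np.int32)

    # renumber 1..n and collect tight bounding boxes
    out = np.zeros_like(labels)
    bboxes: dict[int, tuple[slice, slice, slice]] = {}
    objects = ndi.find_objects(labels)
    nid = 0
    for old, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        nid += 1
        out[labels == old] = nid
        bboxes[nid] = sl
    return NucleusLabelMap(out, bboxes)


# ---------------------------------------------------------------------------
# MSER focus detection
# ---------------------------------------------------------------------------

@dataclass
class MserParams:
    """Per-slice MSER detector parameters (high-recall defaults).

    The intensity range inside each nucleus bounding box is quantized into
    ``n_levels`` thresholds; components are tracked across thresholds and a
    component is maximally stable where its relative area change over
    ``delta`` levels is a local minimum not exceeding ``max_variation``.
    """

    n_levels: int = 48
    delta: int = 2
    min_area: int = 4
    max_area: int = 150
    max_variation: float = 1.0
    min_volume_voxels: int = 4
    nms_overlap: float = 0.5  # within-slice suppression of nested regions
    link_overlap: float = 0.3  # z-link needs this footprint overlap (fraction of smaller)
    link_centroid_px: float = 2.5  # ... and lateral centroid distance below this
    merge_break: float = 3.0  # stop the leaf walk when the area jumps by this factor
    split_sigma_px: tuple = (0.5, 1.0, 1.0)  # smoothing before saddle splitting (z, y, x)
    split_footprint: tuple = (3, 4, 4)  # local-maximum separation for splitting
    min_peak_sep_um: float = 0.55  # split seeds closer than this are one focus


def _mser_slice(img: np.ndarray, p: MserParams) -> list[tuple[np.ndarray, float]]:
    """MSER regions of one 2D slice.

    Returns a list of ``(boolean mask, variation)`` pairs. Implemented as a
    quantized threshold sweep: at each level the bright components of
    ``img >= thr`` are labeled; a component at level l is linked to the
    component at level l-1 containing it, and stability is the relative area
    growth over ``delta`` levels down the threshold chain.
    """
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return []
    thresholds = np.linspace(lo, hi, p.n_levels + 2)[1:-1]  # exclude min/max
    L = len(thresholds)
    labels_per_level = []
    areas_per_level = []
    for thr in thresholds:
        lab, n = ndi.label(img >= thr)
        labels_per_level.append(lab)
        areas_per_level.append(np.bincount(lab.ravel(), minlength=n + 1))

    # parent[l][c] = component id at level l-1 that contains component c of level l
    parents = [None]
    for l in range(1, L):
        lab_hi = labels_per_level[l]
        lab_lo = labels_per_level[l - 1]
        n_hi = areas_per_level[l].shape[0]
        par = np.zeros(n_hi, dtype=np.int32)
        flat_hi = lab_hi.ravel()
        nz = flat_hi > 0
        # any pixel of the child also carries the parent label
        np.maximum.at(par, flat_hi[nz], lab_lo.ravel()[nz])
        parents.append(par)

    # area of the ancestor `delta` levels down (towards lower thresholds)
    variations = []
    for l in range(L):
        areas = areas_per_level[l].astype(np.float64)
        n = areas.shape[0]
        if l - p.delta < 0:
            variations.append(np.full(n, np.inf))
            continue
        anc = np.arange(n, dtype=np.int32)
        for step in range(p.delta):
            anc = parents[l - step][anc]
        anc_area = areas_per_level[l - p.delta][anc].astype(np.float64)
        with np.errstate(divide="ignore", invalid="ignore"):
            var = (anc_area - areas) / np.maximum(areas, 1)
        var[0] = np.inf
        variations.append(var)

    # leaves of the component tree = brightest cores (typically one per focus)
    has_child = [np.zeros(a.shape[0], dtype=bool) for a in areas_per_level]
    for l in range(1, L):
        existing = np.nonzero(areas_per_level[l][1:])[0] + 1
        has_child[l - 1][parents[l][existing]] = True

    # walk each leaf down its threshold chain; emit the most stable node,
    # stopping at a merge event (area jump) or the area ceiling
    selected: list[tuple[int, int, float]] = []
    for l in range(L - 1, -1, -1):
        for c in np.nonzero(areas_per_level[l][1:])[0] + 1:
            if has_child[l][c]:
                continue
            j, cj = l, int(c)
            prev_area = int(areas_per_level[j][cj])
            best = None
            while True:
                a = int(areas_per_level[j][cj])
                if a > p.max_area:
                    break
                if prev_area >= p.min_area and a > p.merge_break * prev_area:
                    break
                v = float(variations[j][cj])
                if a >= p.min_area and np.isfinite(v) and v <= p.max_variation:
                    if best is None or v < best[2]:
                        best = (j, cj, v)
                prev_area = a
                if j == 0:
                    break
                cj = int(parents[j][cj])
                j -= 1
            if best is not None:
                selected.append(best)

    # within-slice suppression of nested/overlapping selections: accept the
    # compact cores first so that a merged super-region covering several
    # cores is rejected rather than suppressing them
    selected.sort(key=lambda t: (areas_per_level[t[0]][t[1]], t[2]))
    accepted_masks: list[np.ndarray] = []
    out = []
    covered = np.zeros(img.shape, dtype=bool)
    for l, c, v in selected:
        mask = labels_per_level[l] == c
        area = int(mask.sum())
        if area == 0:
            continue
        if covered[mask].sum() > p.nms_overlap * area:
            continue
        covered |= mask
        out.append((mask, v))
    return out


def detect_candidates(
    stack: ConfocalStack,
    label_map: NucleusLabelMap,
    nucleus_id: int,
    channel: str,
    mser_params: MserParams | None = None,
) -> list[FocusCandidate]:
    """Detect 3D focus candidates inside one nucleus bounding box.

    Per-slice MSER regions are linked across z when their footprints overlap;
    the resulting voxel sets are clipped to the nucleus mask.
    """
    if channel not in FOCUS_CHANNELS:
        raise ValueError(f"channel must be one of {FOCUS_CHANNELS}, got {channel!r}")
    p = mser_params or MserParams()
    if nucleus_id not in label_map.bboxes:
        raise KeyError(f"nucleus id {nucleus_id} not present")
    box = label_map.bboxes[nucleus_id]
    img3 = stack.require(channel).astype(np.float64)[box]
    nuc_mask = label_map.labels[box] == nucleus_id

    # per-slice regions: (z, footprint mask, variation)
    slice_regions: list[tuple[int, np.ndarray, float]] = []
    for z in range(img3.shape[0]):
        if not nuc_mask[z].any():
            continue
        for mask2d, v in _mser_slice(img3[z], p):
            mask2d = mask2d & nuc_mask[z]
            if mask2d.sum() >= 1:
                slice_regions.append((z, mask2d, v))
    if not slice_regions:
        return []

    # union-find z-linking by footprint overlap in adjacent slices
    parent = list(range(len(slice_regions)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    by_z: dict[int, list[int]] = {}
    centroids = []
    for idx, (z, mask2d, _) in enumerate(slice_regions):
        by_z.setdefault(z, []).append(idx)
        ys, xs = np.nonzero(mask2d)
        centroids.append((ys.mean(), xs.mean()))
    for z, idxs in by_z.items():
        for i in idxs:
            ai = slice_regions[i][1].sum()
            for dz_link in (1, 2):  # tolerate a one-slice gap in faint foci
                for j in by_z.get(z + dz_link, ()):
                    dc = math.hypot(
                        centroids[i][0] - centroids[j][0],
                        centroids[i][1] - centroids[j][1],
                    )
                    if dc > p.link_centroid_px:
                        continue
                    inter = np.count_nonzero(slice_regions[i][1] & slice_regions[j][1])
                    if inter >= p.link_overlap * min(ai, slice_regions[j][1].sum()):
                        union(i, j)

    groups: dict[int, list[int]] = {}
    for idx in range(len(slice_regions)):
        groups.setdefault(find(idx), []).append(idx)

    def split_group(voxels: np.ndarray) -> list[np.ndarray]:
        """Split a linked voxel set at 3D intensity saddles.

        Two foci stacked in z (or blended laterally) can end up in one
        linked component bridged by faint but stable tail regions; a
        watershed seeded at the local maxima of the smoothed intensity
        separates them.
        """
        z0, y0, x0 = voxels.min(axis=0)
        z1, y1, x1 = voxels.max(axis=0) + 1
        sub = np.zeros((z1 - z0, y1 - y0, x1 - x0), dtype=bool)
        sub[voxels[:, 0] - z0, voxels[:, 1] - y0, voxels[:, 2] - x0] = True
        vals = np.where(sub, img3[z0:z1, y0:y1, x0:x1], 0.0)
        smooth = ndi.gaussian_filter(vals, p.split_sigma_px)
        peaks = peak_local_max(
            smooth, footprint=np.ones(p.split_footprint), labels=sub,
            exclude_border=False,
        )
        if len(peaks) > 1:
            # cluster seeds closer than the resolvable separation so a
            # single focus cannot be split by twin noise peaks
            phys = peaks * np.array([dz, dy, dx])
            order = np.argsort(-smooth[tuple(peaks.T)])
            kept_idx: list[int] = []
            for i in order:
                if all(
                    np.linalg.norm(phys[i] - phys[j]) >= p.min_peak_sep_um
                    for j in kept_idx
                ):
                    kept_idx.append(i)
            peaks = peaks[kept_idx]
        if len(peaks) <= 1:
            return [voxels]
        markers = np.zeros(sub.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        split = watershed(-smooth, markers, mask=sub)
        out = []
        for lab in range(1, len(peaks) + 1):
            zz, yy, xx = np.nonzero(split == lab)
            if len(zz):
                out.append(np.column_stack([zz + z0, yy + y0, xx + x0]))
        return out or [voxels]

    dz, dy, dx = stack.voxel_size_um
    z_off, y_off, x_off = box[0].start, box[1].start, box[2].start
    candidates = []
    for members in groups.values():
        vox_list = []
        variation = np.inf
        for idx in members:
            z, mask2d, v = slice_regions[idx]
            ys, xs = np.nonzero(mask2d)
            vox_list.append(np.column_stack([np.full(len(ys), z), ys, xs]))
            variation = min(variation, v)
        merged = np.concatenate(vox_list)
        # drop duplicate voxels from overlapping same-slice regions
        merged = np.unique(merged, axis=0)
        for voxels in split_group(merged):
            if len(voxels) < p.min_volume_voxels:
                continue
            vals = img3[voxels[:, 0], voxels[:, 1], voxels[:, 2]]
            footprint_px = len(
                np.unique(voxels[:, 1] * img3.shape[2] + voxels[:, 2])
            )
            abs_vox = voxels + np.array([z_off, y_off, x_off])
            centroid = (
                float(abs_vox[:, 0].mean() * dz),
                float(abs_vox[:, 1].mean() * dy),
                float(abs_vox[:, 2].mean() * dx),
            )
            candidates.append(
                FocusCandidate(
                    voxels=abs_vox,
                    centroid_um=centroid,
                    volume_voxels=len(voxels),
                    area_pixels=footprint_px,
                    mean_intensity=float(vals.mean()),
                    stability=float(variation),
                    channel=channel,
                    nucleus_id=nucleus_id,
                )
            )
    candidates.sort(key=lambda c: c.centroid_um)
    return candidates


# ---------------------------------------------------------------------------
# Features and classification
# ---------------------------------------------------------------------------

def extract_features(candidate: FocusCandidate, stack: ConfocalStack,
                     label_map: NucleusLabelMap | None = None) -> np.ndarray:
    """Feature vector for one candidate (order fixed by ``FEATURE_NAMES``).

    Intensity features are normalized by the nucleus median intensity, and
    contrast is measured against a dilated local-background shell, so the
    vector is invariant to a positive rescaling of the stack.
    """
    if len(candidate.voxels) == 0:
        raise ValueError("candidate has an empty voxel set")
    img = stack.require(candidate.channel).astype(np.float64)
    vox = candidate.voxels
    vals = img[vox[:, 0], vox[:, 1], vox[:, 2]]

    # nucleus median as the intensity scale
    if label_map is not None and candidate.nucleus_id in label_map.bboxes:
        box = label_map.bboxes[candidate.nucleus_id]
        nuc_vals = img[box][label_map.labels[box] == candidate.nucleus_id]
        scale = float(np.median(nuc_vals)) if nuc_vals.size else 1.0
    else:
        scale = float(np.median(img))
    scale = max(scale, 1e-9)

    # local background: a shell two dilations around the candidate
    zmin, ymin, xmin = vox.min(axis=0)
    zmax, ymax, xmax = vox.max(axis=0)
    pad = 4
    z0, y0, x0 = max(zmin - pad, 0), max(ymin - pad, 0), max(xmin - pad, 0)
    z1 = min(zmax + pad + 1, img.shape[0])
    y1 = min(ymax + pad + 1, img.shape[1])
    x1 = min(xmax + pad + 1, img.shape[2])
    local = np.zeros((z1 - z0, y1 - y0, x1 - x0), dtype=bool)
    local[vox[:, 0] - z0, vox[:, 1] - y0, vox[:, 2] - x0] = True
    shell = ndi.binary_dilation(local, iterations=3) & ~local
    bg_vals = img[z0:z1, y0:y1, x0:x1][shell]
    bg = float(np.median(bg_vals)) if bg_vals.size else scale
    bg = max(bg, 1e-9)

    contrast = (float(vals.mean()) - bg) / bg
    stability = candidate.stability if np.isfinite(candidate.stability) else 1e3
    return np.array(
        [
            float(vals.mean()) / scale,
            float(vals.max()) / scale,
            contrast,
            np.log1p(candidate.volume_voxels),
            np.log1p(candidate.area_pixels),
            stability,
        ]
    )


@dataclass
class FociClassifier:
    """Standardized maximum-margin linear decision rule over focus features.

    ``margin(x) = w · (x - mu) / sd + b``; a candidate is accepted when
    ``margin + bias_shift > 0``. ``bias_shift`` trades recall against
    precision (+inf accepts everything, -inf nothing).
    """

    weights: np.ndarray
    intercept: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    training_accuracy: float = float("nan")
    feature_names: tuple = FEATURE_NAMES
    version: str = "1"

    def margins(self, features: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        Xs = (X - self.feature_mean) / self.feature_scale
        return Xs @ self.weights + self.intercept

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "feature_names": list(self.feature_names),
                "weights": self.weights.tolist(),
                "intercept": self.intercept,
                "feature_mean": self.feature_mean.tolist(),
                "feature_scale": self.feature_scale.tolist(),
                "training_accuracy": self.training_accuracy,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FociClassifier":
        d = json.loads(text)
        return cls(
            weights=np.array(d["weights"]),
            intercept=float(d["intercept"]),
            feature_mean=np.array(d["feature_mean"]),
            feature_scale=np.array(d["feature_scale"]),
            training_accuracy=float(d.get("training_accuracy", float("nan"))),
            feature_names=tuple(d.get("feature_names", FEATURE_NAMES)),
            version=str(d.get("version", "1")),
        )


def train_classifier(features: np.ndarray, labels: np.ndarray) -> FociClassifier:
    """Fit the linear maximum-margin focus classifier.

    ``labels`` are boolean/0-1 (True = genuine focus). Both classes must be
    present. Features are standardized before fitting.
    """
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import LinearSVC

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be (n, d) with one label per row")
    if len(np.unique(y)) < 2:
        raise ValueError("training needs both positive and negative examples")
    scaler = StandardScaler().fit(X)
    svm = LinearSVC(C=1.0, max_iter=20000).fit(scaler.transform(X), y)
    acc = float(svm.score(scaler.transform(X), y))
    return FociClassifier(
        weights=svm.coef_.ravel().copy(),
        intercept=float(svm.intercept_[0]),
        feature_mean=scaler.mean_.copy(),
        feature_scale=scaler.scale_.copy(),
        training_accuracy=acc,
    )


def classify(
    candidates: list[FocusCandidate],
    features: np.ndarray,
    clf: FociClassifier,
    bias_shift: float = 0.0,
) -> list[FocusCall]:
    """Apply the classifier; acceptance is monotone in ``bias_shift``."""
    if not candidates:
        return []
    margins = clf.margins(features)
    calls = []
    for cand, m in zip(candidates, margins):
        calls.append(
            FocusCall(
                voxels=cand.voxels,
                centroid_um=cand.centroid_um,
                volume_voxels=cand.volume_voxels,
                area_pixels=cand.area_pixels,
                mean_intensity=cand.mean_intensity,
                stability=cand.stability,
                channel=cand.channel,
                nucleus_id=cand.nucleus_id,
                margin=float(m),
                accepted=bool(m + bias_shift > 0),
            )
        )
    return calls


def suppress_duplicate_calls(
    calls: list[FocusCall], radius_um: float = 0.5, z_scale: float = 1.3
) -> list[FocusCall]:
    """Suppress accepted calls closer than ``radius_um`` to a stronger one.

    The high-recall detector may emit several fragments of one focus; among
    accepted calls within the radius only the one with the largest
    classifier margin survives (ties: larger volume). The distance is
    anisotropic: the axial component is divided by ``z_scale`` because the
    axial PSF extent (and hence the z-spread of fragments) exceeds the
    lateral one. Rejected fragments are returned with ``accepted=False``.
    """
    scale = np.array([1.0 / z_scale, 1.0, 1.0])
    accepted = [c for c in calls if c.accepted]
    accepted.sort(key=lambda c: (-c.margin, -c.volume_voxels))
    kept: list[FocusCall] = []
    dropped = set()
    for c in accepted:
        pos = np.array(c.centroid_um) * scale
        if any(
            np.linalg.norm(pos - np.array(k.centroid_um) * scale) < radius_um
            for k in kept
        ):
            dropped.add(id(c))
        else:
            kept.append(c)
    out = []
    for c in calls:
        if id(c) in dropped:
            c = FocusCall(
                voxels=c.voxels, centroid_um=c.centroid_um,
                volume_voxels=c.volume_voxels, area_pixels=c.area_pixels,
                mean_intensity=c.mean_intensity, stability=c.stability,
                channel=c.channel, nucleus_id=c.nucleus_id,
                margin=c.margin, accepted=False,
            )
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# Colocalization matching
# ---------------------------------------------------------------------------

def _overlap_fraction(a: FocusCandidate, b: FocusCandidate) -> float:
    sa = set(map(tuple, a.voxels))
    sb = set(map(tuple, b.voxels))
    inter = len(sa & sb)
    denom = min(len(sa), len(sb))
    return inter / denom if denom else 0.0


def match_colocalized(
    gh2ax: list[FocusCall],
    p53bp1: list[FocusCall],
    *,
    criterion: str = "distance",
    d_max_um: float = 0.5,
    f_min: float = 0.25,
) -> list[DsbCall]:
    """One-to-one greedy matching of accepted γH2AX and 53BP1 foci.

    ``criterion='distance'`` pairs foci with centroid distance <= ``d_max_um``,
    greedily by increasing distance (ties broken by lower γH2AX focus index,
    then lower 53BP1 index); ``criterion='overlap'`` requires an overlap
    fraction (intersection over the smaller volume) >= ``f_min`` and matches
    greedily by decreasing overlap. Each focus joins at most one DSB call.
    """
    if criterion not in ("distance", "overlap"):
        raise ValueError("criterion must be 'distance' or 'overlap'")
    ga = [f for f in gh2ax if f.accepted]
    pa = [f for f in p53bp1 if f.accepted]
    if not ga or not pa:
        return []

    pairs = []
    for i, fg in enumerate(ga):
        for j, fp in enumerate(pa):
            d = float(np.linalg.norm(np.array(fg.centroid_um) - np.array(fp.centroid_um)))
            if criterion == "distance":
                if d <= d_max_um:
                    pairs.append((d, i, j))
            else:
                ov = _overlap_fraction(fg, fp)
                if ov >= f_min:
                    pairs.append((-ov, i, j))
    pairs.sort()
    used_g: set[int] = set()
    used_p: set[int] = set()
    calls = []
    for key, i, j in pairs:
        if i in used_g or j in used_p:
            continue
        used_g.add(i)
        used_p.add(j)
        d = float(np.linalg.norm(np.array(ga[i].centroid_um) - np.array(pa[j].centroid_um)))
        calls.append(
            DsbCall(
                gh2ax_index=i,
                p53bp1_index=j,
                distance_um=d,
                overlap_fraction=_overlap_fraction(ga[i], pa[j]),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Per-nucleus counting
# ---------------------------------------------------------------------------

@dataclass
class PipelineParams:
    """End-to-end counting parameters."""

    mser: MserParams = field(default_factory=MserParams)
    bias_shift: float = 0.0
    criterion: str = "distance"
    d_max_um: float = 0.5
    f_min: float = 0.25
    duplicate_radius_um: float = 0.5
    duplicate_z_scale: float = 1.3


def count_nucleus(
    stack: ConfocalStack,
    label_map: NucleusLabelMap,
    nucleus_id: int,
    clf: FociClassifier,
    params: PipelineParams | None = None,
) -> tuple[dict, dict]:
    """Count DSBs in one nucleus.

    Returns ``(count_record, details)`` where the record is the kinetics row
    (DSB count plus the max-projection pixel areas of the matched γH2AX
    foci) and ``details`` carries the per-channel focus calls and DSB calls.
    """
    params = params or PipelineParams()
    calls = {}
    for channel in FOCUS_CHANNELS:
        cands = detect_candidates(stack, label_map, nucleus_id, channel, params.mser)
        if cands:
            feats = np.array([extract_features(c, stack, label_map) for c in cands])
            raw = classify(cands, feats, clf, params.bias_shift)
            calls[channel] = suppress_duplicate_calls(
                raw, params.duplicate_radius_um, params.duplicate_z_scale
            )
        else:
            calls[channel] = []
    dsbs = match_colocalized(
        calls["gH2AX"],
        calls["p53BP1"],
        criterion=params.criterion,
        d_max_um=params.d_max_um,
        f_min=params.f_min,
    )
    accepted_g = [f for f in calls["gH2AX"] if f.accepted]
    areas = [accepted_g[c.gh2ax_index].area_pixels for c in dsbs]
    voxel_vol = float(np.prod(stack.voxel_size_um))
    record = make_count_record(
        nucleus_id,
        len(dsbs),
        areas,
        dose_gy=stack.meta.get("dose_gy", 0.0),
        t_pi_min=stack.meta.get("t_pi_min", 0.0),
        treatment=stack.meta.get("treatment", "none"),
    )
    record["nucleus_volume_um3"] = float(
        (label_map.labels == nucleus_id).sum() * voxel_vol
    )
    return record, {"calls": calls, "dsbs": dsbs}


def count_stack(
    stack: ConfocalStack,
    clf: FociClassifier,
    params: PipelineParams | None = None,
    *,
    label_map: NucleusLabelMap | None = None,
) -> list[dict]:
    """Segment (unless a label map is supplied) and count every nucleus."""
    if label_map is None:
        label_map = segment_nuclei(stack)
    return [
        count_nucleus(stack, label_map, nid, clf, params)[0] for nid in label_map.ids
    ]
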