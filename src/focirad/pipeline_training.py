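"""Truth-supervised training and scoring utilities for the focus classifier.

These helpers close the loop between the synthetic generator and the
counting pipeline: candidates detected on simulated stacks are labeled by
matching against the generator's true focus positions, a linear SVM is
trained on those labels, and detection performance (recall, precision) is
scored with the same one-to-one matching.
"""

from __future__ import annotations

import numpy as np

from focirad import foci_pipeline as fp
from focirad import synthetic_data as syn
from focirad.datatypes import ConfocalStack, FocusCandidate


def match_candidates_to_truth(
    candidates: list[FocusCandidate],
    truth_foci,
    nucleus_id: int,
    channel: str,
    match_radius_um: float = 0.5,
) -> np.ndarray:
    """Boolean labels: which candidates correspond to a true focus.

    One-to-one greedy matching by centroid distance within
    ``match_radius_um``. For the 53BP1 channel only colocalized ('both')
    truth foci are eligible; for γH2AX every true focus is.
    """
    sub = truth_foci[truth_foci["nucleus_id"] == nucleus_id]
    if channel == "p53BP1":
        sub = sub[sub["channel"] == "both"]
    truth_pos = sub[["z_um", "y_um", "x_um"]].to_numpy()
    labels = np.zeros(len(candidates), dtype=bool)
    if len(candidates) == 0 or len(truth_pos) == 0:
        return labels
    cand_pos = np.array([c.centroid_um for c in candidates])
    pairs = []
    for i in range(len(cand_pos)):
        d = np.linalg.norm(truth_pos - cand_pos[i], axis=1)
        for j in np.nonzero(d <= match_radius_um)[0]:
            pairs.append((d[j], i, int(j)))
    pairs.sort()
    used_c, used_t = set(), set()
    for _, i, j in pairs:
        if i in used_c or j in used_t:
            continue
        used_c.add(i)
        used_t.add(j)
        labels[i] = True
    return labels


def collect_training_set(
    rng: np.random.Generator,
    n_nuclei: int = 12,
    *,
    doses=(0.0, 2.0, 4.0),
    times=(30.0, 60.0, 240.0),
    mser: fp.MserParams | None = None,
):
    """Simulate nuclei over a dose/time grid and label detected candidates.

    Returns ``(features, labels)`` pooled over both focus channels.
    """
    mser = mser or fp.MserParams()
    feats, labels = [], []
    conditions = [(d, t) for d in doses for t in times]
    per = max(n_nuclei // len(conditions), 1)
    for dose, t in conditions:
        stack, truth = syn.simulate_stack(dose, t, per, rng=rng)
        label_map = fp.segment_nuclei(stack)
        for nid in label_map.ids:
            tid = _truth_id(label_map, truth, nid)
            for channel in ("gH2AX", "p53BP1"):
                cands = fp.detect_candidates(stack, label_map, nid, channel, mser)
                if not cands:
                    continue
                y = match_candidates_to_truth(
                    cands, truth.foci, tid, channel, match_radius_um=0.35
                )
                # drop ambiguous near-misses: unmatched fragments of a true
                # focus would otherwise poison the negative class
                sub = truth.foci[truth.foci["nucleus_id"] == tid]
                if channel == "p53BP1":
                    sub = sub[sub["channel"] == "both"]
                tpos = sub[["z_um", "y_um", "x_um"]].to_numpy()
                keep = np.ones(len(cands), dtype=bool)
                if len(tpos):
                    for i, c in enumerate(cands):
                        dmin = np.linalg.norm(tpos - np.array(c.centroid_um), axis=1).min()
                        if not y[i] and dmin < 0.7:
                            keep[i] = False
                X = np.array([fp.extract_features(c, stack, label_map) for c in cands])
                feats.append(X[keep])
                labels.append(y[keep])
    if not feats:
        raise RuntimeError("no candidates detected on the training stacks")
    return np.concatenate(feats), np.concatenate(labels)


def _truth_id(label_map, truth, nucleus_id: int) -> int:
    """Map a segmentation label to the generator nucleus id it covers."""
    mask = label_map.labels == nucleus_id
    vals = truth.nucleus_masks[mask]
    vals = vals[vals > 0]
    if vals.size == 0:
        return -1
    return int(np.bincount(vals).argmax())


def train_default_classifier(
    rng: np.random.Generator, n_nuclei: int = 12
) -> fp.FociClassifier:
    """Train the focus classifier on a synthetic dose/time grid."""
    X, y = collect_training_set(rng, n_nuclei)
    if y.all() or not y.any():
        raise RuntimeError("training candidates are single-class; enlarge the grid")
    return fp.train_classifier(X, y)


def score_detection(
    stack: ConfocalStack,
    truth,
    clf: fp.FociClassifier | None,
    params: fp.PipelineParams | None = None,
    *,
    channel: str = "gH2AX",
    match_radius_um: float = 0.5,
) -> dict:
    """Recall/precision of candidates (and of accepted calls if clf given).

    Truth matching is one-to-one at ``match_radius_um``. Counts are pooled
    over all segmented nuclei of the stack.
    """
    params = params or fp.PipelineParams()
    label_map = fp.segment_nuclei(stack)
    tp_cand = n_cand = tp_call = n_call = n_truth = 0
    for nid in label_map.ids:
        tid = _truth_id(label_map, truth, nid)
        sub = truth.foci[truth.foci["nucleus_id"] == tid]
        if channel == "p53BP1":
            sub = sub[sub["channel"] == "both"]
        n_truth += len(sub)
        cands = fp.detect_candidates(stack, label_map, nid, channel, params.mser)
        y = match_candidates_to_truth(cands, truth.foci, tid, channel, match_radius_um)
        n_cand += len(cands)
        tp_cand += int(y.sum())
        if clf is not None and cands:
            X = np.array([fp.extract_features(c, stack, label_map) for c in cands])
            calls = fp.classify(cands, X, clf, params.bias_shift)
            calls = fp.suppress_duplicate_calls(
                calls, params.duplicate_radius_um, params.duplicate_z_scale
            )
            accepted = [c for c in calls if c.accepted]
            y_acc = match_candidates_to_truth(
                accepted, truth.foci, tid, channel, match_radius_um
            )
            n_call += len(accepted)
            tp_call += int(y_acc.sum())
    out = {
        "n_truth": n_truth,
        "candidate_recall": tp_cand / n_truth if n_truth else float("nan"),
        "n_candidates": n_cand,
        "tp_candidates": tp_cand,
    }
    if clf is not None:
        out["call_recall"] = tp_call / n_truth if n_truth else float("nan")
        out["call_precision"] = tp_call / n_call if n_call else float("nan")
        out["n_calls"] = n_call
        out["tp_calls"] = tp_call
    return out
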