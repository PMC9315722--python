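"""Salient-ROI extraction from attention gates.

The pooling gates assign every node a post-softmax weight per feature
dimension, so a node's mean gate value is a direct measure of how much the
classifier attends to that ROI.  Per fold, layer and diagnostic group, node
scores are the two-stage mean (over feature dimensions, then over the
group's subjects) of the gate matrices.  The top-q ROIs of each fold are
recorded, and an ROI is declared *salient* for a (layer, group) pair when it
ranks in the top q in strictly more than half of the cross-validation folds
(> 5 of 10 in the reference setting).  Salient sets are annotated with the
seven canonical functional networks of the parcellation, as the fraction of
salient ROIs falling in each network.

ROI identifiers in all public outputs are 1-based, matching parcellation
files; weight vectors are indexed 0-based internally (ROI id = index + 1).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graphs import Parcellation


@dataclass
class NodeWeightRecord:
    """Group-mean node attention scores for one (fold, layer, group)."""

    fold: int
    layer: int
    group: str  # "case" or "control"
    weights: np.ndarray  # length-N, nonnegative

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if not np.isfinite(self.weights).all():
            raise ValueError("node weights must be finite")
        if self.group not in ("case", "control"):
            raise ValueError(f"group must be 'case' or 'control', got {self.group!r}")


@dataclass
class SalientRoiSet:
    """Consolidated salient ROIs for one (layer, group).

    ``selection_counts`` holds, for every ROI id, the number of folds in
    which it ranked top-q; ``roi_ids`` the ids whose count strictly exceeds
    the consolidation threshold.
    """

    layer: int
    group: str
    roi_ids: frozenset[int]
    selection_counts: dict[int, int] = field(default_factory=dict)
    mean_weights: dict[int, float] = field(default_factory=dict)


@dataclass
class NetworkProportion:
    layer: int
    group: str
    fractions: dict[str, float]


def node_weight_from_gates(gate_stack: np.ndarray) -> np.ndarray:
    """Length-N node scores from a (B, N, d) stack of post-softmax gates.

    Per subject, a node's score is the mean of its gate values across the d
    feature dimensions; the group score is the mean across subjects.
    """
    gate_stack = np.asarray(gate_stack, dtype=float)
    if gate_stack.ndim == 2:
        gate_stack = gate_stack[None]
    if gate_stack.shape[0] < 1:
        raise ValueError("need gate matrices for at least one subject")
    return gate_stack.mean(axis=2).mean(axis=0)


def top_q_rois(weights: np.ndarray, q: int) -> frozenset[int]:
    """The q highest-scoring ROI ids (1-based); boundary ties resolve to the
    lowest ids, so the result is deterministic and has exactly q members."""
    weights = np.asarray(weights, dtype=float).ravel()
    n = weights.size
    if not 1 <= q <= n:
        raise ValueError(f"q must be in [1, {n}], got {q}")
    # sort by (weight desc, roi id asc); stable for exact ties
    order = np.lexsort((np.arange(n), -weights))
    return frozenset(int(i) + 1 for i in order[:q])


def default_top_q(n_rois: int) -> int:
    """The 'first quarter of ROIs' rule (50 of 200), generalised to any N."""
    return int(np.ceil(n_rois / 4))


def consolidate(
    records: list[NodeWeightRecord],
    q: int | None = None,
    min_folds: int | None = None,
    n_folds: int | None = None,
) -> dict[tuple[int, str], SalientRoiSet]:
    """Consolidate per-fold top-q ROI sets into salient sets per (layer, group).

    An ROI is retained iff it appears in the fold-level top-q strictly more
    than ``min_folds`` times (default: half the folds, i.e. > 5 of 10).
    """
    if not records:
        raise ValueError("no node-weight records given")
    # folds are numbered 1..K; K is the largest fold seen unless given
    k = n_folds if n_folds is not None else max(r.fold for r in records)
    folds = list(range(1, k + 1))
    if min_folds is None:
        min_folds = k // 2
    n = records[0].weights.size
    if q is None:
        q = default_top_q(n)

    by_key: dict[tuple[int, str], dict[int, np.ndarray]] = defaultdict(dict)
    for r in records:
        if r.weights.size != n:
            raise ValueError("node-weight records differ in length")
        by_key[(r.layer, r.group)][r.fold] = r.weights

    out: dict[tuple[int, str], SalientRoiSet] = {}
    for (layer, group), fold_weights in sorted(by_key.items()):
        missing = sorted(set(folds) - set(fold_weights))
        if missing:
            raise ValueError(
                f"layer {layer} group {group}: missing folds {missing}")
        counts = np.zeros(n, dtype=int)
        for fold in folds:
            for roi in top_q_rois(fold_weights[fold], q):
                counts[roi - 1] += 1
        mean_w = np.mean([fold_weights[f] for f in folds], axis=0)
        salient = frozenset(int(i) + 1 for i in np.flatnonzero(counts > min_folds))
        out[(layer, group)] = SalientRoiSet(
            layer=layer,
            group=group,
            roi_ids=salient,
            selection_counts={i + 1: int(c) for i, c in enumerate(counts)},
            mean_weights={i + 1: float(w) for i, w in enumerate(mean_w)},
        )
    return out


def network_proportions(s: SalientRoiSet, parc: Parcellation) -> NetworkProportion:
    """Fraction of a salient set falling in each of the 7 functional networks."""
    if not s.roi_ids:
        raise ValueError(
            f"layer {s.layer} group {s.group}: empty salient set has no proportions")
    known = set(parc.roi_ids.tolist())
    unknown = sorted(set(s.roi_ids) - known)
    if unknown:
        raise ValueError(f"ROI id(s) not in parcellation: {unknown}")
    fractions = {net: 0.0 for net in sorted(set(parc.networks))}
    for roi in s.roi_ids:
        fractions[parc.network_of(roi)] += 1.0
    total = len(s.roi_ids)
    return NetworkProportion(
        layer=s.layer, group=s.group,
        fractions={net: c / total for net, c in fractions.items()})


def salient_table(
    sets: dict[tuple[int, str], SalientRoiSet], parc: Parcellation
) -> pd.DataFrame:
    """Long-format table of salient ROIs with names, networks and counts."""
    rows = []
    id_to_row = {int(r): i for i, r in enumerate(parc.roi_ids)}
    for (layer, group), s in sorted(sets.items()):
        for roi in sorted(s.roi_ids):
            i = id_to_row[roi]
            rows.append({
                "layer": layer, "group": group, "roi_id": roi,
                "roi_name": parc.roi_names[i], "network": parc.networks[i],
                "count": s.selection_counts[roi],
                "mean_weight": s.mean_weights[roi],
            })
    return pd.DataFrame(
        rows, columns=["layer", "group", "roi_id", "roi_name", "network",
                       "count", "mean_weight"])
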