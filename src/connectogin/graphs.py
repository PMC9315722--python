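"""Functional-connectivity matrices and brain-graph construction.

A subject's resting-state recording is summarised as a T x N matrix of ROI
mean time series.  Pearson correlation between every ROI pair, Fisher-z
transformed (arctanh), gives the N x N functional connectome.  The connectome
is sparsified by keeping the top M% strongest candidate edges and turned into
a weighted, undirected graph whose node features are one-hot ROI identities.

Three edge-weight conventions are supported for the sparsified graph:

``abs``
    rank candidates by \\|z\\| and keep \\|z\\| as the edge weight (all weights
    positive);
``positive_only``
    discard negative connectivity, rank and weight by z;
``signed``
    rank by \\|z\\| but keep the signed z as the edge weight, so strong
    negative connectivity survives thresholding.

ROI identifiers are 1-based in all files and public tables; array indices are
0-based internally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("connectogin")

#: the seven canonical cortical functional systems used for ROI annotation
YEO7_NETWORKS = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default_mode",
)

EDGE_CASES = ("abs", "positive_only", "signed")

#: correlations are clipped to +/- R_MAX before arctanh when clipping is on
R_MAX = 1.0 - 1e-7


class DegenerateSignalError(ValueError):
    """An ROI time series carries no variance (or a perfect correlation)."""


@dataclass
class RoiTimeSeries:
    """One subject's ROI mean time series, T timepoints x N ROIs."""

    subject_id: str
    values: np.ndarray
    roi_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (T x N) array")
        if not self.roi_ids:
            self.roi_ids = list(range(1, self.values.shape[1] + 1))
        if len(self.roi_ids) != self.values.shape[1]:
            raise ValueError("roi_ids length does not match number of columns")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        if self.n_timepoints < 3:
            raise ValueError(
                f"subject {self.subject_id}: need >= 3 timepoints for a "
                f"nondegenerate correlation, got {self.n_timepoints}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError(f"subject {self.subject_id}: non-finite values")
        sd = self.values.std(axis=0)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            names = ", ".join(str(self.roi_ids[i]) for i in dead[:5])
            raise DegenerateSignalError(
                f"subject {self.subject_id}: zero-variance ROI column(s) {names}"
            )


@dataclass
class FCMatrix:
    """Fisher-z transformed correlation matrix; symmetric, zero diagonal."""

    subject_id: str
    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2 or self.z.shape[0] != self.z.shape[1]:
            raise ValueError("FC matrix must be square")

    @property
    def n_rois(self) -> int:
        return self.z.shape[0]

    def validate(self) -> None:
        if not np.allclose(self.z, self.z.T, atol=1e-8):
            raise ValueError(f"subject {self.subject_id}: FC matrix not symmetric")
        if np.abs(np.diag(self.z)).max(initial=0.0) != 0.0:
            raise ValueError(f"subject {self.subject_id}: FC diagonal must be 0")
        off = self.z[~np.eye(self.n_rois, dtype=bool)]
        if off.size and not np.isfinite(off).all():
            raise ValueError(f"subject {self.subject_id}: non-finite FC entries")


@dataclass
class BrainGraph:
    """Sparse weighted undirected graph over ROIs with one-hot node features.

    ``edges`` is an (E, 2) array of 0-based node pairs with i < j;
    ``edge_weights`` the matching real weights.  Node features are the
    N x N identity (one-hot ROI labels) and are materialised on demand.
    """

    subject_id: str
    label: int
    edges: np.ndarray
    edge_weights: np.ndarray
    n_nodes: int

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.edge_weights = np.asarray(self.edge_weights, dtype=float).ravel()
        if self.edges.shape[0] != self.edge_weights.shape[0]:
            raise ValueError("edges / edge_weights length mismatch")
        if self.edges.size and (self.edges[:, 0] >= self.edges[:, 1]).any():
            raise ValueError("edges must satisfy i < j (no self-loops)")

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def node_features(self) -> np.ndarray:
        return np.eye(self.n_nodes)

    def adjacency(self, dtype=float) -> np.ndarray:
        """Dense symmetric weighted adjacency matrix."""
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=dtype)
        if self.edges.size:
            i, j = self.edges[:, 0], self.edges[:, 1]
            a[i, j] = self.edge_weights
            a[j, i] = self.edge_weights
        return a


@dataclass
class Parcellation:
    """ROI lookup: id (1-based), anatomical name, functional network, MNI mm."""

    roi_ids: np.ndarray
    roi_names: list[str]
    networks: list[str]
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.roi_ids = np.asarray(self.roi_ids, dtype=int)
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        n = self.roi_ids.size
        if not (len(self.roi_names) == len(self.networks) == self.coordinates.shape[0] == n):
            raise ValueError("parcellation column lengths differ")
        unknown = sorted(set(self.networks) - set(YEO7_NETWORKS))
        if unknown:
            raise ValueError(f"unknown network label(s): {unknown}")

    @property
    def n_rois(self) -> int:
        return self.roi_ids.size

    def network_of(self, roi_id: int) -> str:
        idx = np.flatnonzero(self.roi_ids == roi_id)
        if idx.size == 0:
            raise KeyError(f"ROI id {roi_id} not in parcellation")
        return self.networks[int(idx[0])]


def compute_fc(ts: RoiTimeSeries, clip_perfect: bool = True) -> FCMatrix:
    """Pearson correlation of every ROI pair, Fisher-z transformed.

    The diagonal is forced to zero (self-correlation is never transformed).
    Off-diagonal |r| = 1 makes arctanh infinite; with ``clip_perfect`` (the
    default, intended for synthetic data where perfect correlations are
    legitimate) r is clipped to +/-(1 - 1e-7) first, otherwise it is an error.
    """
    ts.validate()
    r = np.corrcoef(ts.values, rowvar=False)
    np.fill_diagonal(r, 0.0)
    if clip_perfect:
        r = np.clip(r, -R_MAX, R_MAX)
    elif np.abs(r).max(initial=0.0) >= 1.0:
        i, j = np.unravel_index(int(np.abs(r).argmax()), r.shape)
        raise DegenerateSignalError(
            f"subject {ts.subject_id}: |r| = 1 between ROIs "
            f"{ts.roi_ids[i]} and {ts.roi_ids[j]} (infinite Fisher z); "
            "enable clipping to proceed"
        )
    z = np.arctanh(r)
    z = (z + z.T) / 2.0  # enforce exact symmetry against float round-off
    np.fill_diagonal(z, 0.0)
    return FCMatrix(subject_id=ts.subject_id, z=z)


def group_average_fc(fcs: list[FCMatrix], subject_id: str = "group_mean") -> FCMatrix:
    """Entrywise mean connectome of a group of subjects."""
    if not fcs:
        raise ValueError("cannot average an empty list of FC matrices")
    n = fcs[0].n_rois
    for fc in fcs:
        if fc.n_rois != n:
            raise ValueError(
                f"FC size mismatch: {fc.subject_id} has {fc.n_rois} ROIs, expected {n}"
            )
    z = np.mean([fc.z for fc in fcs], axis=0)
    return FCMatrix(subject_id=subject_id, z=z)


def _n_retained(density_m: float, n_candidates: int) -> int:
    # round-half-up for a platform-independent edge count
    return int(np.floor(density_m / 100.0 * n_candidates + 0.5))


def build_graph(
    fc: FCMatrix,
    label: int,
    density_m: float = 25.0,
    case: str = "abs",
    subject_id: str | None = None,
) -> BrainGraph:
    """Threshold a connectome to its top ``density_m`` percent edges.

    Candidates are the N(N-1)/2 upper-triangle entries.  The ranking key is
    \\|z\\| for ``abs`` and ``signed`` and z for ``positive_only`` (negative
    entries are excluded from the candidate pool there).  Ties at the cutoff
    are broken deterministically by (key desc, i asc, j asc).
    """
    if not 0 < density_m <= 100:
        raise ValueError("density_m must be in (0, 100]")
    if case not in EDGE_CASES:
        raise ValueError(f"case must be one of {EDGE_CASES}, got {case!r}")
    n = fc.n_rois
    iu, ju = np.triu_indices(n, k=1)
    z = fc.z[iu, ju]

    if case == "positive_only":
        keep = z > 0
        iu, ju, z = iu[keep], ju[keep], z[keep]
        key = z
        weights = z
    else:
        key = np.abs(z)
        weights = np.abs(z) if case == "abs" else z

    n_candidates = n * (n - 1) // 2
    n_keep = _n_retained(density_m, n_candidates)
    if case == "positive_only" and key.size < n_keep:
        warnings.warn(
            f"subject {fc.subject_id}: only {key.size} positive edges available "
            f"for a target of {n_keep}; keeping all positive edges",
            stacklevel=2,
        )
        n_keep = key.size

    # stable ranking: key descending, then (i, j) ascending
    order = np.lexsort((ju, iu, -key))[:n_keep]
    order.sort()  # edge list in (i, j) order for readability
    return BrainGraph(
        subject_id=subject_id if subject_id is not None else fc.subject_id,
        label=int(label),
        edges=np.column_stack([iu[order], ju[order]]),
        edge_weights=weights[order],
        n_nodes=n,
    )
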