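"""Synthetic cohorts with planted group differences in functional connectivity.

Each subject's ROI time series is drawn from a zero-mean multivariate normal
whose correlation structure mimics a cortical parcellation organised into the
seven canonical functional networks: ROIs are partitioned into seven
near-equal blocks, correlation is ``r0`` within a block and 0 between blocks.
Case subjects differ from controls only inside a *planted* ROI subset, where
pairwise correlation is raised by ``delta`` — a localised hyperconnectivity
effect.  The generator therefore provides (i) a separable two-class
classification problem whose discriminative signal lives on a known edge set
and (ii) ground truth for saliency recovery: the planted ROIs are the ones a
faithful attention mechanism should flag.

Defaults emulate the reference cohort shape: 150 subjects per group,
200 ROIs, 200 timepoints, r0 = 0.2, delta = 0.25 on a 20-ROI block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graphs import YEO7_NETWORKS, FCMatrix, Parcellation, RoiTimeSeries, compute_fc


@dataclass
class SimConfig:
    n_subjects_per_group: int = 150
    n_rois: int = 200
    n_timepoints: int = 200
    r0: float = 0.2
    delta: float = 0.25
    planted_rois: tuple[int, ...] = tuple(range(1, 21))  # 1-based ids
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1 or self.n_rois < 2:
            raise ValueError("need >= 1 subject per group and >= 2 ROIs")
        if self.n_timepoints < 3:
            raise ValueError("need >= 3 timepoints")
        bad = [r for r in self.planted_rois if not 1 <= r <= self.n_rois]
        if bad:
            raise ValueError(f"planted ROI ids outside 1..{self.n_rois}: {bad}")
        if len(set(self.planted_rois)) != len(self.planted_rois):
            raise ValueError("planted_rois contains duplicates")


@dataclass
class GroundTruth:
    """Exact target covariances and the planted discriminative ROI set."""

    cov_control: np.ndarray
    cov_case: np.ndarray
    planted_rois: tuple[int, ...]
    blocks: list[np.ndarray] = field(default_factory=list)

    @property
    def planted_index(self) -> np.ndarray:
        return np.asarray(self.planted_rois, dtype=int) - 1


def network_blocks(n_rois: int) -> list[np.ndarray]:
    """Partition 0-based ROI indices into 7 near-equal contiguous blocks."""
    return [np.asarray(b) for b in np.array_split(np.arange(n_rois), 7)]


def toy_parcellation(n_rois: int, seed: int = 0) -> Parcellation:
    """A synthetic parcellation matching the generator's block structure.

    ROI names encode network membership; coordinates are arbitrary points in
    an MNI-sized bounding box, provided only so coordinate exports work.
    """
    rng = np.random.default_rng(seed)
    blocks = network_blocks(n_rois)
    networks = [""] * n_rois
    names = [""] * n_rois
    for net, block in zip(YEO7_NETWORKS, blocks):
        for rank, i in enumerate(block, start=1):
            networks[i] = net
            names[i] = f"{net}_{rank}"
    coords = np.column_stack([
        rng.uniform(-70, 70, n_rois),
        rng.uniform(-105, 70, n_rois),
        rng.uniform(-45, 75, n_rois),
    ])
    return Parcellation(roi_ids=np.arange(1, n_rois + 1), roi_names=names,
                        networks=networks, coordinates=coords)


def target_covariances(cfg: SimConfig) -> GroundTruth:
    """Build the exact control/case covariance matrices and check them.

    The correlation matrix has ``r0`` within each of the 7 blocks and zero
    between blocks; case subjects additionally get ``+delta`` on every pair
    of planted ROIs.  Both targets must be positive definite.
    """
    n = cfg.n_rois
    blocks = network_blocks(n)
    corr = np.eye(n)
    for block in blocks:
        ix = np.ix_(block, block)
        corr[ix] = cfg.r0
        corr[block, block] = 1.0
    cov_control = cfg.noise_sd ** 2 * corr

    corr_case = corr.copy()
    planted = np.asarray(cfg.planted_rois, dtype=int) - 1
    ix = np.ix_(planted, planted)
    corr_case[ix] = corr_case[ix] + cfg.delta
    corr_case[planted, planted] = 1.0
    cov_case = cfg.noise_sd ** 2 * corr_case

    for name, cov in (("control", cov_control), ("case", cov_case)):
        lam = float(np.linalg.eigvalsh(cov).min())
        if lam <= 0:
            raise ValueError(
                f"{name} target covariance is not positive definite "
                f"(smallest eigenvalue {lam:.3e}); reduce r0 or delta")
    return GroundTruth(cov_control=cov_control, cov_case=cov_case,
                       planted_rois=tuple(cfg.planted_rois), blocks=blocks)


def make_cohort(cfg: SimConfig) -> tuple[list[tuple[RoiTimeSeries, int]], GroundTruth]:
    """Sample a full cohort of ROI time series with labels (0 control, 1 case).

    Subjects are independent draws given the seed; controls and cases come
    from their respective target covariances.  Subjects are returned
    interleaved (control, case, control, ...) with ids encoding the group.
    """
    truth = target_covariances(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    chol = {0: np.linalg.cholesky(truth.cov_control),
            1: np.linalg.cholesky(truth.cov_case)}
    cohort: list[tuple[RoiTimeSeries, int]] = []
    for s in range(cfg.n_subjects_per_group):
        for label, tag in ((0, "con"), (1, "case")):
            white = rng.standard_normal((cfg.n_timepoints, cfg.n_rois))
            ts = RoiTimeSeries(
                subject_id=f"sim-{tag}-{s + 1:04d}",
                values=white @ chol[label].T)
            cohort.append((ts, label))
    return cohort, truth


def make_fc_cohort(cfg: SimConfig) -> tuple[list[tuple[FCMatrix, int]], GroundTruth]:
    """Cohort of Fisher-z connectomes (time series simulated internally)."""
    cohort, truth = make_cohort(cfg)
    return [(compute_fc(ts), label) for ts, label in cohort], truth
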