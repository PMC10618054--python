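"""Landscape switching: non-equilibrium transitions between stage potentials.

The protocol clusters the pre-switch equilibrium ensemble (average-linkage on
pairwise aligned RMSD), picks a small set of representative initial
structures from every sufficiently populated cluster (population > 0.2% of
the ensemble, two structures per cluster by default), instantaneously swaps
the stage potential, and collects constant-temperature relaxation
trajectories on the post-switch landscape with checkpoints at 1, 10, 100 and
1000 tau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation

from .engine import LangevinSettings, Trajectory, maxwell_velocities, run_trajectory
from .polymer_model import StagePotential, as_configuration

__all__ = [
    "ClusterSet",
    "SwitchingRun",
    "cluster_ensemble",
    "select_initials",
    "switch_and_relax",
    "time_resolved_ensemble",
]


@dataclass
class ClusterSet:
    """Partition of an ensemble by structural similarity.

    ``assignments`` maps each structure to a 0-based cluster label (labels
    ordered by first-member index); ``medoid_indices`` hold the structure
    minimizing the total within-cluster distance.
    """

    structures: np.ndarray       # (M, N, 3)
    assignments: np.ndarray      # (M,) int
    populations: np.ndarray      # fraction per cluster, sums to 1
    medoid_indices: np.ndarray   # (n_clusters,) int
    distances: np.ndarray        # (M, M) aligned RMSD

    def __post_init__(self) -> None:
        if not np.isclose(self.populations.sum(), 1.0):
            raise ValueError("cluster populations must sum to 1")

    @property
    def n_clusters(self) -> int:
        return self.populations.size


@dataclass
class SwitchingRun:
    """Relaxation trajectories after an instantaneous potential swap."""

    source_label: str
    target_label: str
    initials: np.ndarray             # (R, N, 3)
    trajectories: list               # one Trajectory per initial
    checkpoint_times: tuple
    duration: float

    def __post_init__(self) -> None:
        if len(self.trajectories) != self.initials.shape[0]:
            raise ValueError("one trajectory per initial structure required")
        for t in self.checkpoint_times:
            if not 0 <= t <= self.duration + 1e-9:
                raise ValueError(f"checkpoint {t} tau outside the {self.duration} tau run")


def _aligned_rmsd_matrix(structures: np.ndarray) -> np.ndarray:
    """Pairwise RMSD after optimal rigid superposition (Kabsch)."""
    M = structures.shape[0]
    centred = structures - structures.mean(axis=1, keepdims=True)
    D = np.zeros((M, M))
    for a in range(M):
        for b in range(a + 1, M):
            rot, rssd = Rotation.align_vectors(centred[a], centred[b])
            D[a, b] = D[b, a] = rssd / np.sqrt(structures.shape[1])
    return D


def cluster_ensemble(ensemble, distance_threshold: float) -> ClusterSet:
    """Average-linkage agglomerative clustering on aligned-RMSD distances.

    Cut at ``distance_threshold`` (sigma).  Deterministic given input order;
    cluster labels are renumbered by each cluster's first member, ties in
    medoid selection break toward the lower index.  A single structure forms
    one trivial cluster.
    """
    structures = np.array([as_configuration(s) for s in ensemble], dtype=float)
    M = structures.shape[0]
    if M == 1:
        return ClusterSet(structures, np.zeros(1, dtype=int), np.ones(1),
                          np.zeros(1, dtype=int), np.zeros((1, 1)))
    D = _aligned_rmsd_matrix(structures)
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=distance_threshold, criterion="distance")
    # renumber labels by order of first appearance
    order: dict[int, int] = {}
    labels = np.empty(M, dtype=int)
    for m, lab in enumerate(raw):
        if lab not in order:
            order[lab] = len(order)
        labels[m] = order[lab]
    n_clusters = len(order)
    populations = np.bincount(labels, minlength=n_clusters) / M
    medoids = np.empty(n_clusters, dtype=int)
    for c in range(n_clusters):
        members = np.flatnonzero(labels == c)
        within = D[np.ix_(members, members)].sum(axis=1)
        medoids[c] = members[int(np.argmin(within))]  # argmin takes first on ties
    return ClusterSet(structures, labels, populations, medoids, D)


def select_initials(clusters: ClusterSet, min_population: float = 0.002,
                    per_cluster: int = 2) -> np.ndarray:
    """Representative structures from every sufficiently populated cluster.

    From each cluster with population strictly above ``min_population``, the
    ``per_cluster`` structures nearest the cluster medoid (the medoid first;
    small clusters contribute what they have).  Deterministic.
    """
    if not 0 <= min_population < 1:
        raise ValueError("min_population must be in [0, 1)")
    if per_cluster < 1:
        raise ValueError("per_cluster must be >= 1")
    chosen: list[int] = []
    for c in range(clusters.n_clusters):
        if clusters.populations[c] <= min_population:
            continue
        members = np.flatnonzero(clusters.assignments == c)
        d_to_medoid = clusters.distances[members, clusters.medoid_indices[c]]
        ranked = members[np.argsort(d_to_medoid, kind="stable")]
        chosen.extend(int(i) for i in ranked[:per_cluster])
    if not chosen:
        raise ValueError(
            f"no cluster exceeds the population threshold {min_population}"
        )
    return clusters.structures[chosen]


def switch_and_relax(initials, source: StagePotential, target: StagePotential,
                     settings: LangevinSettings, duration: float,
                     checkpoint_times: tuple = (1.0, 10.0, 100.0, 1000.0),
                     record_stride: float = 1.0) -> SwitchingRun:
    """Swap V(source) -> V(target) at t = 0 and relax at constant temperature.

    No re-thermalization: positions carry over from the pre-switch ensemble
    and velocities are Maxwell-Boltzmann at the running temperature, which is
    statistically identical to retaining equilibrium momenta.  Frames are
    recorded at the regular stride, which is chosen to divide every
    checkpoint so each checkpoint time has an exact frame.
    """
    if source.n_loci != target.n_loci:
        raise ValueError(
            f"source ({source.n_loci} loci) and target ({target.n_loci} loci) "
            "potentials were calibrated for different chain lengths"
        )
    initials = np.array([as_configuration(c) for c in initials], dtype=float)
    if initials.shape[1] != target.n_loci:
        raise ValueError("initial structures do not match the potentials' chain length")
    for t in checkpoint_times:
        if t > duration + 1e-9:
            raise ValueError(f"checkpoint {t} tau exceeds the {duration} tau duration")

    seed_seqs = np.random.SeedSequence(settings.seed).spawn(initials.shape[0])
    trajectories: list[Trajectory] = []
    for r in range(initials.shape[0]):
        rng = np.random.default_rng(seed_seqs[r])
        v0 = maxwell_velocities(target.n_loci, settings.temperature, rng)
        traj = run_trajectory(initials[r], target, settings, duration=duration,
                              record_stride=record_stride, velocities=v0, rng=rng)
        traj.manifest["replica"] = r
        traj.manifest["switch"] = f"{source.label} -> {target.label}"
        trajectories.append(traj)
    return SwitchingRun(source.label, target.label, initials, trajectories,
                        tuple(checkpoint_times), duration)


def time_resolved_ensemble(run: SwitchingRun, t: float) -> np.ndarray:
    """One structure per replica: the frame nearest ``t`` in each trajectory."""
    if not run.trajectories:
        raise ValueError("empty switching run")
    if not 0 <= t <= run.duration + 1e-9:
        raise ValueError(f"time {t} tau outside the {run.duration} tau run")
    return np.array([traj.frame_nearest(t) for traj in run.trajectories])
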