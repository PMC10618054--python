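"""Structural observables of chromosome ensembles.

Per-configuration geometry comes from the gyration tensor: its trace gives
R_g^2 and the spread of its eigenvalues gives the asphericity Delta
(0 = perfect sphere, 1 = rod).  Ensemble observables are the free-energy
landscape over (R_g, Delta), and the fluctuation matrix
M_ij = <delta r_i . delta r_j> computed after iterative rigid-body alignment
onto the ensemble mean (the mean, not a cluster representative, because
chromosome ensembles are too heterogeneous for any single cluster to stand in
for the average position).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .polymer_model import as_configuration

__all__ = [
    "GeometryRecord",
    "AlignedEnsemble",
    "FluctuationMatrix",
    "FreeEnergyLandscape",
    "gyration_tensor",
    "geometry",
    "free_energy_landscape",
    "align_ensemble",
    "fluctuation_matrix",
    "delta_M",
    "msd",
]


@dataclass(frozen=True)
class GeometryRecord:
    """R_g, asphericity and gyration-tensor eigenvalues of one configuration."""

    Rg: float            # sigma
    Delta: float         # dimensionless, NaN when tr T = 0
    eigenvalues: tuple   # (lambda1 >= lambda2 >= lambda3), sigma^2


@dataclass
class AlignedEnsemble:
    """Rigid-body-aligned structures plus their mean; required input for M_ij."""

    structures: np.ndarray  # (M, N, 3)
    mean: np.ndarray        # (N, 3)
    iterations: int


@dataclass
class FluctuationMatrix:
    """M_ij = <delta r_i . delta r_j> over an aligned ensemble (sigma^2)."""

    M: np.ndarray
    ensemble_size: int

    def __post_init__(self) -> None:
        if not np.allclose(self.M, self.M.T, atol=1e-10, rtol=0.0):
            raise ValueError("fluctuation matrix must be symmetric")
        if np.any(np.diag(self.M) < -1e-12):
            raise ValueError("per-locus variances must be non-negative")


@dataclass
class FreeEnergyLandscape:
    """-ln(probability) over a 2D (R_g, Delta) grid, minimum shifted to 0."""

    values: np.ndarray      # NaN on empty bins
    rg_edges: np.ndarray
    delta_edges: np.ndarray
    defined: np.ndarray


def gyration_tensor(conf) -> np.ndarray:
    """Centred second-moment tensor T = (1/N) sum (r - rbar)(r - rbar)^T."""
    x = np.asarray(conf, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3 or x.shape[0] < 1:
        raise ValueError(f"configuration must be (N, 3), got {x.shape}")
    d = x - x.mean(axis=0)
    return d.T @ d / x.shape[0]


def geometry(conf) -> GeometryRecord:
    """Radius of gyration and asphericity from the gyration-tensor eigenvalues.

    R_g = sqrt(tr T) = sqrt(sum lambda_k);
    Delta = (3/2) sum (lambda_k - mean lambda)^2 / (tr T)^2.
    A degenerate (all-coincident) configuration has R_g = 0 and undefined
    Delta (NaN).
    """
    T = gyration_tensor(conf)
    lam = np.sort(np.linalg.eigvalsh(T))[::-1]
    tr = float(lam.sum())
    rg = float(np.sqrt(max(tr, 0.0)))
    if tr <= 0.0:
        return GeometryRecord(0.0, float("nan"), tuple(lam))
    mean_lam = tr / 3.0
    delta = 1.5 * float(np.sum((lam - mean_lam) ** 2)) / tr**2
    return GeometryRecord(rg, delta, tuple(lam))


def free_energy_landscape(records, bins=40, rg_range=None, delta_range=None) -> FreeEnergyLandscape:
    """2D histogram of (R_g, Delta) converted to -ln p, min-shifted to zero."""
    records = list(records)
    if not records:
        raise ValueError("need at least one geometry record")
    rg = np.array([r.Rg for r in records])
    dl = np.array([r.Delta for r in records])
    keep = np.isfinite(rg) & np.isfinite(dl)
    rng_arg = None
    if rg_range is not None or delta_range is not None:
        rng_arg = [rg_range, delta_range]
    counts, rg_edges, delta_edges = np.histogram2d(
        rg[keep], dl[keep], bins=bins, range=rng_arg
    )
    total = counts.sum()
    if total == 0:
        raise ValueError("no finite (Rg, Delta) records to histogram")
    p = counts / total
    defined = p > 0
    values = np.full_like(p, np.nan)
    values[defined] = -np.log(p[defined])
    values[defined] -= values[defined].min()
    return FreeEnergyLandscape(values, rg_edges, delta_edges, defined)


# ---------------------------------------------------------------------------
# Ensemble alignment and fluctuation matrix


def _kabsch_onto(target: np.ndarray, source: np.ndarray) -> np.ndarray:
    """Optimal proper rotation of centred ``source`` onto centred ``target``."""
    rot, _ = Rotation.align_vectors(target, source)
    return source @ rot.as_matrix().T


def align_ensemble(ensemble, tol: float = 1e-8, max_iter: int = 200) -> AlignedEnsemble:
    """Iteratively superpose an ensemble onto its running mean structure.

    Each structure is centred and rotated by the least-squares (Kabsch)
    rotation onto the current mean; the mean is recomputed until it moves by
    less than ``tol`` (RMS).  Idempotent up to the tolerance.
    """
    structures = np.array([as_configuration(s) for s in ensemble], dtype=float)
    if structures.shape[0] < 2:
        raise ValueError("alignment needs at least 2 structures")
    structures = structures - structures.mean(axis=1, keepdims=True)
    # initial reference: the raw ensemble mean, so re-aligning an aligned
    # ensemble is a no-op; fall back to the first member when rotations
    # cancel the mean almost exactly (e.g. rigid copies at random attitudes)
    mean = structures.mean(axis=0)
    if np.sqrt(np.mean(mean**2)) < 1e-8 * np.sqrt(np.mean(structures**2)):
        mean = structures[0].copy()
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for m in range(structures.shape[0]):
            structures[m] = _kabsch_onto(mean, structures[m])
        new_mean = structures.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        shift = float(np.sqrt(np.mean((new_mean - mean) ** 2)))
        mean = new_mean
        if shift < tol:
            break
    return AlignedEnsemble(structures, mean, iterations)


def fluctuation_matrix(aligned: AlignedEnsemble) -> FluctuationMatrix:
    """M_ij = <delta r_i . delta r_j> with delta r = r - <r> over the ensemble.

    Refuses raw (unaligned) input: M is only meaningful after the rigid-body
    motion has been removed.
    """
    if not isinstance(aligned, AlignedEnsemble):
        raise TypeError(
            "fluctuation_matrix requires an AlignedEnsemble from "
            "align_ensemble(); M_ij is alignment-dependent"
        )
    d = aligned.structures - aligned.structures.mean(axis=0)
    M = np.einsum("mik,mjk->ij", d, d) / d.shape[0]
    M = 0.5 * (M + M.T)
    return FluctuationMatrix(M, d.shape[0])


def delta_M(M_t: FluctuationMatrix, M_0: FluctuationMatrix) -> np.ndarray:
    """Elementwise change of coherent motion, M(t) - M(0)."""
    if M_t.M.shape != M_0.M.shape:
        raise ValueError("fluctuation matrices have different shapes")
    return M_t.M - M_0.M


def msd(traj, lag: float) -> np.ndarray:
    """Per-locus time-averaged mean squared displacement at the given lag.

    Per-frame centre-of-mass drift is removed first, so a rigid translation
    contributes nothing.  Requires uniformly spaced frames spanning the lag.
    """
    times = np.asarray(traj.frame_times, dtype=float)
    if times.size < 2:
        raise ValueError("need at least 2 frames")
    strides = np.diff(times)
    stride = strides[0]
    if not np.allclose(strides, stride, rtol=1e-6, atol=1e-12):
        raise ValueError("msd requires uniformly spaced frames")
    k = int(round(lag / stride))
    if k < 1 or k >= times.size:
        raise ValueError(
            f"lag {lag} tau is outside the trajectory span "
            f"({times[-1] - times[0]} tau at stride {stride})"
        )
    x = traj.frames - traj.frames.mean(axis=1, keepdims=True)
    disp = x[k:] - x[:-k]
    return np.mean(np.sum(disp**2, axis=2), axis=0)
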