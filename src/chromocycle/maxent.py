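"""Maximum-entropy calibration of the Hi-C bias field.

The biasing potential is linear in the experimental observable (the contact
probability), so the minimal-perturbation ensemble that reproduces a target
map is obtained by iterating: simulate under the current couplings, measure
the ensemble contact probabilities, and move each coupling proportionally to
the residual ``P_sim - P_target``.  Raising alpha_ij raises the energy of a
formed contact (the indicator f >= 0), so over-formed contacts are penalized
and under-formed ones rewarded; the target map is a fixed point of the
update.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .contact_maps import ContactMap, normalize_adjacent, synthetic_region
from .engine import (AnnealingSchedule, LangevinSettings,
                     cold_start_configurations, run_replicas)
from .polymer_model import BiasField, HomopolymerParams, StagePotential

__all__ = [
    "CalibrationState",
    "estimate_contact_probabilities",
    "update_alpha",
    "calibrate",
]


@dataclass
class CalibrationState:
    """Progress of one calibration run.

    ``error_history`` holds one (MAE, Pearson) pair per completed iteration,
    both computed over pairs with |i - j| >= 2 (the adjacent band is pinned
    by normalization and carries no signal).  ``ensemble`` is the
    sampling-window frames of the last iteration.
    """

    iteration: int
    bias: BiasField
    P_sim: ContactMap | None
    error_history: list
    learning_rate: float
    alpha_max: float
    ensemble: np.ndarray | None = None
    converged: bool = False
    diverged: bool = False

    def __post_init__(self) -> None:
        if len(self.error_history) != self.iteration:
            raise ValueError("error history must have one entry per iteration")

    @property
    def best_errors(self) -> tuple[float, float]:
        """(MAE, Pearson) of the best iteration by MAE."""
        maes = [m for m, _ in self.error_history]
        k = int(np.argmin(maes))
        return self.error_history[k]


def estimate_contact_probabilities(ensemble, r_c: float = 1.8, eta: float = 5.0,
                                   region=None, normalize: bool = True) -> ContactMap:
    """Ensemble mean of the smooth contact indicator over all pairs.

    With ``normalize=True`` (default) the adjacent-band convention
    ``P[i, i±1] = 1`` is applied, matching how experimental maps are
    prepared; the same indicator kernel is used here and in the biasing
    potential, so calibration is self-consistent.
    """
    frames = np.ascontiguousarray(ensemble, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3 or frames.shape[0] < 1 or frames.shape[2] != 3:
        raise ValueError(f"ensemble must be (M, N, 3), got {frames.shape}")
    n = frames.shape[1]
    acc = np.zeros((n, n))
    _kernels.accumulate_contacts(frames, r_c, eta, acc)
    P = acc / frames.shape[0]
    if region is None:
        region = synthetic_region(n)
    cmap = ContactMap(region, P)
    return normalize_adjacent(cmap) if normalize else cmap


def _offdiag_mask(n: int) -> np.ndarray:
    S = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    return np.triu(S >= 2)


def _errors(P_sim: np.ndarray, P_target: np.ndarray) -> tuple[float, float]:
    mask = _offdiag_mask(P_sim.shape[0])
    a, b = P_sim[mask], P_target[mask]
    mae = float(np.mean(np.abs(a - b)))
    pearson = float(np.corrcoef(a, b)[0, 1])
    return mae, pearson


def update_alpha(state: CalibrationState, P_target: ContactMap) -> BiasField:
    """Proportional fixed-point update of the couplings.

    alpha'_ij = clamp(alpha_ij + lr (P_sim - P_target)_ij, ±alpha_max) for
    |i - j| >= 2; the diagonal and adjacent bands stay exactly zero.
    """
    if state.P_sim is None:
        raise ValueError("no simulated map to update from")
    sim, tgt = state.P_sim.P, P_target.P
    if sim.shape != tgt.shape:
        raise ValueError("simulated and target maps have different shapes")
    if np.any(~np.isfinite(sim)) or np.any(~np.isfinite(tgt)):
        raise ValueError("NaN in simulated or target map")
    n = sim.shape[0]
    S = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    update = state.learning_rate * (sim - tgt)
    update[S < 2] = 0.0
    alpha = np.clip(state.bias.alpha + update, -state.alpha_max, state.alpha_max)
    return BiasField(0.5 * (alpha + alpha.T))


def calibrate(target: ContactMap,
              params: HomopolymerParams | None = None,
              settings: LangevinSettings | None = None,
              schedule: AnnealingSchedule | None = None,
              n_replicas: int = 8,
              max_iter: int = 20,
              tol: float = 0.02,
              learning_rate: float = 3.0,
              lr_decay: float | None = 3.0,
              alpha_max: float = 10.0,
              final_eval_replicas: int | None = None,
              label: str = "calibrated",
              callback=None) -> CalibrationState:
    """Iterate simulate -> measure -> update until the maps agree.

    Each round runs ``n_replicas`` annealed trajectories (4 epsilon down to
    1 epsilon, second half sampled, stride chosen so at least 50 frames per
    replica enter the estimate), measures the ensemble contact map and
    applies the proportional update with a decaying learning rate
    (lr / (1 + it / lr_decay), Robbins-Monro style) so the couplings settle
    instead of random-walking on the sampling noise.  If the MAE rises three
    iterations in a row the base rate is halved; a second streak stops the
    run with ``diverged=True`` and the history intact.

    ``final_eval_replicas`` runs that many extra replicas under the final
    couplings purely to measure the calibrated ensemble's map with less
    sampling noise; the enlarged ensemble replaces ``P_sim`` and
    ``ensemble`` and its errors are appended to the history.
    """
    if params is None:
        params = HomopolymerParams.for_chain(target.n_loci)
    if settings is None:
        settings = LangevinSettings()
    if schedule is None:
        schedule = AnnealingSchedule()
    n = target.n_loci
    bias = BiasField.zeros(n)
    lr = learning_rate
    window = 0.5 * schedule.total_duration
    stride = max(settings.timestep, window / 50.0)

    rng = np.random.default_rng(np.random.SeedSequence([settings.seed, 0xC0DE]))
    initials = cold_start_configurations(n, params, rng, n_replicas)

    history: list[tuple[float, float]] = []
    P_sim_map = None
    ensemble = None
    converged = diverged = False
    rising = 0
    lr_halved = False

    for it in range(max_iter):
        lr_it = lr if lr_decay is None else lr / (1.0 + it / lr_decay)
        stage = StagePotential(label, params, bias)
        seed_it = int(np.random.SeedSequence([settings.seed, it]).generate_state(1)[0] % (2**31))
        trajs = run_replicas(initials, stage, replace(settings, seed=seed_it),
                             schedule=schedule, record_stride=stride,
                             n_replicas=n_replicas)
        ensemble = np.concatenate([t.sampling_frames() for t in trajs])
        P_sim_map = estimate_contact_probabilities(
            ensemble, params.contact_cutoff, params.switching_steepness,
            region=target.region,
        )
        mae, pearson = _errors(P_sim_map.P, target.P)
        if history and mae > history[-1][0]:
            rising += 1
        else:
            rising = 0
        history.append((mae, pearson))
        if callback is not None:
            callback(it, mae, pearson)
        state = CalibrationState(len(history), bias, P_sim_map, history, lr_it,
                                 alpha_max, ensemble)
        if mae <= tol:
            converged = True
            break
        if rising >= 3:
            if lr_halved:
                diverged = True
                break
            lr = lr / 2.0
            lr_halved = True
            rising = 0
            state = replace(state, learning_rate=lr if lr_decay is None
                            else lr / (1.0 + it / lr_decay))
        if it < max_iter - 1:
            bias = update_alpha(state, target)
        initials = [t.frames[-1] for t in trajs]

    if final_eval_replicas and not diverged:
        stage = StagePotential(label, params, bias)
        seed_ev = int(np.random.SeedSequence(
            [settings.seed, 60321]).generate_state(1)[0] % (2**31))
        trajs = run_replicas(initials, stage, replace(settings, seed=seed_ev),
                             schedule=schedule, record_stride=stride,
                             n_replicas=final_eval_replicas)
        extra = np.concatenate([t.sampling_frames() for t in trajs])
        ensemble = np.concatenate([ensemble, extra]) if ensemble is not None else extra
        P_sim_map = estimate_contact_probabilities(
            ensemble, params.contact_cutoff, params.switching_steepness,
            region=target.region,
        )
        mae, pearson = _errors(P_sim_map.P, target.P)
        history.append((mae, pearson))
        if mae <= tol:
            converged = True

    # the returned bias is the one that generated the returned ensemble/P_sim
    return CalibrationState(len(history), bias, P_sim_map, history, lr,
                            alpha_max, ensemble, converged=converged,
                            diverged=diverged)
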