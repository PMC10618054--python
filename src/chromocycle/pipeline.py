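"""Config-driven end-to-end runs: synth -> calibrate -> switch -> analyse.

Two scale presets are provided.  ``desk`` (60 beads, 6 replicas, 120 tau
annealed trajectories, 10 calibration rounds) runs a full stage or transition
on one CPU in minutes and is what the analysis scripts and tests exercise;
``production`` (510 beads, 100 replicas, 1000 tau) records the full-scale
protocol and is documented as cluster-scale.  Every artifact directory gets a
manifest with the config, derived seeds and package version, so a rerun with
the same config and seed reproduces the tables exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .contact_maps import (ContactMap, enhanced_contacts, insulation_profile,
                           read_contact_map, write_contact_map)
from .engine import AnnealingSchedule, LangevinSettings
from .maxent import CalibrationState, calibrate, estimate_contact_probabilities
from .metrics import (align_ensemble, delta_M, fluctuation_matrix,
                      free_energy_landscape, geometry)
from .pathways import (ProfileSeries, fit_profile_pca, insulation_observable,
                       enhanced_observable, linear_interpolation_path,
                       path_deviation, project_series)
from .polymer_model import HomopolymerParams, StagePotential
from .switching import (SwitchingRun, cluster_ensemble, select_initials,
                        switch_and_relax, time_resolved_ensemble)

__all__ = [
    "ScalePreset", "RunConfig", "StageResult", "TransitionResult",
    "DESK", "PRODUCTION", "run_stage", "run_transition",
    "run_stage_pipeline", "run_transition_pipeline",
]


@dataclass(frozen=True)
class ScalePreset:
    """Problem sizes for one scale of the pipeline."""

    name: str
    n_loci: int
    n_replicas: int
    max_iter: int
    anneal_total: float          # tau
    anneal_ramp: float           # tau
    switch_duration: float       # tau
    checkpoints: tuple
    switch_stride: float = 1.0   # tau
    cluster_threshold: float = 2.5   # sigma, aligned RMSD
    min_population: float = 0.002
    per_cluster: int = 2
    min_initials: int = 8
    max_initials: int = 12
    interp_steps: int = 11

    def schedule(self) -> AnnealingSchedule:
        return AnnealingSchedule(4.0, 1.0, self.anneal_ramp, self.anneal_total)


DESK = ScalePreset("desk", n_loci=60, n_replicas=6, max_iter=10,
                   anneal_total=120.0, anneal_ramp=30.0,
                   switch_duration=1000.0, checkpoints=(1.0, 10.0, 100.0, 1000.0))
PRODUCTION = ScalePreset("production", n_loci=510, n_replicas=100, max_iter=30,
                         anneal_total=1000.0, anneal_ramp=250.0,
                         switch_duration=1000.0,
                         checkpoints=(1.0, 10.0, 100.0, 1000.0),
                         min_initials=100, max_initials=200)
_PRESETS = {"desk": DESK, "production": PRODUCTION}


@dataclass
class RunConfig:
    """Pipeline configuration; round-trips losslessly through JSON."""

    name: str = "run"
    scale: str = "desk"
    base_seed: int = 0
    output_root: str = "results"
    stage_maps: list = field(default_factory=list)   # (label, path) pairs
    overrides: dict = field(default_factory=dict)    # ScalePreset field overrides

    def preset(self) -> ScalePreset:
        base = _PRESETS[self.scale]
        if self.overrides:
            fields = {f.name for f in dataclasses.fields(ScalePreset)}
            unknown = set(self.overrides) - fields
            if unknown:
                raise ValueError(f"unknown preset overrides: {sorted(unknown)}")
            ov = dict(self.overrides)
            if "checkpoints" in ov:
                ov["checkpoints"] = tuple(ov["checkpoints"])
            base = dataclasses.replace(base, **ov)
        return base

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        data["stage_maps"] = [tuple(x) for x in data.get("stage_maps", [])]
        return cls(**data)


@dataclass
class StageResult:
    """Everything one calibrated stage produces."""

    label: str
    potential: StagePotential
    calibration: CalibrationState
    contact_map: ContactMap      # simulated map of the final ensemble
    ensemble: np.ndarray


@dataclass
class TransitionResult:
    """Artifacts of one landscape-switching transition."""

    run: SwitchingRun
    checkpoint_maps: dict        # time -> ContactMap
    checkpoint_mae: dict         # time -> MAE to the target map
    delta_M_matrices: dict       # time -> ndarray
    geometry_table: pd.DataFrame
    deviation_insulation: float
    deviation_enhanced: float


def _stage_seed(base_seed: int, tag: str) -> int:
    # zlib.crc32 is stable across processes, unlike hash()
    import zlib
    ent = np.random.SeedSequence([base_seed, zlib.crc32(tag.encode())])
    return int(ent.generate_state(1)[0] % (2**31))


def run_stage(target: ContactMap, label: str, preset: ScalePreset,
              seed: int) -> StageResult:
    """Calibrate one stage potential against a target map."""
    if target.n_loci != preset.n_loci:
        raise ValueError(
            f"target has {target.n_loci} loci but the {preset.name} preset "
            f"expects {preset.n_loci}"
        )
    params = HomopolymerParams.for_chain(target.n_loci)
    settings = LangevinSettings(seed=seed)
    state = calibrate(target, params=params, settings=settings,
                      schedule=preset.schedule(), n_replicas=preset.n_replicas,
                      max_iter=preset.max_iter, label=label)
    potential = StagePotential(label, params, state.bias)
    return StageResult(label, potential, state, state.P_sim, state.ensemble)


def _offdiag_mae(A: np.ndarray, B: np.ndarray) -> float:
    n = A.shape[0]
    S = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    mask = np.triu(S >= 2)
    return float(np.mean(np.abs(A[mask] - B[mask])))


def _mean_profile(frames: np.ndarray, params, region, observable) -> np.ndarray:
    cmap = estimate_contact_probabilities(
        frames, params.contact_cutoff, params.switching_steepness, region=region
    )
    return observable(cmap)


def run_transition(source: StageResult, target: StageResult,
                   preset: ScalePreset, seed: int) -> TransitionResult:
    """Cluster, select, switch, and analyse one stage transition."""
    clusters = cluster_ensemble(source.ensemble, preset.cluster_threshold)
    initials = select_initials(clusters, preset.min_population, preset.per_cluster)
    if initials.shape[0] < preset.min_initials:
        # top up with evenly spaced ensemble members (deterministic)
        extra = source.ensemble[
            np.linspace(0, source.ensemble.shape[0] - 1,
                        preset.min_initials - initials.shape[0]).astype(int)
        ]
        initials = np.concatenate([initials, extra])
    initials = initials[: preset.max_initials]

    settings = LangevinSettings(seed=seed)
    run = switch_and_relax(initials, source.potential, target.potential,
                           settings, preset.switch_duration,
                           checkpoint_times=preset.checkpoints,
                           record_stride=preset.switch_stride)

    params = target.potential.params
    region = source.contact_map.region
    times = (0.0,) + tuple(preset.checkpoints)
    aligned0 = align_ensemble(time_resolved_ensemble(run, 0.0))
    M0 = fluctuation_matrix(aligned0)

    checkpoint_maps, checkpoint_mae, dmats = {}, {}, {}
    geo_rows = []
    for t in times:
        ens = time_resolved_ensemble(run, t)
        cmap = estimate_contact_probabilities(
            ens, params.contact_cutoff, params.switching_steepness, region=region
        )
        checkpoint_maps[t] = cmap
        checkpoint_mae[t] = _offdiag_mae(cmap.P, target.contact_map.P)
        if t > 0:
            Mt = fluctuation_matrix(align_ensemble(ens))
            dmats[t] = delta_M(Mt, M0)
        for r, conf in enumerate(ens):
            g = geometry(conf)
            geo_rows.append({"time": t, "replica": r, "Rg": g.Rg, "Delta": g.Delta})
    geometry_table = pd.DataFrame(geo_rows)

    # pathway PCA: fit on endpoint + checkpoint ensemble-mean profiles
    deviations = {}
    for obs_name, observable in (("insulation", insulation_observable()),
                                 ("enhanced", enhanced_observable())):
        fit_profiles = [observable(source.contact_map)]
        sim_profiles = []
        for t in times:
            prof = _mean_profile(time_resolved_ensemble(run, t), params, region,
                                 observable)
            fit_profiles.append(prof)
            sim_profiles.append(prof)
        fit_profiles.append(observable(target.contact_map))
        model = fit_profile_pca(fit_profiles)
        sim_proj = project_series(
            model, ProfileSeries(np.array(times), np.array(sim_profiles)),
            provenance="simulated",
        )
        interp = linear_interpolation_path(source.contact_map,
                                           target.contact_map,
                                           preset.interp_steps, observable)
        interp_proj = project_series(model, interp, provenance="interpolated")
        deviations[obs_name] = path_deviation(sim_proj, interp_proj)

    return TransitionResult(run, checkpoint_maps, checkpoint_mae, dmats,
                            geometry_table, deviations["insulation"],
                            deviations["enhanced"])


# ---------------------------------------------------------------------------
# Config-driven drivers with on-disk artifacts


def _write_manifest(outdir: Path, config: RunConfig, seeds: dict,
                    artifacts: list, name: str = "manifest.json") -> None:
    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "derived_seeds": seeds,
        "artifacts": sorted(str(a) for a in artifacts),
    }
    (outdir / name).write_text(json.dumps(manifest, indent=1))


def run_stage_pipeline(config: RunConfig) -> dict:
    """Calibrate every configured stage map and write its analysis artifacts.

    For each stage: the stage-potential archive, the calibration error log,
    the simulated contact map, per-structure geometry, the free-energy
    landscape grid, the fluctuation matrix, and insulation/enhanced-contact
    observables.  Missing input files are reported before any compute.
    """
    preset = config.preset()
    for label, path in config.stage_maps:
        if not Path(path).is_file():
            raise FileNotFoundError(f"stage map for {label!r} not found: {path}")

    results: dict[str, StageResult] = {}
    root = Path(config.output_root) / config.name
    root.mkdir(parents=True, exist_ok=True)
    seeds, artifacts = {}, []
    for label, path in config.stage_maps:
        from .contact_maps import synthetic_region
        region = synthetic_region(preset.n_loci)
        target = read_contact_map(path, region)
        seed = _stage_seed(config.base_seed, f"stage:{label}")
        seeds[label] = seed
        result = run_stage(target, label, preset, seed)
        results[label] = result

        outdir = root / f"stage_{label}"
        outdir.mkdir(exist_ok=True)
        result.potential.save(outdir / "stage.json")
        pd.DataFrame(result.calibration.error_history,
                     columns=["mae", "pearson"]).to_csv(
            outdir / "calibration.csv", index_label="iteration")
        write_contact_map(result.contact_map, outdir / "simulated_map.txt")
        geo = [geometry(c) for c in result.ensemble]
        pd.DataFrame({"Rg": [g.Rg for g in geo],
                      "Delta": [g.Delta for g in geo]}).to_csv(
            outdir / "geometry.csv", index_label="structure")
        M = fluctuation_matrix(align_ensemble(result.ensemble))
        np.savetxt(outdir / "fluctuation_matrix.txt", M.M, fmt="%.8g")
        ins = insulation_profile(result.contact_map)
        np.savetxt(outdir / "insulation.txt", ins.scores, fmt="%.8g")
        emap = enhanced_contacts(result.contact_map)
        np.savetxt(outdir / "enhanced.txt", emap.matrix, fmt="%.8g")
        land = free_energy_landscape(geo, bins=20)
        np.savetxt(outdir / "free_energy.txt", land.values, fmt="%.8g")
        np.savez_compressed(outdir / "ensemble.npz", frames=result.ensemble)
        artifacts.extend(outdir.glob("*"))
    _write_manifest(root, config, seeds, artifacts, "stages_manifest.json")
    return results


def load_stage_result(stage_dir) -> StageResult:
    """Reload a stage's artifacts written by :func:`run_stage_pipeline`."""
    stage_dir = Path(stage_dir)
    potential = StagePotential.load(stage_dir / "stage.json")
    from .contact_maps import synthetic_region
    region = synthetic_region(potential.n_loci)
    contact_map = read_contact_map(stage_dir / "simulated_map.txt", region)
    ensemble = np.load(stage_dir / "ensemble.npz")["frames"]
    log = pd.read_csv(stage_dir / "calibration.csv")
    history = list(zip(log["mae"], log["pearson"]))
    state = CalibrationState(len(history), potential.bias, contact_map,
                             history, float("nan"), float("nan"), ensemble)
    return StageResult(potential.label, potential, state, contact_map, ensemble)


def run_transition_pipeline(config: RunConfig, results: dict) -> dict:
    """Run landscape switching between every consecutive pair of stages."""
    preset = config.preset()
    labels = [label for label, _ in config.stage_maps]
    if len(labels) < 2:
        raise ValueError("need at least two calibrated stages for transitions")
    root = Path(config.output_root) / config.name
    root.mkdir(parents=True, exist_ok=True)
    transitions: dict[str, TransitionResult] = {}
    seeds, artifacts = {}, []
    for a, b in zip(labels[:-1], labels[1:]):
        tag = f"{a}->{b}"
        seed = _stage_seed(config.base_seed, f"switch:{tag}")
        seeds[tag] = seed
        tr = run_transition(results[a], results[b], preset, seed)
        transitions[tag] = tr
        outdir = root / f"transition_{a}_to_{b}"
        outdir.mkdir(exist_ok=True)
        tr.geometry_table.to_csv(outdir / "geometry_series.csv", index=False)
        pd.DataFrame({"time": list(tr.checkpoint_mae),
                      "mae_to_target": list(tr.checkpoint_mae.values())}).to_csv(
            outdir / "relaxation_mae.csv", index=False)
        for t, dm in tr.delta_M_matrices.items():
            np.savetxt(outdir / f"delta_M_t{t:g}.txt", dm, fmt="%.8g")
        pd.DataFrame([{"observable": "insulation",
                       "deviation": tr.deviation_insulation},
                      {"observable": "enhanced",
                       "deviation": tr.deviation_enhanced}]).to_csv(
            outdir / "pathway_deviation.csv", index=False)
        artifacts.extend(outdir.glob("*"))
    _write_manifest(root, config, seeds, artifacts, "transitions_manifest.json")
    return transitions
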