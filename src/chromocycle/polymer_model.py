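"""Reduced-unit energetics of the coarse-grained chromosome chain.

The chain is a bead-on-a-string homopolymer (one bead per 100 kb locus in the
reference setup) with harmonic pseudo-bonds, a linear-placement-favoured angle
term, a capped soft-core repulsion that lets chain segments cross (emulating
topoisomerase activity), and a half-harmonic spherical confinement sized to a
target nuclear volume fraction.  On top of this sits the Hi-C biasing
potential ``V_bias = sum_{i<j} alpha_ij f(r_ij)`` whose couplings are
calibrated by maximum-entropy iteration (see :mod:`chromocycle.maxent`);
``f`` is a smooth contact indicator whose ensemble mean is the simulated
contact probability.

Units: length sigma (the pseudo-bond scale), energy epsilon, time tau,
bead mass 1; temperatures absorb the Boltzmann constant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _kernels

__all__ = [
    "HomopolymerParams",
    "BiasField",
    "StagePotential",
    "confinement_radius_from_fraction",
    "contact_indicator",
    "homopolymer_energy_forces",
    "bias_energy_forces",
    "total_energy_forces",
    "as_configuration",
]

_ARCHIVE_FORMAT_VERSION = 1


def as_configuration(x) -> np.ndarray:
    """Validate and return an (N, 3) float64 chain configuration."""
    arr = np.ascontiguousarray(x, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 2:
        raise ValueError(f"configuration must be (N>=2, 3), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("configuration contains non-finite coordinates")
    return arr


def confinement_radius_from_fraction(n_beads: int, fraction: float) -> float:
    """Sphere radius at which ``n_beads`` beads of diameter sigma occupy ``fraction``.

    Solves n * (sigma/2)^3 / R^3 = fraction, the convention used to mimic a
    10% chromosome volume fraction inside the nucleus.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if n_beads < 1:
        raise ValueError("need at least one bead")
    return (n_beads / fraction) ** (1.0 / 3.0) / 2.0


@dataclass(frozen=True)
class HomopolymerParams:
    """Parameters of the non-specific homopolymer potential (reduced units).

    ``confinement_radius = None`` disables the wall; ``0.0`` makes the wall a
    full harmonic trap at the origin (useful for single-bead checks).
    """

    bond_length: float = 1.0          # sigma
    bond_stiffness: float = 100.0     # epsilon / sigma^2
    angle_stiffness: float = 2.0      # epsilon, V = k (1 + cos theta)
    softcore_strength: float = 1.0    # epsilon, WCA prefactor
    softcore_cap: float = 4.0         # epsilon, per-pair energy bound
    contact_cutoff: float = 1.8       # sigma, r_c of the contact indicator
    switching_steepness: float = 5.0  # 1 / sigma, eta of the indicator
    confinement_radius: float | None = None  # sigma
    wall_stiffness: float = 100.0     # epsilon / sigma^2

    def __post_init__(self) -> None:
        for name in ("bond_stiffness", "angle_stiffness", "softcore_strength",
                     "wall_stiffness"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.softcore_cap <= 0 or not np.isfinite(self.softcore_cap):
            raise ValueError("softcore_cap must be finite and positive")
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be positive")

    @classmethod
    def for_chain(cls, n_beads: int, volume_fraction: float = 0.10,
                  **overrides) -> "HomopolymerParams":
        """Defaults with the confinement sized to the given volume fraction."""
        radius = confinement_radius_from_fraction(n_beads, volume_fraction)
        return cls(confinement_radius=radius, **overrides)

    def _wall_radius(self) -> float:
        return -1.0 if self.confinement_radius is None else float(self.confinement_radius)


@dataclass
class BiasField:
    """Symmetric alpha_ij coupling matrix of the Hi-C biasing potential.

    The diagonal and both first off-diagonals are exactly zero: adjacent-loci
    probabilities are pinned to 1 by the normalization convention, so biasing
    them would only fight the bond term.
    """

    alpha: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("alpha must be square")
        if not np.all(np.isfinite(a)):
            raise ValueError("alpha must be finite")
        if not np.allclose(a, a.T, atol=1e-12, rtol=0.0):
            raise ValueError("alpha must be symmetric")
        n = a.shape[0]
        for off in (0, 1):
            if np.any(np.diagonal(a, offset=off) != 0.0):
                raise ValueError("alpha must be zero on the diagonal and first off-diagonals")
        self.alpha = np.ascontiguousarray(a)

    @classmethod
    def zeros(cls, n: int) -> "BiasField":
        return cls(np.zeros((n, n)))

    @property
    def n_loci(self) -> int:
        return self.alpha.shape[0]


@dataclass
class StagePotential:
    """Homopolymer parameters plus a calibrated bias field for one cell stage.

    This is the object the landscape-switching protocol swaps: V(Stage) =
    V_homopolymer + V_bias(Stage).
    """

    label: str
    params: HomopolymerParams
    bias: BiasField

    @property
    def n_loci(self) -> int:
        return self.bias.n_loci

    def save(self, path) -> None:
        """Serialize to a single JSON archive (schema-versioned)."""
        payload = {
            "format_version": _ARCHIVE_FORMAT_VERSION,
            "label": self.label,
            "params": {k: v for k, v in self.params.__dict__.items()},
            "alpha": self.bias.alpha.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "StagePotential":
        payload = json.loads(Path(path).read_text())
        version = payload.get("format_version")
        if version != _ARCHIVE_FORMAT_VERSION:
            raise ValueError(f"unsupported stage archive version {version!r}")
        params = HomopolymerParams(**payload["params"])
        return cls(payload["label"], params, BiasField(np.array(payload["alpha"])))


# ---------------------------------------------------------------------------
# Energies and analytic forces


def contact_indicator(r, r_c: float = 1.8, eta: float = 5.0):
    """Smooth per-configuration contact proxy: f(r) = (1 + tanh[eta (r_c - r)]) / 2.

    Monotone non-increasing in r, f(r_c) = 1/2; its ensemble mean is the
    simulated contact probability entering the biasing potential.
    """
    return 0.5 * (1.0 + np.tanh(eta * (r_c - np.asarray(r, dtype=float))))


def homopolymer_energy_forces(conf, params: HomopolymerParams):
    """Energy and analytic forces of the non-specific homopolymer terms."""
    x = as_configuration(conf)
    forces = np.zeros_like(x)
    e = _kernels.homopolymer_ef(
        x, params.bond_length, params.bond_stiffness, params.angle_stiffness,
        params.softcore_strength, params.softcore_cap,
        params._wall_radius(), params.wall_stiffness, forces,
    )
    return float(e), forces


def bias_energy_forces(conf, bias: BiasField, params: HomopolymerParams):
    """Energy and analytic forces of the Hi-C biasing term."""
    x = as_configuration(conf)
    if bias.n_loci != x.shape[0]:
        raise ValueError(
            f"bias field is for {bias.n_loci} loci but the chain has {x.shape[0]}"
        )
    forces = np.zeros_like(x)
    e = _kernels.bias_ef(x, bias.alpha, params.contact_cutoff,
                         params.switching_steepness, forces)
    return float(e), forces


def total_energy_forces(conf, stage: StagePotential):
    """V(Stage) = V_homopolymer + V_bias, with exactly additive forces."""
    e_h, f_h = homopolymer_energy_forces(conf, stage.params)
    e_b, f_b = bias_energy_forces(conf, stage.bias, stage.params)
    return e_h + e_b, f_h + f_b
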