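"""Membrane response: induced transmembrane potential, nanoporation sites,
action-potential bookkeeping, and stochastic transfection.

The induced transmembrane potential uses the steady-state Schwan relation at
its angular maximum, dVm = 1.5 * E * r, with r a cell-scale coupling radius.
Membrane orientation is not tracked on the 2-D grid, so all thresholds act
on magnitudes: a cell porates where |Vm| = |v_rest| + dVm reaches the
poration threshold magnitude (200 mV by default), and is electrically
excitable where the depolarization reaches the action-potential threshold
(15 mV above rest by default).  Action potentials are counted as a
refractory-limited cap, not simulated dynamics.

Transfection of porated cells is stochastic: each porated cell draws an
efficiency p from a clipped Gaussian and realizes delivery as Bernoulli(p),
reproducibly under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .field import FieldGrid, PulseProtocol

__all__ = [
    "MembraneParams",
    "PorationMask",
    "TransfectionGrid",
    "SimSummary",
    "induced_vm",
    "poration_map",
    "ap_events",
    "transfection_map",
    "summarize_simulation",
]


@dataclass(frozen=True)
class MembraneParams:
    """Sciatic-nerve membrane electrophysiology constants.

    Defaults: resting potential -70 mV, action-potential threshold -55 mV,
    nanoporation threshold magnitude 200 mV, refractory period 1 ms,
    conduction velocity 120 m/s, sodium-channel density 600 /µm².
    ``conduction_velocity`` and ``na_channel_density`` are carried and
    reported but drive no dynamics.  ``coupling_radius`` (µm) sets the
    field-to-Vm gain and is an implementation parameter.
    """

    v_rest: float = -70.0
    v_ap_threshold: float = -55.0
    v_poration_threshold: float = 200.0
    refractory: float = 1.0
    conduction_velocity: float = 120.0
    na_channel_density: float = 600.0
    coupling_radius: float = 5.0

    def __post_init__(self):
        if abs(self.v_poration_threshold) <= abs(self.v_rest):
            raise ConfigurationError(
                "|poration threshold| must exceed |resting potential|"
            )
        if self.refractory <= 0:
            raise ConfigurationError("refractory period must be > 0")
        if self.coupling_radius <= 0:
            raise ConfigurationError("coupling_radius must be > 0")

    @property
    def ap_depolarization(self) -> float:
        """Depolarization (mV) from rest to the AP threshold."""
        return abs(self.v_rest) - abs(self.v_ap_threshold)

    def poration_field_threshold(self) -> float:
        """Field level (V/m) at which |Vm| reaches the poration threshold."""
        dvm_volts = (abs(self.v_poration_threshold) - abs(self.v_rest)) * 1e-3
        return dvm_volts / (1.5 * self.coupling_radius * 1e-6)


@dataclass
class PorationMask:
    """Boolean map of nanoporation sites within the tissue domain."""

    porated: np.ndarray
    threshold_field: float

    @property
    def count(self) -> int:
        return int(np.count_nonzero(self.porated))


@dataclass
class TransfectionGrid:
    """Per-cell transfection probability and its realized Bernoulli draw."""

    probability: np.ndarray
    realized: np.ndarray
    mean_efficiency: float
    sd_efficiency: float
    seed: int


@dataclass
class SimSummary:
    """Scalar summary of one simulated treatment."""

    porated_cells: int
    tissue_cells: int
    porated_fraction: float
    realized_cells: int
    realized_fraction: float  # realized / porated (0 when nothing porated)
    max_field: float
    max_vm: float

    def to_dict(self) -> dict:
        return {
            "porated_cells": self.porated_cells,
            "tissue_cells": self.tissue_cells,
            "porated_fraction": self.porated_fraction,
            "realized_cells": self.realized_cells,
            "realized_fraction": self.realized_fraction,
            "max_field_V_per_m": self.max_field,
            "max_vm_mV": self.max_vm,
        }


def induced_vm(
    field: FieldGrid, mem: MembraneParams, tissue: np.ndarray
) -> np.ndarray:
    """Transmembrane-potential magnitude |Vm| (mV) over the tissue domain.

    |Vm| = |v_rest| + 1.5 * |E| * coupling_radius, zero outside tissue.
    """
    dvm_mv = 1.5 * field.values * (mem.coupling_radius * 1e-6) * 1e3
    vm = (abs(mem.v_rest) + dvm_mv) * tissue
    return vm


def poration_map(
    vm: np.ndarray, mem: MembraneParams, tissue: np.ndarray
) -> PorationMask:
    """Threshold |Vm| at the poration level (inclusive) within tissue."""
    porated = (vm >= abs(mem.v_poration_threshold)) & tissue
    return PorationMask(porated=porated, threshold_field=mem.poration_field_threshold())


def ap_events(
    vm: np.ndarray, protocol: PulseProtocol, mem: MembraneParams
) -> np.ndarray:
    """Refractory-capped action-potential count per cell over the train.

    A cell whose depolarization reaches the AP threshold fires
    ``floor(pulse_ms / refractory)`` times per pulse; subthreshold cells
    fire zero.
    """
    per_pulse = int(np.floor(protocol.pulse_ms / mem.refractory))
    depol = vm - abs(mem.v_rest)
    supra = (vm > 0) & (depol >= mem.ap_depolarization)
    return supra.astype(np.int64) * per_pulse * protocol.n_pulses


def transfection_map(
    por: PorationMask,
    mean_eff: float = 0.6,
    sd_eff: float = 0.15,
    seed: int = 0,
) -> TransfectionGrid:
    """Draw per-cell transfection efficiencies and realize delivery.

    Each porated cell draws p ~ Normal(mean_eff, sd_eff) clipped to [0, 1],
    then realizes transfection as Bernoulli(p).  Draws are made in row-major
    order over porated cells only, so the result is bit-reproducible for a
    fixed seed and mask.
    """
    if not 0.0 <= mean_eff <= 1.0:
        raise ConfigurationError("mean_eff must lie in [0, 1]")
    if sd_eff < 0:
        raise ConfigurationError("sd_eff must be >= 0")
    shape = por.porated.shape
    prob = np.zeros(shape, dtype=float)
    realized = np.zeros(shape, dtype=bool)
    idx = np.flatnonzero(por.porated)
    rng = np.random.default_rng(seed)
    if idx.size:
        if sd_eff == 0:
            p = np.full(idx.size, float(mean_eff))
        else:
            p = np.clip(mean_eff + sd_eff * rng.standard_normal(idx.size), 0.0, 1.0)
        u = rng.random(idx.size)
        prob.ravel()[idx] = p
        realized.ravel()[idx] = u < p
    return TransfectionGrid(
        probability=prob,
        realized=realized,
        mean_efficiency=mean_eff,
        sd_efficiency=sd_eff,
        seed=seed,
    )


def summarize_simulation(
    por: PorationMask,
    trans: TransfectionGrid,
    tissue: np.ndarray,
    field: FieldGrid | None = None,
    vm: np.ndarray | None = None,
) -> SimSummary:
    """Collapse the outcome maps to scalar counts and fractions."""
    n_tissue = int(np.count_nonzero(tissue))
    n_por = por.count
    n_real = int(np.count_nonzero(trans.realized))
    return SimSummary(
        porated_cells=n_por,
        tissue_cells=n_tissue,
        porated_fraction=n_por / n_tissue if n_tissue else 0.0,
        realized_cells=n_real,
        realized_fraction=n_real / n_por if n_por else 0.0,
        max_field=float(field.values.max()) if field is not None else float("nan"),
        max_vm=float(vm.max()) if vm is not None else float("nan"),
    )
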