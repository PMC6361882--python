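"""Resolution-recovery resampling ("guess" cones).

Each Markov step of the resolution-recovery variants replaces the
measured detector outputs with a stochastic guess of the true values:

* deposited energies of the first two interactions are redrawn from
  ``N(E_i, sigma_{E_i})`` with sigma from the detector energy model
  evaluated at the *measured* energy (the sigma(E) ~ sigma(E_true)
  approximation, applied literally); the third deposit of a triple is
  never redrawn — it does not enter the energy recovery;
* interaction positions are redrawn uniformly over the pixel footprint
  in the transverse plane and over the depth-error interval along the
  camera axis (six uniforms per double, nine per triple).

The corrected quantities rebuild the origin cone; invalid kinematics
make the Markov step a rejection (the previous origin is kept).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .camera import CameraGeometry, DetectorStage, EnergyResolutionModel, Interaction, ListModeEvent
from .kinematics import (
    ConeParameters,
    build_cone,
    geometric_scatter_cos,
    recover_total_energy_triple,
)

__all__ = [
    "CorrectionPolicy",
    "sample_corrected_energy",
    "sample_corrected_position",
    "resample_cone",
]

_VARIANT_FLAGS = {
    # variant: (correct_position, correct_energy, precalc_init)
    "soe": (False, False, False),
    "oerr": (True, False, False),
    "oerr_e": (True, True, False),
    "oerr_e_pre": (True, True, True),
}


@dataclass(frozen=True)
class CorrectionPolicy:
    """Which detector-resolution corrections a reconstruction variant
    applies (see ``CorrectionPolicy.for_variant``)."""

    correct_position: bool
    correct_energy: bool
    precalc_init: bool
    energy_model: EnergyResolutionModel = field(default_factory=EnergyResolutionModel)

    @classmethod
    def for_variant(cls, variant: str,
                    energy_model: EnergyResolutionModel | None = None) -> "CorrectionPolicy":
        try:
            pos, ene, pre = _VARIANT_FLAGS[variant]
        except KeyError:
            raise ValueError(
                f"unknown variant {variant!r}; expected one of {sorted(_VARIANT_FLAGS)}"
            ) from None
        return cls(pos, ene, pre, energy_model or EnergyResolutionModel())


def sample_corrected_energy(energy: float, model: EnergyResolutionModel,
                            rng: np.random.Generator, max_retries: int = 100) -> float:
    """One Normal draw around the measured energy; nonpositive draws are
    redrawn (at prompt-gamma energies this is a negligible-probability
    branch, so no truncation bias correction is applied)."""
    if energy <= 0:
        raise ValueError("energy must be positive")
    sigma = float(model.sigma_mev(energy))
    if sigma == 0.0:
        return float(energy)
    for _ in range(max_retries):
        e = rng.normal(energy, sigma)
        if e > 0:
            return float(e)
    return float(energy)


def sample_corrected_position(interaction: Interaction, stage: DetectorStage,
                              rng: np.random.Generator) -> np.ndarray:
    """Uniform draw over the pixel footprint (lab y, z) and the
    depth-error interval (lab x, clipped to the crystal)."""
    x, y, z = interaction.position
    u = rng.uniform(-0.5, 0.5, size=3)
    x2 = x + u[0] * stage.depth_error
    x2 = float(np.clip(x2, *stage.x_range))
    y2 = y + u[1] * stage.pixel_pitch_u
    z2 = z + u[2] * stage.pixel_pitch_v
    return np.array([x2, y2, z2])


def resample_cone(event: ListModeEvent, policy: CorrectionPolicy,
                  geometry: CameraGeometry, rng: np.random.Generator) -> ConeParameters | None:
    """Build the (possibly corrected) origin cone for one Markov step.

    Applies position and/or energy corrections per the policy, recomputes
    the total energy (sum for doubles, geometric recovery for triples)
    and returns the cone, or ``None`` when the corrected kinematics are
    invalid (the caller keeps the previous origin).
    """
    ints = list(event.interactions)
    if policy.correct_position:
        positions = [
            sample_corrected_position(it, geometry.stage(it.stage_id), rng) for it in ints
        ]
    else:
        positions = [it.position for it in ints]
    if policy.correct_energy:
        energies = [
            sample_corrected_energy(it.energy, policy.energy_model, rng)
            for it in ints[:2]
        ]
    else:
        energies = [it.energy for it in ints[:2]]

    if event.n_interactions == 2:
        e_total = energies[0] + energies[1]
    else:
        c = geometric_scatter_cos(positions[0], positions[1], positions[2])
        if not np.isfinite(c) or c >= 1.0 - 1e-12:
            return None
        e_total = recover_total_energy_triple(energies[0], energies[1], c)
    if not np.isfinite(e_total):
        return None

    full_energies = list(energies)
    if len(ints) == 3:
        full_energies.append(ints[2].energy)  # E3 is never corrected
    corrected = ListModeEvent(
        event_id=event.event_id,
        interactions=tuple(
            Interaction(stage_id=it.stage_id, position=p, energy=e)
            for it, p, e in zip(ints, positions, full_energies)
        ),
        species_label=event.species_label,
    )
    return build_cone(corrected, e_total)
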