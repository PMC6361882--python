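"""Three-stage pixelated Compton-camera model.

Coordinate conventions (lab frame, all lengths in mm, energies in MeV
unless stated otherwise):

* the proton beam travels along ``+z`` (depth into the phantom), with the
  phantom entrance at ``z = 0``;
* the camera axis is ``+x``, perpendicular to the beam; each detector
  stage is a slab whose pixel grid spans the ``(y, z)`` plane and whose
  crystal depth runs along ``x``;
* within a stage, pixel centres are reported for the transverse ``(y, z)``
  coordinates while the interaction depth ``x`` is measured with a
  bounded uniform error (``depth_error``).

The energy-resolution model is the FWHM form ``a + b*sqrt(E)`` with ``E``
in keV (the only convention consistent with CZT arrays quoted at 1.64%
relative FWHM at 662 keV and 5.13% at 59.5 keV), or alternatively a
proportional-sigma model ``sigma_E = eta * sqrt(E)`` with ``E`` in MeV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DetectorStage",
    "CameraGeometry",
    "EnergyResolutionModel",
    "Interaction",
    "ListModeEvent",
    "energy_fwhm",
    "pixel_quantize",
]


@dataclass(frozen=True)
class DetectorStage:
    """One pixelated CZT detection stage.

    Parameters
    ----------
    stage_id : int
        1-based stage number in scatter order (1..3).
    standoff : float
        Lab ``x`` of the stage entrance face, mm.
    n_pixels_u, n_pixels_v : int
        Pixel counts along lab ``y`` and lab ``z``.
    pixel_pitch_u, pixel_pitch_v : float
        Pixel pitches ``D_ix, D_iy`` along lab ``y`` and ``z``, mm.
    crystal_depth : float
        Crystal thickness along the camera axis (lab ``x``), mm.
    depth_error : float
        Half-width *total* span of the uniform depth-measurement error
        ``delta_iz``, mm (the measured depth is uniform within
        ``+-depth_error/2`` of the true depth).
    center_u, center_v : float
        Lab ``(y, z)`` of the pixel-grid centre (the camera axis).
    """

    stage_id: int
    standoff: float
    n_pixels_u: int
    n_pixels_v: int
    pixel_pitch_u: float
    pixel_pitch_v: float
    crystal_depth: float
    depth_error: float = 0.0
    center_u: float = 0.0
    center_v: float = 0.0

    def __post_init__(self) -> None:
        if self.pixel_pitch_u <= 0 or self.pixel_pitch_v <= 0:
            raise ValueError("pixel pitches must be positive")
        if self.crystal_depth <= 0:
            raise ValueError("crystal_depth must be positive")
        if self.depth_error < 0:
            raise ValueError("depth_error must be nonnegative")

    # -- derived extents ---------------------------------------------------
    @property
    def x_range(self) -> tuple[float, float]:
        """Depth range ``[entrance, back]`` of the crystal along lab x."""
        return (self.standoff, self.standoff + self.crystal_depth)

    @property
    def u_range(self) -> tuple[float, float]:
        half = 0.5 * self.n_pixels_u * self.pixel_pitch_u
        return (self.center_u - half, self.center_u + half)

    @property
    def v_range(self) -> tuple[float, float]:
        half = 0.5 * self.n_pixels_v * self.pixel_pitch_v
        return (self.center_v - half, self.center_v + half)

    def contains(self, position: np.ndarray) -> bool:
        x, y, z = np.asarray(position, dtype=float)
        (x0, x1), (u0, u1), (v0, v1) = self.x_range, self.u_range, self.v_range
        return (x0 <= x <= x1) and (u0 <= y <= u1) and (v0 <= z <= v1)


@dataclass(frozen=True)
class CameraGeometry:
    """Ordered three-stage camera layout.

    ``stage_separation`` is the air gap between the back face of one stage
    and the entrance face of the next, so consecutive standoffs differ by
    ``stage_separation + crystal_depth``.
    """

    stages: tuple[DetectorStage, ...]
    stage_separation: float
    phantom_to_stage1: float
    axis_yz: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self) -> None:
        if len(self.stages) != 3:
            raise ValueError("a three-stage camera needs exactly 3 stages")
        xs = [s.standoff for s in self.stages]
        if not all(b > a for a, b in zip(xs, xs[1:])):
            raise ValueError("stages must be ordered by increasing standoff")
        for a, b in zip(self.stages, self.stages[1:]):
            gap = b.standoff - (a.standoff + a.crystal_depth)
            if not np.isclose(gap, self.stage_separation, atol=1e-9):
                raise ValueError(
                    "standoff differences must equal stage_separation + crystal_depth"
                )

    def stage(self, stage_id: int) -> DetectorStage:
        return self.stages[stage_id - 1]

    @classmethod
    def from_stage_specs(
        cls,
        pixel_counts: tuple[tuple[int, int], ...],
        pixel_pitch: float,
        crystal_depth: float,
        depth_error: float,
        stage_separation: float,
        phantom_to_stage1: float,
        axis_yz: tuple[float, float] = (0.0, 100.0),
    ) -> "CameraGeometry":
        stages = []
        x = phantom_to_stage1
        for i, (nu, nv) in enumerate(pixel_counts, start=1):
            stages.append(
                DetectorStage(
                    stage_id=i,
                    standoff=x,
                    n_pixels_u=nu,
                    n_pixels_v=nv,
                    pixel_pitch_u=pixel_pitch,
                    pixel_pitch_v=pixel_pitch,
                    crystal_depth=crystal_depth,
                    depth_error=depth_error,
                    center_u=axis_yz[0],
                    center_v=axis_yz[1],
                )
            )
            x += crystal_depth + stage_separation
        return cls(
            stages=tuple(stages),
            stage_separation=stage_separation,
            phantom_to_stage1=phantom_to_stage1,
            axis_yz=axis_yz,
        )

    @classmethod
    def small_phantom(cls) -> "CameraGeometry":
        """Default setup for the 10x10x20 cm phantom: stages 1-2 are 25x25
        arrays of 2x2x15 mm CZT pixels, stage 3 is 50x50 of the same
        pixels, 50 mm gaps, camera 150 mm from the beam axis, 1 mm depth
        error."""
        return cls.from_stage_specs(
            pixel_counts=((25, 25), (25, 25), (50, 50)),
            pixel_pitch=2.0,
            crystal_depth=15.0,
            depth_error=1.0,
            stage_separation=50.0,
            phantom_to_stage1=150.0,
        )

    @classmethod
    def large_phantom(cls) -> "CameraGeometry":
        """Setup for the 20x20x20 cm phantom: 1x1x15 mm pixels with the
        same total CZT areas (50x50 and 100x100 arrays)."""
        return cls.from_stage_specs(
            pixel_counts=((50, 50), (50, 50), (100, 100)),
            pixel_pitch=1.0,
            crystal_depth=15.0,
            depth_error=1.0,
            stage_separation=50.0,
            phantom_to_stage1=150.0,
        )


@dataclass(frozen=True)
class EnergyResolutionModel:
    """Detector energy resolution.

    ``ab_fwhm``: FWHM(E) = max(0, a + b*sqrt(E)) with E and the FWHM in
    keV, sigma_E = FWHM/2.355.  ``eta_sqrt``: sigma_E = eta*sqrt(E) with E
    in MeV.  Defaults reproduce a CZT pixel array (a = -0.2892 keV,
    b = 0.4332 keV^(1/2)) and eta = 1.5%.
    """

    kind: str = "ab_fwhm"
    a: float = -0.2892
    b: float = 0.4332
    eta: float = 0.015

    def __post_init__(self) -> None:
        if self.kind not in ("ab_fwhm", "eta_sqrt"):
            raise ValueError(f"unknown energy model kind: {self.kind!r}")

    def fwhm_kev(self, energy_kev):
        return energy_fwhm(energy_kev, self)

    def sigma_mev(self, energy_mev):
        """Standard deviation of the measured energy, MeV."""
        energy_mev = np.asarray(energy_mev, dtype=float)
        if self.kind == "ab_fwhm":
            fwhm = np.maximum(0.0, self.a + self.b * np.sqrt(energy_mev * 1e3))
            return fwhm / 2.355 / 1e3
        return self.eta * np.sqrt(energy_mev)


def energy_fwhm(energy_kev, model: EnergyResolutionModel):
    """FWHM of the measured-energy distribution, keV.

    Clamped at zero below the (unreachable above the 1 MeV analysis cut)
    point where ``a + b*sqrt(E)`` would go negative.
    """
    energy_kev = np.asarray(energy_kev, dtype=float)
    if np.any(energy_kev <= 0):
        raise ValueError("energy must be positive")
    if model.kind == "ab_fwhm":
        return np.maximum(0.0, model.a + model.b * np.sqrt(energy_kev))
    # eta_sqrt: sigma in MeV, convert the argument and result through keV
    return 2.355 * model.eta * np.sqrt(energy_kev / 1e3) * 1e3


@dataclass(frozen=True)
class Interaction:
    """One measured interaction: stage, position ``L_i`` (pixel-centre
    transverse coordinates plus measured depth), deposited energy."""

    stage_id: int
    position: np.ndarray
    energy: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.energy <= 0:
            raise ValueError("deposited energy must be positive")


@dataclass(frozen=True)
class ListModeEvent:
    """One detected photon: 2 or 3 interactions in scatter order."""

    event_id: int
    interactions: tuple[Interaction, ...]
    species_label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "interactions", tuple(self.interactions))
        n = len(self.interactions)
        if n not in (2, 3):
            raise ValueError("an event has exactly 2 or 3 interactions")
        ids = [i.stage_id for i in self.interactions]
        if len(set(ids)) != n:
            raise ValueError("interactions must be in distinct stages")

    @property
    def n_interactions(self) -> int:
        return len(self.interactions)


def pixel_quantize(true_position, stage: DetectorStage, rng: np.random.Generator):
    """Degrade a true interaction position to what the detector reports.

    Transverse coordinates snap to the centre of the containing pixel;
    the depth (lab ``x``) is perturbed by Uniform(-depth_error/2,
    +depth_error/2) and clipped to the crystal.  Returns ``None`` if the
    position lies outside the stage (not detected).
    """
    p = np.asarray(true_position, dtype=float)
    if not stage.contains(p):
        return None
    x, y, z = p
    u0, _ = stage.u_range
    v0, _ = stage.v_range
    iu = min(int((y - u0) / stage.pixel_pitch_u), stage.n_pixels_u - 1)
    iv = min(int((z - v0) / stage.pixel_pitch_v), stage.n_pixels_v - 1)
    y_meas = u0 + (iu + 0.5) * stage.pixel_pitch_u
    z_meas = v0 + (iv + 0.5) * stage.pixel_pitch_v
    x_meas = x + rng.uniform(-0.5, 0.5) * stage.depth_error
    x_meas = float(np.clip(x_meas, *stage.x_range))
    return np.array([x_meas, y_meas, z_meas])
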