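"""Synthetic list-mode generator with an analytically known source.

This module is the stand-in for a full Monte Carlo proton-transport +
detector simulation.  The emitted prompt-gamma (PG) field is a
parametric model: a depth-emission density along the beam (linear rise
plus a Bragg-peak Gaussian, cut off distally by a sigmoid) and a
transverse Gaussian beam spot.  Photon transport is replaced by direct
geometric construction: for each sampled origin, interaction vertices
are drawn inside the designated detector stages and the deposited
energies are set *exactly* consistent with Compton kinematics along the
resulting polyline, so that with all resolution effects disabled every
event's origin cone contains its true origin to numerical precision.
Detector degradation is then applied on top: transverse pixel
quantization, a bounded uniform depth error, and Gaussian energy blur
from the camera's energy-resolution model.

Deliberately not modelled: Klein-Nishina cross-section weighting
(optional flag), attenuation and secondary interactions in the phantom,
Doppler broadening, background/annihilation contamination (optional
injection for window-rejection tests), detector efficiency vs energy.
The per-origin detection probability is constant by construction, so the
depth density of detected-event origins equals the emission density and
the model's analytic falloff positions are the ground truth for
reconstruction accuracy.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.special import expit

from .camera import CameraGeometry, EnergyResolutionModel, ListModeEvent
from .io import ListModeData, write_image, write_pglm
from .kinematics import (
    MEC2,
    EnergyWindows,
    geometric_scatter_cos,
    recover_total_energy_triple,
)
from .metrics import Profile1D, ProfileMetrics, measure
from .recon import VOIGrid

__all__ = [
    "EmissionModel",
    "GroundTruth",
    "analytic_profile_metrics",
    "simulate_event",
    "events_from_origins",
    "generate_events",
    "simulate_dataset",
    "generate_dataset",
]

#: double/triple mix of detected coincidences (64k doubles vs 184k triples)
DEFAULT_TRIPLE_FRACTION = 0.74

#: detected coincidence counts per PG line used in the study conditions
DEFAULT_EVENT_COUNTS = {"14N": 88_000, "12C": 74_000, "15O": 41_000, "16O": 45_000}


@dataclass(frozen=True)
class EmissionModel:
    """Parametric PG source with analytically known falloff positions.

    The (unnormalized) depth-emission density is

        f(z) = max(0, p0 + p1*z + A*exp(-(z - z_p)^2 / (2 s_p^2)))
               * logistic((z_f - z) / s),      z_f = z_p + falloff_offset

    i.e. an entrance plateau with a linear rise, a Bragg-peak Gaussian,
    and a distal sigmoid cutoff; transverse (x, y) are Gaussian with
    ``sigma_t`` around the beam axis.  All lengths mm, energies MeV.
    """

    line_energy: float
    p0: float = 0.3
    p1: float = 0.003          # mm^-1
    amplitude: float = 1.0
    peak_z: float = 101.0
    sigma_peak: float = 2.5
    falloff_offset: float = 2.3
    sigmoid_scale: float = 1.0
    sigma_t: float = 3.0
    depth_range: tuple[float, float] = (0.0, 200.0)
    species: str = ""

    @property
    def falloff_center(self) -> float:
        return self.peak_z + self.falloff_offset

    def depth_pdf(self, z) -> np.ndarray:
        """Unnormalized emission density; zero outside ``depth_range``."""
        z = np.asarray(z, dtype=float)
        base = self.p0 + self.p1 * z + self.amplitude * np.exp(
            -((z - self.peak_z) ** 2) / (2.0 * self.sigma_peak**2)
        )
        base = np.maximum(base, 0.0)
        if self.sigmoid_scale == 0.0:
            sig = np.where(z < self.falloff_center, 1.0,
                           np.where(z == self.falloff_center, 0.5, 0.0))
        else:
            sig = expit((self.falloff_center - z) / self.sigmoid_scale)
        lo, hi = self.depth_range
        return np.where((z >= lo) & (z <= hi), base * sig, 0.0)

    def _depth_cdf_grid(self, n: int = 20_001):
        lo, hi = self.depth_range
        z = np.linspace(lo, hi, n)
        f = self.depth_pdf(z)
        cdf = np.concatenate([[0.0], np.cumsum((f[1:] + f[:-1]) * 0.5 * np.diff(z))])
        if cdf[-1] <= 0:
            raise ValueError("emission density integrates to zero")
        return z, cdf / cdf[-1]

    def sample_origin(self, rng: np.random.Generator, n: int,
                      transverse_bounds: float = 50.0) -> np.ndarray:
        """n origins (x, y, z): depth by inverse-CDF on a fine grid,
        transverse Gaussian truncated to ``|x|, |y| <= transverse_bounds``."""
        z_grid, cdf = self._depth_cdf_grid()
        z = np.interp(rng.random(n), cdf, z_grid)
        if self.sigma_t == 0.0:
            xy = np.zeros((n, 2))
        else:
            xy = rng.normal(0.0, self.sigma_t, size=(n, 2))
            bad = np.max(np.abs(xy), axis=1) > transverse_bounds
            while np.any(bad):
                xy[bad] = rng.normal(0.0, self.sigma_t, size=(int(bad.sum()), 2))
                bad = np.max(np.abs(xy), axis=1) > transverse_bounds
        return np.column_stack([xy[:, 0], xy[:, 1], z])

    # -- presets -----------------------------------------------------------
    @classmethod
    def preset(cls, species: str) -> "EmissionModel":
        """Per-line emission presets for a 120 MeV beam in water.

        The 12C/15O/16O profiles are Bragg-peak-like (concentrated peak
        just before the distal edge); 14N is broad and line-like (large
        peak width, shallow distal slope), emulating its weak correlation
        with the dose peak.
        """
        try:
            return _PRESETS[species]
        except KeyError:
            raise ValueError(
                f"unknown species {species!r}; expected one of {sorted(_PRESETS)}"
            ) from None


_PRESETS = {
    # broad, line-like profile with a shallow distal slope
    "14N": EmissionModel(
        line_energy=2.31, p0=0.9, p1=0.001, amplitude=0.55,
        peak_z=88.0, sigma_peak=11.0, falloff_offset=5.5, sigmoid_scale=6.0,
        species="14N",
    ),
    "12C": EmissionModel(
        line_energy=4.44, p0=0.35, p1=0.003, amplitude=0.9,
        peak_z=101.2, sigma_peak=3.0, falloff_offset=2.3, sigmoid_scale=1.0,
        species="12C",
    ),
    "15O": EmissionModel(
        line_energy=5.25, p0=0.35, p1=0.003, amplitude=0.8,
        peak_z=98.7, sigma_peak=3.5, falloff_offset=3.6, sigmoid_scale=2.5,
        species="15O",
    ),
    # sharpest peak / closest dose correlation of the four lines
    "16O": EmissionModel(
        line_energy=6.13, p0=0.25, p1=0.003, amplitude=1.0,
        peak_z=101.3, sigma_peak=2.5, falloff_offset=3.3, sigmoid_scale=1.2,
        species="16O",
    ),
}


def analytic_profile_metrics(model: EmissionModel, smoothing_fwhm: float = 2.0,
                             dz: float = 0.01) -> ProfileMetrics:
    """Deterministic ground-truth metrics of the smoothed emission
    profile (peak, 80%/50% distal falloffs, width at 80%), computed on a
    dense depth grid so the interpolation error is ~``dz``."""
    lo, hi = model.depth_range
    z = np.arange(lo, hi + dz / 2, dz)
    f = model.depth_pdf(z)
    if smoothing_fwhm > 0:
        f = gaussian_filter1d(f, sigma=smoothing_fwhm / 2.355 / dz, mode="nearest")
    return measure(Profile1D(positions=z, values=f))


@dataclass
class GroundTruth:
    """True origins of the accepted events (binned on the VOI grid) plus
    the analytic metrics of the smoothed emission profile."""

    voi: VOIGrid
    histogram: np.ndarray
    metrics: ProfileMetrics
    model: EmissionModel

    def __post_init__(self) -> None:
        assert tuple(self.histogram.shape) == tuple(self.voi.dims)


# ---------------------------------------------------------------------------
# event construction


def _uniform_in_stage(stage, rng: np.random.Generator, n: int) -> np.ndarray:
    (x0, x1), (u0, u1), (v0, v1) = stage.x_range, stage.u_range, stage.v_range
    out = np.empty((n, 3))
    out[:, 0] = rng.uniform(x0, x1, n)
    out[:, 1] = rng.uniform(u0, u1, n)
    out[:, 2] = rng.uniform(v0, v1, n)
    return out


def _quantize_batch(p: np.ndarray, stage, rng: np.random.Generator) -> np.ndarray:
    """Vectorized counterpart of :func:`pgoe.camera.pixel_quantize` for
    points known to lie inside the stage."""
    out = np.empty_like(p)
    u0, _ = stage.u_range
    v0, _ = stage.v_range
    iu = np.minimum(((p[:, 1] - u0) / stage.pixel_pitch_u).astype(int),
                    stage.n_pixels_u - 1)
    iv = np.minimum(((p[:, 2] - v0) / stage.pixel_pitch_v).astype(int),
                    stage.n_pixels_v - 1)
    out[:, 1] = u0 + (iu + 0.5) * stage.pixel_pitch_u
    out[:, 2] = v0 + (iv + 0.5) * stage.pixel_pitch_v
    x = p[:, 0] + rng.uniform(-0.5, 0.5, len(p)) * stage.depth_error
    out[:, 0] = np.clip(x, *stage.x_range)
    return out


def _blur_energies(e: np.ndarray, model: EnergyResolutionModel,
                   rng: np.random.Generator, max_retries: int = 100) -> np.ndarray:
    sigma = model.sigma_mev(e)
    out = rng.normal(e, sigma)
    for _ in range(max_retries):
        bad = out <= 0
        if not np.any(bad):
            break
        out[bad] = rng.normal(e[bad], sigma[bad])
    out[out <= 0] = e[out <= 0]
    return out


def _klein_nishina_accept(e_in: np.ndarray, cos_t: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    """Rejection mask under the Klein-Nishina differential cross-section
    (normalized to its maximum over the angle range)."""
    eps = e_in / MEC2
    r = 1.0 / (1.0 + eps * (1.0 - cos_t))  # E_out / E_in
    kn = r**2 * (r + 1.0 / r - (1.0 - cos_t**2))
    kn_fwd = 2.0  # value at cos_t -> 1 (r -> 1): r+1/r - sin^2 = 2
    return rng.random(len(e_in)) <= kn / kn_fwd


def events_from_origins(origins: np.ndarray, line_energy: float,
                        geometry: CameraGeometry,
                        energy_model: EnergyResolutionModel,
                        rng: np.random.Generator,
                        triple_fraction: float = DEFAULT_TRIPLE_FRACTION,
                        blur: bool = True, quantize: bool = True,
                        klein_nishina: bool = False):
    """One event attempt per origin; returns ``(data, valid, true_pos)``.

    ``valid`` marks attempts with realisable kinematics; ``true_pos`` are
    the exact (pre-degradation) interaction vertices of the valid events.
    Doubles scatter in stage 1 and are fully absorbed in stage 2; triples
    scatter in stages 1-2 and deposit the remainder in stage 3 (the third
    deposit is recorded but carries no kinematic information for the
    reconstruction).
    """
    origins = np.asarray(origins, dtype=float)
    m = len(origins)
    s1, s2, s3 = geometry.stages
    p1 = _uniform_in_stage(s1, rng, m)
    p2 = _uniform_in_stage(s2, rng, m)
    p3 = _uniform_in_stage(s3, rng, m)
    is_triple = rng.random(m) < triple_fraction

    d01 = p1 - origins
    cos1 = geometric_scatter_cos(origins, p1, p2)
    e0 = line_energy
    esc1 = e0 / (1.0 + e0 / MEC2 * (1.0 - cos1))
    e1 = e0 - esc1
    cos2 = geometric_scatter_cos(p1, p2, p3)
    esc2 = esc1 / (1.0 + esc1 / MEC2 * (1.0 - cos2))
    e2 = np.where(is_triple, esc1 - esc2, esc1)
    e3 = np.where(is_triple, esc2, 0.0)

    valid = (
        np.isfinite(cos1) & (cos1 < 1.0 - 1e-12)
        & (e1 > 1e-9) & (e2 > 1e-9)
        & np.all(np.isfinite(d01), axis=1)
    )
    valid &= ~is_triple | (np.isfinite(cos2) & (cos2 < 1.0 - 1e-12) & (e3 > 1e-9))
    if klein_nishina:
        valid &= _klein_nishina_accept(np.full(m, e0), cos1, rng)
        acc2 = _klein_nishina_accept(esc1, cos2, rng)
        valid &= ~is_triple | acc2

    idx = np.flatnonzero(valid)
    n = len(idx)
    true_pos = np.full((n, 3, 3), np.nan)
    true_pos[:, 0] = p1[idx]
    true_pos[:, 1] = p2[idx]
    true_pos[:, 2] = np.where(is_triple[idx, None], p3[idx], np.nan)

    meas = true_pos.copy()
    if quantize:
        meas[:, 0] = _quantize_batch(true_pos[:, 0], s1, rng)
        meas[:, 1] = _quantize_batch(true_pos[:, 1], s2, rng)
        trip = is_triple[idx]
        if np.any(trip):
            meas[trip, 2] = _quantize_batch(true_pos[trip, 2], s3, rng)

    ene = np.column_stack([e1[idx], e2[idx], e3[idx]])
    if blur:
        flat = ene.ravel()
        pres = flat > 0
        flat[pres] = _blur_energies(flat[pres], energy_model, rng)
        ene = flat.reshape(ene.shape)
    ene[~is_triple[idx], 2] = np.nan

    nint = np.where(is_triple[idx], 3, 2).astype(np.int8)
    stg = np.tile(np.array([1, 2, 3], dtype=np.int8), (n, 1))
    stg[nint == 2, 2] = 0
    meas[nint == 2, 2] = np.nan
    data = ListModeData(
        n_interactions=nint,
        positions=meas,
        energies=ene,
        stage_ids=stg,
        species=np.array([""] * n, dtype=object),
        event_ids=np.arange(n, dtype=np.int64),
    )
    return data, valid, true_pos


def simulate_event(origin, line_energy: float, geometry: CameraGeometry,
                   energy_model: EnergyResolutionModel, rng: np.random.Generator,
                   kind: str | None = None, blur: bool = True,
                   quantize: bool = True) -> ListModeEvent | None:
    """Single-event convenience wrapper; ``kind`` forces 'double' or
    'triple'.  Returns ``None`` when the drawn polyline is kinematically
    degenerate."""
    tf = {"double": 0.0, "triple": 1.0}.get(kind, DEFAULT_TRIPLE_FRACTION)
    data, valid, _ = events_from_origins(
        np.asarray(origin, dtype=float)[None, :], line_energy, geometry,
        energy_model, rng, triple_fraction=tf, blur=blur, quantize=quantize,
    )
    if len(data) == 0:
        return None
    return data.to_events()[0]


def _total_energies(data: ListModeData) -> np.ndarray:
    et = data.energies[:, 0] + data.energies[:, 1]
    trip = data.n_interactions == 3
    if np.any(trip):
        c = geometric_scatter_cos(
            data.positions[trip, 0], data.positions[trip, 1], data.positions[trip, 2]
        )
        et = et.copy()
        et[trip] = recover_total_energy_triple(
            data.energies[trip, 0], data.energies[trip, 1], c
        )
    return et


def generate_events(model: EmissionModel, n_events: int,
                    geometry: CameraGeometry,
                    energy_model: EnergyResolutionModel,
                    rng: np.random.Generator,
                    windows: EnergyWindows | None = None,
                    triple_fraction: float = DEFAULT_TRIPLE_FRACTION,
                    blur: bool = True, quantize: bool = True,
                    klein_nishina: bool = False,
                    background_fraction: float = 0.0,
                    max_batches: int = 200):
    """Generate exactly ``n_events`` accepted events of the model's line.

    Events are produced in batches, degraded, passed through the
    total-energy selection and kept only if they land in their own line's
    window.  ``background_fraction`` mixes in that fraction of 511 keV
    annihilation photons (same emission geometry) before selection; the
    1 MeV cut is expected to reject them all, which the rejection tally
    makes testable.  Returns ``(data, origins, n_attempted)`` where
    ``origins`` are the true emission points of the kept events.
    """
    windows = windows or EnergyWindows()
    centers = np.asarray(windows.line_centers)
    own = int(np.argmin(np.abs(centers - model.line_energy)))
    chunks, origin_chunks = [], []
    n_kept = 0
    n_attempted = 0
    for _ in range(max_batches):
        if n_kept >= n_events:
            break
        m = max(2000, int(1.3 * (n_events - n_kept)))
        origins = model.sample_origin(rng, m)
        n_attempted += m
        if background_fraction > 0.0:
            is_bg = rng.random(m) < background_fraction
        else:  # keep the draw sequence of background-free runs unchanged
            is_bg = np.zeros(m, dtype=bool)
        line = np.where(is_bg, 0.511, model.line_energy)
        # per-line construction (the batch builder takes one line energy)
        parts = []
        for energy in np.unique(line):
            sel = line == energy
            d, valid, _ = events_from_origins(
                origins[sel], energy, geometry, energy_model, rng,
                triple_fraction=triple_fraction, blur=blur, quantize=quantize,
                klein_nishina=klein_nishina,
            )
            parts.append((d, origins[sel][valid]))
        data = ListModeData(
            n_interactions=np.concatenate([p[0].n_interactions for p in parts]),
            positions=np.concatenate([p[0].positions for p in parts]),
            energies=np.concatenate([p[0].energies for p in parts]),
            stage_ids=np.concatenate([p[0].stage_ids for p in parts]),
            species=np.concatenate([p[0].species for p in parts]),
            event_ids=np.arange(sum(len(p[0]) for p in parts), dtype=np.int64),
        )
        batch_origins = np.concatenate([p[1] for p in parts])
        keep, labels = windows.classify(_total_energies(data))
        keep &= labels == own
        data = data.subset(keep)
        data.species[:] = windows.line_labels[own]
        chunks.append(data)
        origin_chunks.append(batch_origins[keep])
        n_kept += len(data)
    if n_kept < n_events:
        raise RuntimeError(
            f"only {n_kept}/{n_events} events accepted after {max_batches} batches"
        )
    data = ListModeData(
        n_interactions=np.concatenate([c.n_interactions for c in chunks])[:n_events],
        positions=np.concatenate([c.positions for c in chunks])[:n_events],
        energies=np.concatenate([c.energies for c in chunks])[:n_events],
        stage_ids=np.concatenate([c.stage_ids for c in chunks])[:n_events],
        species=np.concatenate([c.species for c in chunks])[:n_events],
        event_ids=np.arange(n_events, dtype=np.int64),
    )
    origins = np.concatenate(origin_chunks)[:n_events]
    return data, origins, n_attempted


def simulate_dataset(species: str, n_events: int | None = None, seed: int = 0,
                     geometry: CameraGeometry | None = None,
                     energy_model: EnergyResolutionModel | None = None,
                     voi: VOIGrid | None = None,
                     windows: EnergyWindows | None = None,
                     smoothing_fwhm: float = 2.0,
                     **kwargs):
    """In-memory dataset for one PG line under the default study
    conditions; returns ``(data, ground_truth, manifest)``."""
    model = EmissionModel.preset(species)
    n_events = n_events if n_events is not None else DEFAULT_EVENT_COUNTS[species]
    geometry = geometry or CameraGeometry.small_phantom()
    energy_model = energy_model or EnergyResolutionModel()
    voi = voi or VOIGrid.default()
    rng = np.random.default_rng(seed)
    data, origins, n_attempted = generate_events(
        model, n_events, geometry, energy_model, rng, windows=windows, **kwargs
    )
    # a single-bin axis of the VOI is a projection plane: collapse that
    # coordinate so the truth histogram is the projected origin density
    origins_binned = origins.copy()
    for ax in range(3):
        if voi.dims[ax] == 1:
            origins_binned[:, ax] = voi.lo[ax] + 0.5 * voi.bin[ax]
    truth = GroundTruth(
        voi=voi,
        histogram=voi.histogram(origins_binned),
        metrics=analytic_profile_metrics(model, smoothing_fwhm=smoothing_fwhm),
        model=model,
    )
    manifest = {
        "species": species,
        "seed": seed,
        "n_events": n_events,
        "n_attempted": n_attempted,
        "n_doubles": int(np.sum(data.n_interactions == 2)),
        "n_triples": int(np.sum(data.n_interactions == 3)),
        "emission_model": asdict(model),
        "energy_model": asdict(energy_model),
        "analytic_metrics": asdict(truth.metrics),
    }
    return data, truth, manifest


def generate_dataset(species: str, out_dir, n_events: int | None = None,
                     seed: int = 0, **kwargs):
    """Write a dataset to disk: PGLM CSV, ground-truth image (+ sidecar)
    and a JSON manifest.  Deterministic given the seed."""
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data, truth, manifest = simulate_dataset(species, n_events=n_events, seed=seed,
                                             **kwargs)
    write_pglm(out_dir / "events.pglm.csv", data)
    write_image(out_dir / "ground_truth.img", truth.histogram, truth.voi)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return data, truth, manifest
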