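"""Origin-ensembles reconstruction engine.

The engine keeps one candidate origin per detected event, constrained to
that event's Compton cone, and improves the ensemble by Metropolis moves:
a proposed new origin in voxel ``j`` (uniformly sampled on the — possibly
resolution-corrected — cone surface inside the VOI) replaces the current
origin in voxel ``i`` with probability ``min(1, (c_j + 1) eps_i /
(c_i eps_j))`` where ``c`` are per-voxel origin counts and ``eps`` voxel
sensitivities (uniform here).  One *sweep* visits every event once in
stored order (the ordered modification; a stochastic event order is kept
behind ``event_order="random"`` for comparison).  After burn-in the
per-sweep count fields are averaged into the output image.

Variants:

``soe``
    fixed measured cones, no corrections (the no-resolution-recovery
    baseline);
``oerr``
    per-step position resampling over the pixel footprint;
``oerr_e``
    position plus energy resampling;
``oerr_e_pre``
    as ``oerr_e`` with the pre-calculated initialization: k >= 1
    corrected cone samples per event build a provisional density map and
    each event starts from one of its own candidates drawn with
    probability proportional to that density.

Heavy runs go through numba kernels (:mod:`pgoe._kernels`); a pure-python
backend with identical chain logic is available for small problems and
for instrumented tests (``backend="python"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from . import _kernels
from .camera import CameraGeometry, EnergyResolutionModel
from .kinematics import ConeParameters
from .resolution import CorrectionPolicy, resample_cone

__all__ = [
    "VOIGrid",
    "EnsembleState",
    "ReconConfig",
    "ReconResult",
    "accept_ratio",
    "sample_point_on_cone_in_voi",
    "initialize_ensemble",
    "oe_sweep",
    "reconstruct",
]


@dataclass(frozen=True)
class VOIGrid:
    """Voxel grid: half-open bins ``[lo, lo + bin)``, 0-based indices."""

    lo: tuple[float, float, float]
    bin: tuple[float, float, float]
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.bin):
            raise ValueError("bin sizes must be positive")
        if any(d <= 0 for d in self.dims):
            raise ValueError("dims must be positive")
        object.__setattr__(self, "lo", tuple(float(v) for v in self.lo))
        object.__setattr__(self, "bin", tuple(float(v) for v in self.bin))
        object.__setattr__(self, "dims", tuple(int(v) for v in self.dims))

    @classmethod
    def default(cls) -> "VOIGrid":
        """Default planar VOI at 1 mm: a single-bin-thick slab in the
        beam plane (x in [-0.5, 0.5)), clipped to the small phantom
        (y in [-50, 50), depth z in [0, 200)).  Reconstruction on this
        grid is a 2-D projection image; the thin slab keeps the voxel
        occupancy (events per voxel) high enough for the origin-ensemble
        clustering to equilibrate quickly, and restricting candidate
        origins to the phantom volume keeps cone-tangency rims outside
        the physical source region from attracting ensemble mass."""
        return cls(lo=(-0.5, -50.0, 0.0), bin=(1.0, 1.0, 1.0), dims=(1, 100, 200))

    @classmethod
    def volumetric(cls) -> "VOIGrid":
        """3-D alternative: 1 mm grid over x, y in [-15.5, 15.5) (31
        bins, beam axis on a bin centre) and z in [0, 160).  Slower to
        equilibrate (sparse occupancy) but gives a true 3-D image."""
        return cls(lo=(-15.5, -15.5, 0.0), bin=(1.0, 1.0, 1.0), dims=(31, 31, 160))

    @property
    def hi(self) -> tuple[float, float, float]:
        return tuple(l + b * d for l, b, d in zip(self.lo, self.bin, self.dims))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def centers(self, axis: int) -> np.ndarray:
        return self.lo[axis] + (np.arange(self.dims[axis]) + 0.5) * self.bin[axis]

    def edges(self, axis: int) -> np.ndarray:
        return self.lo[axis] + np.arange(self.dims[axis] + 1) * self.bin[axis]

    def contains(self, point) -> bool:
        p = np.asarray(point, dtype=float)
        return bool(np.all(p >= self.lo) and np.all(p < self.hi))

    def voxel_index(self, point) -> int:
        """Flat voxel index of a point, or -1 outside the VOI."""
        p = np.asarray(point, dtype=float)
        if not self.contains(p):
            return -1
        idx = ((p - np.asarray(self.lo)) / np.asarray(self.bin)).astype(int)
        idx = np.minimum(idx, np.asarray(self.dims) - 1)
        return int((idx[0] * self.dims[1] + idx[1]) * self.dims[2] + idx[2])

    def histogram(self, points: np.ndarray) -> np.ndarray:
        """3-D histogram of points on this grid (points outside dropped)."""
        points = np.asarray(points, dtype=float)
        h, _ = np.histogramdd(points, bins=[self.edges(a) for a in range(3)])
        return h


@dataclass
class EnsembleState:
    """Mutable chain state: one origin per event plus voxel counts."""

    origins: np.ndarray          # (n, 3) current origin points
    vox: np.ndarray              # (n,) flat voxel index, -1 = dropped
    counts: np.ndarray           # (n_voxels,) origin counts c_v
    sensitivities: np.ndarray    # (n_voxels,) eps_v
    accum: np.ndarray            # (n_voxels,) post-burn-in accumulator
    n_accum: int = 0
    sweep: int = 0
    dropped: int = 0

    @property
    def n_active(self) -> int:
        return int(np.sum(self.vox >= 0))


@dataclass(frozen=True)
class ReconConfig:
    """Reconstruction settings (defaults follow the study conditions:
    100 ordered sweeps, burn-in at half, k = 8 pre-calculated samples for
    ``oerr_e_pre``, uniform voxel sensitivity, surface-area-uniform cone
    sampling)."""

    variant: str = "oerr_e_pre"
    k: int | None = None
    n_sweeps: int = 100
    burn_in: int | None = None
    seed: int = 0
    voi: VOIGrid = field(default_factory=VOIGrid.default)
    energy_model: EnergyResolutionModel = field(default_factory=EnergyResolutionModel)
    surface_measure: str = "area"      # or "chord"
    event_order: str = "ordered"       # or "random"
    backend: str = "numba"             # or "python"
    max_azimuth_trials: int = 256
    init_retries: int = 4
    init_strategy: str = "density"     # or "uniform"
    check_conservation: bool = False

    def __post_init__(self) -> None:
        if self.resolved_k < 1:
            raise ValueError("k must be >= 1")
        if not 0 <= self.resolved_burn_in < self.n_sweeps:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_sweeps")
        if self.surface_measure not in ("chord", "area"):
            raise ValueError("surface_measure must be 'chord' or 'area'")
        if self.event_order not in ("ordered", "random"):
            raise ValueError("event_order must be 'ordered' or 'random'")

    @property
    def resolved_k(self) -> int:
        if self.k is not None:
            return self.k
        return 8 if self.variant == "oerr_e_pre" else 1

    @property
    def resolved_burn_in(self) -> int:
        return self.n_sweeps // 2 if self.burn_in is None else self.burn_in

    @property
    def policy(self) -> CorrectionPolicy:
        return CorrectionPolicy.for_variant(self.variant, self.energy_model)


@dataclass
class ReconResult:
    image: np.ndarray
    voi: VOIGrid
    diagnostics: dict
    state: EnsembleState


def accept_ratio(c_i: int, c_j: int, eps_i: float = 1.0, eps_j: float = 1.0) -> float:
    """Metropolis ratio ``(c_j + 1) eps_i / (c_i eps_j)``; a move into a
    zero-sensitivity voxel is rejected outright (ratio 0)."""
    if c_i < 1:
        raise ValueError("the moving event must be counted in its own voxel (c_i >= 1)")
    if eps_j == 0.0:
        return 0.0
    return (c_j + 1.0) * eps_i / (c_i * eps_j)


def sample_point_on_cone_in_voi(cone: ConeParameters, voi: VOIGrid,
                                rng: np.random.Generator,
                                max_trials: int = 256,
                                surface_measure: str = "area"):
    """Random point on the cone surface inside the VOI, or ``None`` if
    no draw lands in the VOI within ``max_trials`` azimuth trials.

    ``surface_measure="area"`` (the default policy) samples uniformly
    with respect to the cone's surface-area element (density ~ t dt dphi
    on the in-VOI patch, via rejection across azimuths).
    ``surface_measure="chord"`` is the legacy measure: azimuth uniform
    over the VOI-visible arc, then uniform along the in-VOI chord; it
    overweights short corner-grazing chords and is kept for sensitivity
    analysis only.
    """
    d = cone.axis
    cosb = float(np.cos(cone.half_angle))
    sinb = float(np.sin(cone.half_angle))
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = a - np.dot(a, d) * d
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    lo = np.asarray(voi.lo)
    hi = np.asarray(voi.hi)
    corners = np.array([[lo[i] if c & (1 << i) else hi[i] for i in range(3)]
                        for c in range(8)])
    d2max = float(np.max(np.sum((corners - cone.apex) ** 2, axis=1)))
    for _ in range(max_trials):
        phi = 2.0 * np.pi * rng.random()
        g = cosb * d + sinb * (np.cos(phi) * u + np.sin(phi) * v)
        tlo, thi = 1e-12, np.inf
        ok = True
        for k in range(3):
            if abs(g[k]) < 1e-14:
                if not (lo[k] <= cone.apex[k] < hi[k]):
                    ok = False
                    break
            else:
                t1 = (lo[k] - cone.apex[k]) / g[k]
                t2 = (hi[k] - cone.apex[k]) / g[k]
                if t1 > t2:
                    t1, t2 = t2, t1
                tlo = max(tlo, t1)
                thi = min(thi, t2)
                if tlo >= thi:
                    ok = False
                    break
        if not ok:
            continue
        if surface_measure == "area":
            w = thi**2 - tlo**2
            if rng.random() * d2max > w:
                continue
            t = np.sqrt(tlo**2 + rng.random() * w)
        else:
            t = tlo + rng.random() * (thi - tlo)
        pt = cone.apex + t * g
        if voi.contains(pt):
            return pt
    return None


# ---------------------------------------------------------------------------
# array packing shared by both backends


def _to_arrays(data):
    """(n_int, positions, energies, stage_ids) from a ListModeData-like
    object or a list of ListModeEvent."""
    if hasattr(data, "positions"):
        return (
            np.ascontiguousarray(data.n_interactions, dtype=np.int64),
            np.ascontiguousarray(np.nan_to_num(data.positions), dtype=np.float64),
            np.ascontiguousarray(np.nan_to_num(data.energies), dtype=np.float64),
            # kernels index 0-based per-stage parameter arrays
            np.ascontiguousarray(data.stage_ids, dtype=np.int64) - 1,
        )
    events = list(data)
    n = len(events)
    nint = np.zeros(n, dtype=np.int64)
    pos = np.zeros((n, 3, 3))
    ene = np.zeros((n, 3))
    stg = np.zeros((n, 3), dtype=np.int64)
    for i, ev in enumerate(events):
        nint[i] = ev.n_interactions
        for k, it in enumerate(ev.interactions):
            pos[i, k] = it.position
            ene[i, k] = it.energy
            stg[i, k] = it.stage_id - 1
    return nint, pos, ene, stg


def _stage_arrays(geometry: CameraGeometry):
    """Per-stage resolution parameters indexed by 0-based stage."""
    ns = len(geometry.stages)
    depth_err = np.zeros(ns)
    pitch_u = np.zeros(ns)
    pitch_v = np.zeros(ns)
    x_lo = np.zeros(ns)
    x_hi = np.zeros(ns)
    for i, s in enumerate(geometry.stages):
        depth_err[i] = s.depth_error
        pitch_u[i] = s.pixel_pitch_u
        pitch_v[i] = s.pixel_pitch_v
        x_lo[i], x_hi[i] = s.x_range
    return depth_err, pitch_u, pitch_v, x_lo, x_hi


def _energy_model_params(model: EnergyResolutionModel):
    return (0 if model.kind == "ab_fwhm" else 1), model.a, model.b, model.eta


def _derive_seeds(seed: int, n: int = 3) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in (ss.generate_state(n) % np.uint32(2**31 - 1))]


# ---------------------------------------------------------------------------
# pure-python backend (reference implementation, instrumented tests)


def initialize_ensemble(events, config: ReconConfig, geometry: CameraGeometry,
                        rng: np.random.Generator) -> EnsembleState:
    """Pre-calculated (or plain, k = 1) random initialization.

    For each event, k candidate origins are drawn on its cone
    (resolution-corrected cones for ``oerr_e_pre``, measured cones
    otherwise); a provisional density map over all k*N candidates then
    selects each event's starting origin among its own candidates with
    probability proportional to the density at the candidate's voxel
    (uniform among candidates when all their densities are zero).
    Events with no valid in-VOI candidate are dropped and counted.
    """
    events = list(events)
    policy = config.policy
    if not policy.precalc_init:
        policy = replace(policy, correct_position=False, correct_energy=False)
    voi = config.voi
    k = config.resolved_k
    n = len(events)
    cand_vox = np.full((n, k), -1, dtype=np.int64)
    cand_pos = np.zeros((n, k, 3))
    for i, ev in enumerate(events):
        for c in range(k):
            for _ in range(config.init_retries):
                cone = resample_cone(ev, policy, geometry, rng)
                if cone is None:
                    continue
                pt = sample_point_on_cone_in_voi(
                    cone, voi, rng, config.max_azimuth_trials, config.surface_measure
                )
                if pt is not None:
                    cand_vox[i, c] = voi.voxel_index(pt)
                    cand_pos[i, c] = pt
                    break
    return _select_initial(cand_vox, cand_pos, voi, config, rng)


def _select_initial(cand_vox, cand_pos, voi: VOIGrid, config: ReconConfig,
                    rng: np.random.Generator) -> EnsembleState:
    n, k = cand_vox.shape
    nv = voi.n_voxels
    valid = cand_vox >= 0
    density = np.bincount(cand_vox[valid].ravel(), minlength=nv).astype(float)
    if config.init_strategy == "density":
        w = np.where(valid, density[np.clip(cand_vox, 0, None)], 0.0)
    else:
        w = valid.astype(float)
    rowsum = w.sum(axis=1)
    flat_rows = (rowsum == 0) & valid.any(axis=1)
    w[flat_rows] = valid[flat_rows].astype(float)
    rowsum = w.sum(axis=1)
    vox = np.full(n, -1, dtype=np.int64)
    origins = np.zeros((n, 3))
    ok = rowsum > 0
    if np.any(ok):
        u = rng.random(n) * rowsum
        sel = (np.cumsum(w, axis=1) > u[:, None]).argmax(axis=1)
        vox[ok] = cand_vox[np.arange(n), sel][ok]
        origins[ok] = cand_pos[np.arange(n), sel][ok]
    counts = np.bincount(vox[vox >= 0], minlength=nv).astype(np.int64)
    return EnsembleState(
        origins=origins,
        vox=vox,
        counts=counts,
        sensitivities=np.ones(nv),
        accum=np.zeros(nv),
        dropped=int(np.sum(~ok)),
    )


def oe_sweep(state: EnsembleState, events, config: ReconConfig,
             geometry: CameraGeometry, rng: np.random.Generator,
             propose: Callable | None = None,
             accept_override: bool | None = None,
             trace: list | None = None) -> float:
    """One ordered (or stochastic) sweep of the python backend, in place.

    Visits every event once (steps 2-5 of the chain: record voxel i,
    resample the cone per the variant policy, draw a point j on it inside
    the VOI, Metropolis-accept).  ``propose`` replaces the cone-sampling
    proposal (test hook, called as ``propose(event_index, rng) ->
    point``); ``accept_override`` forces the acceptance decision;
    ``trace`` collects the visit order.  Returns the acceptance rate.
    Accumulates counts when the sweep index is past burn-in.
    """
    events = list(events)
    n = len(events)
    voi = config.voi
    policy = config.policy
    accepted = 0
    attempted = 0
    if config.event_order == "ordered":
        order = range(n)
    else:
        order = rng.integers(0, n, size=n)
    for e in order:
        if state.vox[e] < 0:
            continue
        if trace is not None:
            trace.append(int(e))
        attempted += 1
        if propose is not None:
            pt = propose(e, rng)
        else:
            cone = resample_cone(events[e], policy, geometry, rng)
            if cone is None:
                continue
            pt = sample_point_on_cone_in_voi(
                cone, voi, rng, config.max_azimuth_trials, config.surface_measure
            )
        if pt is None:
            continue
        j = voi.voxel_index(pt)
        if j < 0:
            continue
        i = int(state.vox[e])
        r = accept_ratio(state.counts[i], state.counts[j],
                         state.sensitivities[i], state.sensitivities[j])
        if accept_override is not None:
            acc = accept_override
        else:
            acc = r >= 1.0 or rng.random() < r
        if acc:
            state.counts[i] -= 1
            state.counts[j] += 1
            state.vox[e] = j
            state.origins[e] = pt
            accepted += 1
    if config.check_conservation:
        assert state.counts.sum() == state.n_active, "count conservation violated"
        assert np.all(state.counts >= 0)
    if state.sweep >= config.resolved_burn_in:
        state.accum += state.counts
        state.n_accum += 1
    state.sweep += 1
    return accepted / attempted if attempted else 0.0


# ---------------------------------------------------------------------------
# driver


def reconstruct(data, config: ReconConfig,
                geometry: CameraGeometry | None = None) -> ReconResult:
    """Full reconstruction: initialization + n_sweeps, averaged image.

    ``data`` is a :class:`~pgoe.io.ListModeData` or a list of
    :class:`~pgoe.camera.ListModeEvent` that already passed the energy
    selection.  The returned image is the post-burn-in mean of the voxel
    count field on the VOI grid.
    """
    geometry = geometry or CameraGeometry.small_phantom()
    nint, pos, ene, stg = _to_arrays(data)
    if nint.size == 0:
        raise ValueError("empty event list")
    if np.any(ene[:, :2] <= 0):
        raise ValueError("nonpositive deposited energies in selected events")
    voi = config.voi
    seeds = _derive_seeds(config.seed)
    policy = config.policy
    burn_in = config.resolved_burn_in

    if config.backend == "python":
        rng_init = np.random.default_rng(seeds[0])
        rng_sweep = np.random.default_rng(seeds[1])
        events = data.to_events() if hasattr(data, "to_events") else list(data)
        state = initialize_ensemble(events, config, geometry, rng_init)
        acc = [
            oe_sweep(state, events, config, geometry, rng_sweep)
            for _ in range(config.n_sweeps)
        ]
        acc = np.asarray(acc)
    elif config.backend == "numba":
        stage_params = _stage_arrays(geometry)
        emp = _energy_model_params(config.energy_model)
        init_pos = policy.correct_position and policy.precalc_init
        init_ene = policy.correct_energy and policy.precalc_init
        cand_vox, cand_pos = _kernels.sample_candidates(
            nint, pos, ene, stg, *stage_params, *emp,
            init_pos, init_ene,
            np.asarray(voi.lo), np.asarray(voi.bin),
            np.asarray(voi.dims, dtype=np.int64),
            config.resolved_k, config.init_retries, seeds[0],
            config.max_azimuth_trials, config.surface_measure == "area",
        )
        state = _select_initial(cand_vox, cand_pos, voi, config,
                                np.random.default_rng(seeds[2]))
        acc, n_acc = _kernels.run_sweeps(
            nint, pos, ene, stg, *stage_params, *emp,
            policy.correct_position, policy.correct_energy,
            np.asarray(voi.lo), np.asarray(voi.bin),
            np.asarray(voi.dims, dtype=np.int64),
            state.origins, state.vox, state.counts, state.accum,
            config.n_sweeps, burn_in, seeds[1],
            config.max_azimuth_trials, config.surface_measure == "area",
            config.event_order == "ordered",
        )
        state.sweep = config.n_sweeps
        state.n_accum = int(n_acc)
    else:
        raise ValueError(f"unknown backend {config.backend!r}")

    if state.counts.sum() != state.n_active:
        raise AssertionError("count conservation violated")
    image = (state.accum / state.n_accum).reshape(voi.dims)
    diagnostics = {
        "variant": config.variant,
        "backend": config.backend,
        "seed": config.seed,
        "n_events": int(nint.size),
        "dropped": int(state.dropped),
        "k": config.resolved_k,
        "n_sweeps": config.n_sweeps,
        "burn_in": burn_in,
        "acceptance_per_sweep": np.asarray(acc).tolist(),
        "surface_measure": config.surface_measure,
        "event_order": config.event_order,
        "image_total": float(image.sum()),
    }
    return ReconResult(image=image, voi=voi, diagnostics=diagnostics, state=state)
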