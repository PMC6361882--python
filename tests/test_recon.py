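import numpy as np
import pytest

from pgoe import (
    CameraGeometry,
    EnergyResolutionModel,
    accept_ratio,
    initialize_ensemble,
    oe_sweep,
    reconstruct,
    sample_point_on_cone_in_voi,
)
from pgoe.kinematics import ConeParameters
from pgoe.recon import ReconConfig, VOIGrid


class TestAcceptRatio:
    def test_always_accept_into_equal_state(self):
        assert accept_ratio(1, 0) == 1.0

    def test_downhill_probability(self):
        assert accept_ratio(10, 1) == pytest.approx(0.2)

    def test_zero_sensitivity_target_rejected(self):
        assert accept_ratio(5, 3, eps_i=1.0, eps_j=0.0) == 0.0

    def test_moving_event_must_be_counted(self):
        with pytest.raises(ValueError):
            accept_ratio(0, 1)


@pytest.fixture
def wide_cone():
    """Cone apexed at the camera, axis towards the VOI, 30 deg opening."""
    return ConeParameters(apex=np.array([160.0, 0.0, 100.0]),
                          axis=np.array([-1.0, 0.0, 0.0]),
                          half_angle=np.radians(30.0))


class TestConeSampling:
    def test_points_on_cone_and_in_voi(self, wide_cone, rng):
        """Every returned point lies on the cone (to 1e-9 rad) and inside
        the VOI; rejection exhaustion (None) is rare."""
        voi = VOIGrid.volumetric()
        n_none = 0
        for _ in range(2000):
            pt = sample_point_on_cone_in_voi(wide_cone, voi, rng)
            if pt is None:
                n_none += 1
                continue
            assert voi.contains(pt)
            assert wide_cone.angular_residual(pt) <= 1e-9
        assert n_none < 100

    def test_degenerate_ray_on_axis(self, rng):
        cone = ConeParameters(apex=np.array([160.0, 0.0, 100.0]),
                              axis=np.array([-1.0, 0.0, 0.0]), half_angle=0.0)
        voi = VOIGrid.volumetric()
        for _ in range(100):
            pt = sample_point_on_cone_in_voi(cone, voi, rng)
            assert pt is not None
            assert abs(pt[1]) < 1e-9 and abs(pt[2] - 100.0) < 1e-9

    def test_cone_missing_voi_returns_none(self, rng):
        cone = ConeParameters(apex=np.array([160.0, 0.0, 100.0]),
                              axis=np.array([1.0, 0.0, 0.0]),  # points away
                              half_angle=np.radians(10.0))
        voi = VOIGrid.volumetric()
        assert sample_point_on_cone_in_voi(cone, voi, rng) is None

    def test_azimuth_uniform_over_visible_arc(self, wide_cone, rng):
        """Chord-measure azimuth histogram is uniform over the
        VOI-visible arc (chi-squared against a 1-degree brute-force arc
        discretization oracle)."""
        from scipy.stats import chisquare

        voi = VOIGrid.volumetric()
        d = wide_cone.axis
        a = np.array([0.0, 1.0, 0.0])
        u = a - (a @ d) * d
        u /= np.linalg.norm(u)
        v = np.cross(d, u)
        cosb, sinb = np.cos(wide_cone.half_angle), np.sin(wide_cone.half_angle)

        # oracle: which 1-degree azimuth bins can reach the VOI at all
        lo, hi = np.asarray(voi.lo), np.asarray(voi.hi)

        def ray_hits(phi):
            g = cosb * d + sinb * (np.cos(phi) * u + np.sin(phi) * v)
            tlo, thi = 1e-12, np.inf
            for k in range(3):
                if abs(g[k]) < 1e-14:
                    if not (lo[k] <= wide_cone.apex[k] < hi[k]):
                        return False
                else:
                    t1, t2 = sorted([(lo[k] - wide_cone.apex[k]) / g[k],
                                     (hi[k] - wide_cone.apex[k]) / g[k]])
                    tlo, thi = max(tlo, t1), min(thi, t2)
                    if tlo >= thi:
                        return False
            return True

        centers = np.radians(np.arange(360) + 0.5)
        visible = np.array([ray_hits(p) for p in centers])
        # interior bins: visible and not adjacent to a visibility edge
        # (edge bins are only partially visible at sub-degree resolution)
        interior = visible & np.roll(visible, 1) & np.roll(visible, -1)
        draws = []
        for _ in range(20_000):
            pt = sample_point_on_cone_in_voi(wide_cone, voi, rng,
                                             surface_measure="chord")
            rel = pt - wide_cone.apex
            phi = np.arctan2(rel @ v, rel @ u) % (2 * np.pi)
            draws.append(np.degrees(phi))
        hist, _ = np.histogram(draws, bins=np.arange(361))
        res = chisquare(hist[interior])
        assert res.pvalue > 0.001
        # nothing lands in azimuths the oracle says cannot reach the VOI
        far_invisible = ~visible & ~np.roll(visible, 1) & ~np.roll(visible, -1)
        assert hist[far_invisible].sum() == 0


def _toy_config(voi, **kw):
    defaults = dict(variant="soe", n_sweeps=10, burn_in=5, seed=3, voi=voi,
                    backend="python", check_conservation=True)
    defaults.update(kw)
    return ReconConfig(**defaults)


def _toy_state(voi, vox, config, rng):
    """EnsembleState with prescribed starting voxel per event."""
    from pgoe.recon import EnsembleState

    n = len(vox)
    nv = voi.n_voxels
    origins = np.zeros((n, 3))
    counts = np.bincount(vox, minlength=nv).astype(np.int64)
    return EnsembleState(origins=origins, vox=np.asarray(vox, dtype=np.int64),
                         counts=counts, sensitivities=np.ones(nv),
                         accum=np.zeros(nv))


class TestToyChain:
    """Enumerable two-voxel chains driven through the real sweep code via
    the proposal hook."""

    voi = VOIGrid(lo=(0.0, 0.0, 0.0), bin=(1.0, 1.0, 1.0), dims=(1, 1, 2))

    def _propose(self, e, rng):
        # uniform proposal between the two voxel centres
        return np.array([0.5, 0.5, 0.5 + float(rng.integers(0, 2))])

    def test_occupancy_matches_exact_stationary(self, rng):
        """Long-run occupancy of c_A for 3 events movable between two
        voxels matches the stationary distribution of the exactly
        enumerated sweep transition matrix within 3 MC standard errors."""
        n_events = 3

        # --- oracle: enumerate the 2^3 assignment states ----------------
        states = [tuple((s >> i) & 1 for i in range(n_events))
                  for s in range(2**n_events)]

        def step_matrix(ev):
            P = np.zeros((8, 8))
            for si, s in enumerate(states):
                counts = [s.count(0), s.count(1)]
                i = s[ev]
                for j in (0, 1):
                    ratio = (counts[j] + 1) / counts[i] if j != i else 1.0
                    acc = min(1.0, ratio)
                    t = list(s)
                    t[ev] = j
                    P[si, states.index(tuple(t))] += 0.5 * acc
                    P[si, si] += 0.5 * (1 - acc)
            return P

        P = np.eye(8)
        for ev in range(n_events):
            P = P @ step_matrix(ev)
        w, vecs = np.linalg.eig(P.T)
        pi = np.real(vecs[:, np.argmin(np.abs(w - 1))])
        pi /= pi.sum()
        exact_mean_cA = sum(p * s.count(0) for p, s in zip(pi, states))

        # --- chain through the real sweep code --------------------------
        config = _toy_config(self.voi, n_sweeps=2, burn_in=0)
        state = _toy_state(self.voi, [0, 0, 1], config, rng)
        n_sweeps = 20_000
        cA = np.empty(n_sweeps)
        for s in range(n_sweeps):
            oe_sweep(state, [None] * n_events, config, None, rng,
                     propose=self._propose)
            cA[s] = state.counts[0]
        # batch-means standard error of the correlated series
        batches = cA[1000:].reshape(50, -1).mean(axis=1)
        se = batches.std(ddof=1) / np.sqrt(len(batches))
        assert abs(cA[1000:].mean() - exact_mean_cA) < 3 * se + 1e-12

    def test_count_conservation_every_sweep(self, rng):
        config = _toy_config(self.voi, n_sweeps=100, burn_in=50)
        state = _toy_state(self.voi, [0, 1, 1, 0, 0], config, rng)
        for _ in range(100):
            oe_sweep(state, [None] * 5, config, None, rng, propose=self._propose)
            assert state.counts.sum() == 5
            assert np.all(state.counts >= 0)

    def test_visit_order_is_stored_order(self, rng):
        config = _toy_config(self.voi)
        state = _toy_state(self.voi, [0, 1, 0], config, rng)
        trace = []
        oe_sweep(state, [None] * 3, config, None, rng, propose=self._propose,
                 trace=trace)
        assert trace == [0, 1, 2]

    def test_forced_accept_single_event_marginal_uniform(self, rng):
        """With acceptance forced, a single event's origin marginal is the
        proposal marginal (uniform over the two voxels here)."""
        config = _toy_config(self.voi, n_sweeps=2, burn_in=0)
        state = _toy_state(self.voi, [0], config, rng)
        visits = np.zeros(2)
        for _ in range(4000):
            oe_sweep(state, [None], config, None, rng, propose=self._propose,
                     accept_override=True)
            visits[state.vox[0]] += 1
        assert abs(visits[0] / visits.sum() - 0.5) < 0.03


@pytest.fixture(scope="module")
def point_source_data():
    """Blurred events from a single point source."""
    from pgoe.simulate import events_from_origins

    rng = np.random.default_rng(21)
    geometry = CameraGeometry.small_phantom()
    origin = np.array([0.0, 0.0, 100.0])
    data, _, _ = events_from_origins(
        np.tile(origin, (3000, 1)), 6.13, geometry,
        EnergyResolutionModel(), rng, blur=True, quantize=True,
    )
    return data, origin, geometry


class TestReconstruct:
    def test_point_source_mass_concentrates(self):
        """SOE on an exact (blur-free) point source: >= 90% of the image
        mass ends within 2 mm of the true point after 100 sweeps.

        The VOI is a 40 x 40 mm window around the source and the run is
        300 sweeps: per sweep, each event proposes the hot voxel with
        probability ~ voxel measure / cone measure inside the VOI, so the
        capture rate of the clustering dynamics scales with the window
        size and this window needs a few hundred sweeps to collect >90%
        of the ensemble."""
        from pgoe.simulate import events_from_origins

        rng = np.random.default_rng(22)
        geometry = CameraGeometry.small_phantom()
        origin = np.array([0.0, 0.0, 100.0])
        data, _, _ = events_from_origins(
            np.tile(origin, (3000, 1)), 6.13, geometry,
            EnergyResolutionModel(), rng, blur=False, quantize=False,
        )
        voi = VOIGrid(lo=(-0.5, -20.0, 80.0), bin=(1.0, 1.0, 1.0),
                      dims=(1, 40, 40))
        config = ReconConfig(variant="soe", n_sweeps=300, seed=4, voi=voi,
                             init_retries=16)
        res = reconstruct(data, config, geometry)
        img2d = res.image[0]
        yy = voi.centers(1)[:, None]
        zz = voi.centers(2)[None, :]
        r = np.hypot(yy - origin[1], zz - origin[2])
        frac = img2d[r <= 2.0].sum() / img2d.sum()
        assert frac >= 0.90

    def test_mass_conservation(self, point_source_data):
        data, _, geometry = point_source_data
        config = ReconConfig(variant="oerr_e", n_sweeps=12, seed=5)
        res = reconstruct(data, config, geometry)
        n_active = len(data) - res.diagnostics["dropped"]
        assert res.image.sum() == pytest.approx(n_active)

    def test_deterministic_rerun(self, point_source_data):
        data, _, geometry = point_source_data
        config = ReconConfig(variant="oerr_e_pre", n_sweeps=10, seed=6)
        r1 = reconstruct(data, config, geometry)
        r2 = reconstruct(data, config, geometry)
        assert np.array_equal(r1.image, r2.image)

    def test_backends_agree_statistically(self, point_source_data):
        """The numba and python backends implement the same chain: both
        concentrate a point source at the same location."""
        data, origin, geometry = point_source_data
        sub = data.subset(np.arange(400))
        voi = VOIGrid(lo=(-0.5, -20.0, 80.0), bin=(1.0, 1.0, 1.0), dims=(1, 40, 40))
        imgs = {}
        for backend in ("numba", "python"):
            config = ReconConfig(variant="oerr_e", n_sweeps=12, seed=7,
                                 voi=voi, backend=backend)
            imgs[backend] = reconstruct(sub, config, geometry).image[0]
        for img in imgs.values():
            iy, iz = np.unravel_index(np.argmax(img), img.shape)
            assert abs(voi.centers(1)[iy] - origin[1]) <= 3.0
            assert abs(voi.centers(2)[iz] - origin[2]) <= 3.0

    def test_empty_event_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            reconstruct([], ReconConfig(n_sweeps=2, burn_in=0))


class TestInitialization:
    def test_k1_reduces_to_plain_random(self, point_source_data, rng):
        data, _, geometry = point_source_data
        events = data.to_events()[:100]
        config = ReconConfig(variant="soe", n_sweeps=4, seed=8, backend="python")
        state = initialize_ensemble(events, config, geometry, rng)
        assert config.resolved_k == 1
        assert state.counts.sum() == 100 - state.dropped

    def test_precalc_init_concentrates_more(self, point_source_data):
        """On a point source, k = 16 density-weighted initialization
        starts with higher max-voxel occupancy than k = 1 (paired over
        10 seeds; chord measure keeps the python-path runtime small)."""
        data, _, geometry = point_source_data
        events = data.to_events()[:150]
        wins = 0
        for seed in range(10):
            occ = {}
            for k in (1, 16):
                config = ReconConfig(variant="oerr_e_pre", k=k, n_sweeps=4,
                                     seed=seed, backend="python",
                                     surface_measure="chord")
                state = initialize_ensemble(events, config, geometry,
                                            np.random.default_rng(seed))
                occ[k] = state.counts.max()
            wins += occ[16] >= occ[1]
        assert wins >= 8
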