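"""Compton kinematics, triple-event energy recovery and origin cones.

For a photon of energy ``E_in`` depositing ``E_dep`` in its first
interaction, the scattering angle ``beta`` obeys

    cos(beta) = 1 - m_e c^2 * (1 / (E_in - E_dep) - 1 / E_in)

so each double event defines a half-cone of possible origins with apex at
the first interaction, axis along (L1 - L2) and half-angle ``beta``.

Triple events are not fully absorbed; their incident energy is recovered
from the geometric scattering angle at the second vertex: with deposit
``E2`` and scatter angle ``theta_2`` the energy of the once-scattered
photon is

    E' = E2/2 + sqrt(E2^2/4 + E2 * m_e c^2 / (1 - cos(theta_2)))

and ``E_total = E1 + E'`` (the third deposit never enters).

Invalid kinematics (deposit at or beyond the Compton edge, coincident
vertices) are signalled with NaN / ``None`` rather than exceptions:
events are filtered, not aborted on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .camera import ListModeEvent

MEC2 = 0.511  # electron rest energy, MeV

__all__ = [
    "MEC2",
    "ConeParameters",
    "EnergyWindows",
    "compton_cos_angle",
    "geometric_scatter_cos",
    "recover_total_energy_triple",
    "build_cone",
    "event_total_energy",
    "select_events",
]


@dataclass(frozen=True)
class ConeParameters:
    """Origin half-cone of one event.

    ``axis`` is the unit vector from the second interaction through and
    beyond the apex (towards candidate incoming directions);
    ``half_angle`` is in radians.
    """

    apex: np.ndarray
    axis: np.ndarray
    half_angle: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "apex", np.asarray(self.apex, dtype=float))
        object.__setattr__(self, "axis", np.asarray(self.axis, dtype=float))

    def angular_residual(self, point) -> float:
        """|angle(apex->point, axis) - half_angle| in radians."""
        d = np.asarray(point, dtype=float) - self.apex
        n = np.linalg.norm(d)
        if n == 0:
            return float(self.half_angle)
        c = np.clip(np.dot(d / n, self.axis), -1.0, 1.0)
        return float(abs(np.arccos(c) - self.half_angle))


@dataclass(frozen=True)
class EnergyWindows:
    """Total-energy acceptance: a low cut plus per-line windows.

    Defaults: cut at 1 MeV (rejects 511 keV annihilation gammas) and
    ±0.2 MeV windows around the four prompt-gamma lines 2.31 (14N),
    4.44 (12C), 5.25 (15O) and 6.13 MeV (16O).
    """

    min_total: float = 1.0
    line_centers: tuple[float, ...] = (2.31, 4.44, 5.25, 6.13)
    half_width: float = 0.2
    line_labels: tuple[str, ...] = ("14N", "12C", "15O", "16O")

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")
        if len(self.line_labels) != len(self.line_centers):
            raise ValueError("one label per line center")

    def classify(self, e_total):
        """Vectorized: (kept boolean mask, index of nearest line or -1)."""
        e = np.atleast_1d(np.asarray(e_total, dtype=float))
        centers = np.asarray(self.line_centers)
        idx = np.argmin(np.abs(e[:, None] - centers[None, :]), axis=1)
        in_window = np.abs(e - centers[idx]) <= self.half_width
        keep = (e > self.min_total) & in_window
        return keep, np.where(keep, idx, -1)


def compton_cos_angle(e_in, e_dep):
    """cos(beta) from the Compton relation; NaN where E_dep >= E_in.

    A return value below -1 means the deposit exceeds the Compton edge
    for ``e_in`` (callers flag the event invalid).
    """
    e_in = np.asarray(e_in, dtype=float)
    e_dep = np.asarray(e_dep, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            (e_dep > 0) & (e_dep < e_in),
            1.0 - MEC2 * (1.0 / (e_in - e_dep) - 1.0 / e_in),
            np.nan,
        )
    if out.ndim == 0:
        return float(out)
    return out


def geometric_scatter_cos(l1, l2, l3):
    """Cosine of the angle at the second vertex between (L2-L1) and
    (L3-L2); NaN for coincident points."""
    l1 = np.asarray(l1, dtype=float)
    l2 = np.asarray(l2, dtype=float)
    l3 = np.asarray(l3, dtype=float)
    a = l2 - l1
    b = l3 - l2
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(
            (na > 0) & (nb > 0),
            np.sum(a * b, axis=-1) / (na * nb),
            np.nan,
        )
    c = np.clip(c, -1.0, 1.0)
    if c.ndim == 0:
        return float(c)
    return c


def recover_total_energy_triple(e1, e2, cos_theta2):
    """Incident energy of a triple event from the first two deposits and
    the geometric second-scatter angle; NaN where cos_theta2 >= 1."""
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    c = np.asarray(cos_theta2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        e_prime = np.where(
            (c < 1.0) & (e2 > 0),
            e2 / 2.0 + np.sqrt(e2**2 / 4.0 + e2 * MEC2 / (1.0 - c)),
            np.nan,
        )
    out = e1 + e_prime
    if out.ndim == 0:
        return float(out)
    return out


def event_total_energy(event: ListModeEvent) -> float:
    """Total energy of an event: deposit sum for doubles (full absorption
    assumed), geometric recovery for triples (E3 never enters)."""
    ints = event.interactions
    if len(ints) == 2:
        return ints[0].energy + ints[1].energy
    c = geometric_scatter_cos(ints[0].position, ints[1].position, ints[2].position)
    return recover_total_energy_triple(ints[0].energy, ints[1].energy, c)


def build_cone(event: ListModeEvent, e_total: float) -> ConeParameters | None:
    """Origin cone of one event; ``None`` when the kinematics are invalid
    (cos(beta) outside [-1, 1], or degenerate geometry)."""
    ints = event.interactions
    l1 = ints[0].position
    l2 = ints[1].position
    axis = l1 - l2
    norm = np.linalg.norm(axis)
    if norm == 0 or not np.isfinite(e_total):
        return None
    cosb = compton_cos_angle(e_total, ints[0].energy)
    if not np.isfinite(cosb) or cosb < -1.0 - 1e-9 or cosb > 1.0 + 1e-9:
        return None
    cosb = float(np.clip(cosb, -1.0, 1.0))  # backscatter edge, fp rounding
    return ConeParameters(apex=l1, axis=axis / norm, half_angle=float(np.arccos(cosb)))


def select_events(events, windows: EnergyWindows | None = None):
    """Apply the total-energy cut and line windows.

    Returns ``(kept_events, tally)`` where each kept event carries the
    label of its nearest line and ``tally`` counts kept events per label
    plus the rejects under ``"rejected"``.
    """
    from dataclasses import replace

    windows = windows or EnergyWindows()
    events = list(events)
    if not events:
        return [], {"rejected": 0}
    e_tot = np.array([event_total_energy(ev) for ev in events])
    keep, idx = windows.classify(np.nan_to_num(e_tot, nan=-1.0))
    kept = []
    tally: dict[str, int] = {lab: 0 for lab in windows.line_labels}
    tally["rejected"] = 0
    for ev, k, i in zip(events, keep, idx):
        if k:
            lab = windows.line_labels[i]
            kept.append(replace(ev, species_label=lab))
            tally[lab] += 1
        else:
            tally["rejected"] += 1
    return kept, tally
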