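"""List-mode and image file formats.

PGLM ("prompt-gamma list mode") is a wide CSV: one row per event with
``event_id, n_interactions, species`` followed by
``i{k}_stage, i{k}_x, i{k}_y, i{k}_z, i{k}_E`` blocks for k = 1..3
(the third block is empty for double events).  Coordinates are lab-frame
mm, energies MeV.  Images are stored as a raw little-endian float32
raster in C order plus a JSON sidecar carrying the voxel grid (origin,
bin sizes, dims, half-open bin convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .camera import Interaction, ListModeEvent
from .recon import VOIGrid

__all__ = ["ListModeData", "read_pglm", "write_pglm", "read_image", "write_image"]

_COLUMNS = ["event_id", "n_interactions", "species"] + [
    f"i{k}_{f}" for k in (1, 2, 3) for f in ("stage", "x", "y", "z", "E")
]


@dataclass
class ListModeData:
    """Array-backed list-mode container (the working representation).

    ``positions`` is (n, 3, 3) with NaN rows for the absent third
    interaction of doubles; ``stage_ids`` uses 0 for absent.
    """

    n_interactions: np.ndarray
    positions: np.ndarray
    energies: np.ndarray
    stage_ids: np.ndarray
    species: np.ndarray
    event_ids: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.n_interactions)
        assert self.positions.shape == (n, 3, 3)
        assert self.energies.shape == (n, 3)
        assert self.stage_ids.shape == (n, 3)

    def __len__(self) -> int:
        return len(self.n_interactions)

    def subset(self, index) -> "ListModeData":
        return ListModeData(
            n_interactions=self.n_interactions[index],
            positions=self.positions[index],
            energies=self.energies[index],
            stage_ids=self.stage_ids[index],
            species=self.species[index],
            event_ids=self.event_ids[index],
        )

    def to_events(self) -> list[ListModeEvent]:
        events = []
        for i in range(len(self)):
            ni = int(self.n_interactions[i])
            ints = tuple(
                Interaction(
                    stage_id=int(self.stage_ids[i, k]),
                    position=self.positions[i, k].copy(),
                    energy=float(self.energies[i, k]),
                )
                for k in range(ni)
            )
            sp = self.species[i]
            events.append(
                ListModeEvent(
                    event_id=int(self.event_ids[i]),
                    interactions=ints,
                    species_label=None if sp in ("", None) else str(sp),
                )
            )
        return events

    @classmethod
    def from_events(cls, events) -> "ListModeData":
        events = list(events)
        n = len(events)
        nint = np.zeros(n, dtype=np.int8)
        pos = np.full((n, 3, 3), np.nan)
        ene = np.full((n, 3), np.nan)
        stg = np.zeros((n, 3), dtype=np.int8)
        spc = np.array([ev.species_label or "" for ev in events], dtype=object)
        eid = np.array([ev.event_id for ev in events], dtype=np.int64)
        for i, ev in enumerate(events):
            nint[i] = ev.n_interactions
            for k, it in enumerate(ev.interactions):
                pos[i, k] = it.position
                ene[i, k] = it.energy
                stg[i, k] = it.stage_id
        return cls(nint, pos, ene, stg, spc, eid)


class PGLMFormatError(ValueError):
    """Malformed PGLM content (message carries 1-based file line numbers)."""


def write_pglm(path, data: ListModeData) -> None:
    """Write list-mode events as PGLM CSV (floats at 1e-9 round-trip
    precision or better)."""
    rows = {}
    rows["event_id"] = data.event_ids
    rows["n_interactions"] = data.n_interactions.astype(int)
    rows["species"] = [s if s else "" for s in data.species]
    for k in range(3):
        present = data.n_interactions > k
        rows[f"i{k+1}_stage"] = np.where(present, data.stage_ids[:, k], np.nan)
        for j, f in enumerate(("x", "y", "z")):
            rows[f"i{k+1}_{f}"] = np.where(present, data.positions[:, k, j], np.nan)
        rows[f"i{k+1}_E"] = np.where(present, data.energies[:, k], np.nan)
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


def read_pglm(path) -> ListModeData:
    """Read PGLM CSV; malformed rows are reported with file line numbers."""
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise PGLMFormatError(f"missing columns: {missing}")
    n = len(df)
    nint = df["n_interactions"].to_numpy()
    errors = []
    for r in range(n):
        line = r + 2  # header is line 1
        ni = nint[r]
        if ni not in (2, 3):
            errors.append(f"line {line}: n_interactions must be 2 or 3, got {ni}")
            continue
        for k in range(int(ni)):
            block = [df[f"i{k+1}_{f}"].iloc[r] for f in ("stage", "x", "y", "z", "E")]
            if any(pd.isna(v) for v in block):
                errors.append(
                    f"line {line}: n_interactions={ni} but interaction {k+1} is incomplete"
                )
                break
            if df[f"i{k+1}_E"].iloc[r] <= 0:
                errors.append(f"line {line}: nonpositive energy in interaction {k+1}")
                break
    if errors:
        raise PGLMFormatError("; ".join(errors))
    pos = np.full((n, 3, 3), np.nan)
    ene = np.full((n, 3), np.nan)
    stg = np.zeros((n, 3), dtype=np.int8)
    for k in range(3):
        present = nint > k
        stg[present, k] = df[f"i{k+1}_stage"].to_numpy()[present]
        for j, f in enumerate(("x", "y", "z")):
            pos[present, k, j] = df[f"i{k+1}_{f}"].to_numpy()[present]
        ene[present, k] = df[f"i{k+1}_E"].to_numpy()[present]
    species = df["species"].fillna("").astype(str).to_numpy(dtype=object)
    return ListModeData(
        n_interactions=nint.astype(np.int8),
        positions=pos,
        energies=ene,
        stage_ids=stg,
        species=species,
        event_ids=df["event_id"].to_numpy(np.int64),
    )


def write_image(path, image: np.ndarray, voi: VOIGrid) -> None:
    """Raw float32 raster (C order) + JSON sidecar with the grid."""
    path = Path(path)
    image = np.asarray(image, dtype=np.float32)
    if tuple(image.shape) != tuple(voi.dims):
        raise ValueError(f"image shape {image.shape} does not match VOI dims {voi.dims}")
    image.tofile(path)
    sidecar = {
        "origin_mm": list(map(float, voi.lo)),
        "bin_mm": list(map(float, voi.bin)),
        "dims": list(map(int, voi.dims)),
        "dtype": "float32",
        "order": "C",
        "bins": "half-open [lo, hi), 0-based indices, lab-frame mm",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_image(path):
    """Inverse of :func:`write_image`; returns ``(image, VOIGrid)``."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    dims = tuple(sidecar["dims"])
    raw = np.fromfile(path, dtype=np.float32)
    if raw.size != int(np.prod(dims)):
        raise ValueError(
            f"raster has {raw.size} values but sidecar dims {dims} "
            f"imply {int(np.prod(dims))}"
        )
    voi = VOIGrid(lo=tuple(sidecar["origin_mm"]), bin=tuple(sidecar["bin_mm"]), dims=dims)
    return raw.reshape(dims), voi
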