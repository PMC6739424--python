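"""Container and text I/O for membrane-patch trajectories.

A :class:`LipidTrajectory` holds per-frame positions of lipid marker atoms
(one marker per lipid: the phosphate moiety for phospholipids, the hydroxyl
oxygen for sterols) together with the backbone markers of a membrane-bound
peptide and the periodic box. The marker set is constant across frames and
marker ids are stable, which lets positions live in dense arrays.

The on-disk form is a plain tab-delimited table with a one-line JSON header
carrying the box dimensions::

    #lipidscape-trajectory {"box": [100.0, 100.0]}
    frame  time_ps  record_type  id  species  leaflet  x  y  z
    0      0.0      marker       0   POPC     embedded  ...
    0      0.0      backbone     0   .        .         ...
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HEADER_TAG = "#lipidscape-trajectory"

EMBEDDED = "embedded"
OPPOSING = "opposing"
LEAFLETS = (EMBEDDED, OPPOSING)


@dataclass
class LipidTrajectory:
    """Per-frame lipid marker and peptide backbone coordinates.

    Parameters
    ----------
    times : (F,) array, ps — strictly increasing frame times.
    box : (Lx, Ly) in Å.
    ids : (M,) int — stable marker ids.
    species : (M,) str — lipid species per marker.
    leaflet : (M,) str — ``"embedded"`` (helix-containing) or ``"opposing"``.
    xyz : (F, M, 3) float, Å — marker positions (x, y periodic in the box).
    backbone : (F, B, 3) float, Å — peptide backbone marker positions.
    """

    times: np.ndarray
    box: tuple[float, float]
    ids: np.ndarray
    species: np.ndarray
    leaflet: np.ndarray
    xyz: np.ndarray
    backbone: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.backbone = np.asarray(self.backbone, dtype=float)
        self.ids = np.asarray(self.ids)
        self.species = np.asarray(self.species)
        self.leaflet = np.asarray(self.leaflet)
        if len(self.box) != 2 or min(self.box) <= 0:
            raise ValueError("box must be positive (Lx, Ly)")
        self.box = (float(self.box[0]), float(self.box[1]))
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if self.n_frames and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.n_frames:
            if not (np.isfinite(self.xyz).all() and np.isfinite(self.backbone).all()):
                raise ValueError("coordinates must be finite")
            if self.backbone.shape[1] < 3:
                raise ValueError("each frame needs at least 3 backbone markers")
        bad = set(np.unique(self.leaflet)) - set(LEAFLETS) if self.leaflet.size else set()
        if bad:
            raise ValueError(f"unknown leaflet labels: {sorted(bad)}")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_markers(self) -> int:
        return len(self.ids)

    @property
    def duration_ps(self) -> float:
        return float(self.times[-1] - self.times[0]) if self.n_frames else 0.0

    def marker_mask(self, species: str | None, leaflet: str | None) -> np.ndarray:
        """Boolean mask over markers; ``None`` selects everything."""
        mask = np.ones(self.n_markers, dtype=bool)
        if species is not None:
            mask &= self.species == species
            if not mask.any():
                raise ValueError(f"unknown species {species!r}")
        if leaflet is not None:
            if leaflet not in LEAFLETS:
                raise ValueError(f"unknown leaflet {leaflet!r}")
            mask &= self.leaflet == leaflet
        return mask

    # ------------------------------------------------------------------ I/O

    def to_frame_table(self) -> pd.DataFrame:
        """Long-form table with one row per marker/backbone record per frame."""
        F, M, _ = self.xyz.shape if self.n_frames else (0, self.n_markers, 3)
        B = self.backbone.shape[1] if self.n_frames else 0
        parts = []
        for f in range(F):
            m = pd.DataFrame(
                {
                    "frame": f,
                    "time_ps": self.times[f],
                    "record_type": "marker",
                    "id": self.ids,
                    "species": self.species,
                    "leaflet": self.leaflet,
                    "x": self.xyz[f, :, 0],
                    "y": self.xyz[f, :, 1],
                    "z": self.xyz[f, :, 2],
                }
            )
            b = pd.DataFrame(
                {
                    "frame": f,
                    "time_ps": self.times[f],
                    "record_type": "backbone",
                    "id": np.arange(B),
                    "species": ".",
                    "leaflet": ".",
                    "x": self.backbone[f, :, 0],
                    "y": self.backbone[f, :, 1],
                    "z": self.backbone[f, :, 2],
                }
            )
            parts.append(m)
            parts.append(b)
        cols = ["frame", "time_ps", "record_type", "id", "species", "leaflet", "x", "y", "z"]
        if not parts:
            return pd.DataFrame(columns=cols)
        return pd.concat(parts, ignore_index=True)[cols]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{HEADER_TAG} {json.dumps({'box': list(self.box)})}\n")
            self.to_frame_table().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "LipidTrajectory":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith(HEADER_TAG):
                raise ValueError("missing trajectory header line")
            box = json.loads(header[len(HEADER_TAG):])["box"]
            table = pd.read_csv(fh, sep="\t")
        return cls.from_frame_table(table, box=tuple(box))

    @classmethod
    def from_frame_table(cls, table: pd.DataFrame, box) -> "LipidTrajectory":
        """Build from a long-form table; marker ids must be stable across frames."""
        if table.empty:
            return cls(
                times=np.empty(0),
                box=box,
                ids=np.empty(0, dtype=int),
                species=np.empty(0, dtype=object),
                leaflet=np.empty(0, dtype=object),
                xyz=np.empty((0, 0, 3)),
                backbone=np.empty((0, 0, 3)),
            )
        markers = table[table.record_type == "marker"]
        bb = table[table.record_type == "backbone"]
        frames = np.sort(table.frame.unique())
        times = (
            table.drop_duplicates("frame").set_index("frame")["time_ps"].loc[frames].to_numpy()
        )
        first = markers[markers.frame == frames[0]].sort_values("id")
        ids = first["id"].to_numpy()
        species = first["species"].to_numpy()
        leaflet = first["leaflet"].to_numpy()
        M = len(ids)
        xyz = (
            markers.sort_values(["frame", "id"])[["x", "y", "z"]]
            .to_numpy()
            .reshape(len(frames), M, 3)
        )
        B = (bb.frame == frames[0]).sum()
        backbone = (
            bb.sort_values(["frame", "id"])[["x", "y", "z"]]
            .to_numpy()
            .reshape(len(frames), B, 3)
        )
        return cls(times, tuple(box), ids, species, leaflet, xyz, backbone)


def wrap_coords(xy: np.ndarray, box: tuple[float, float], center=(0.0, 0.0)) -> np.ndarray:
    """Wrap (…, 2) coordinates periodically into the box centred on ``center``."""
    xy = np.asarray(xy, dtype=float)
    L = np.asarray(box, dtype=float)
    c = np.asarray(center, dtype=float)
    return (xy - (c - L / 2.0)) % L + (c - L / 2.0)
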