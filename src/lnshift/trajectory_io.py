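"""Multi-frame XYZ trajectory I/O and element relabelling.

Frames carry element symbols and Cartesian coordinates in Å. Extended-XYZ
comment lines are tolerated; only a ``time`` field (fs) is interpreted, since
dialects vary between MD codes. Atom indexing is 0-based everywhere.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Frame",
    "Trajectory",
    "DonorMap",
    "XYZParseError",
    "XYZFormatError",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "substitute_element",
]

#: Sampling cadence (frames) used for tensor evaluation along AIMD-style
#: trajectories: every 30th 1-fs step, i.e. every 30 fs.
DEFAULT_STRIDE = 30

_TIME_RE = re.compile(r"\btime(?:_fs)?\s*[=:]\s*([-+0-9.eEdD]+)", re.IGNORECASE)


class XYZParseError(ValueError):
    """Malformed XYZ text (bad counts, unparseable atom lines)."""


class XYZFormatError(ValueError):
    """Structurally valid XYZ whose frames are mutually inconsistent."""


@dataclass
class Frame:
    """One snapshot: element labels plus N×3 coordinates in Å."""

    index: int
    elements: list[str]
    coords: np.ndarray
    time: float | None = None  # fs

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an N×3 array")
        if len(self.elements) != self.coords.shape[0]:
            raise ValueError(
                f"frame {self.index}: {len(self.elements)} element labels for "
                f"{self.coords.shape[0]} coordinate rows"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"frame {self.index}: non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "Frame":
        return Frame(self.index, list(self.elements), self.coords.copy(), self.time)


@dataclass
class Trajectory:
    """Ordered frames with a constant atom roster."""

    frames: list[Frame]
    source: str | None = None
    stride: int = 1

    def __post_init__(self) -> None:
        if self.frames:
            ref = self.frames[0].elements
            for fr in self.frames[1:]:
                if fr.elements != ref:
                    raise XYZFormatError(
                        f"frame {fr.index}: element sequence differs from frame "
                        f"{self.frames[0].index}"
                    )
            idx = [fr.index for fr in self.frames]
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms if self.frames else 0

    @property
    def elements(self) -> list[str]:
        return list(self.frames[0].elements) if self.frames else []

    @property
    def times(self) -> np.ndarray:
        return np.array(
            [fr.time if fr.time is not None else float(fr.index) for fr in self.frames]
        )

    def coordinate_array(self) -> np.ndarray:
        """All coordinates stacked as (n_frames, n_atoms, 3)."""
        return np.stack([fr.coords for fr in self.frames])


@dataclass
class DonorMap:
    """0-based atom indices of the metal, the three donor triplets and the
    three pyridyl-proton triplets of the tricapped C3 complex."""

    metal: int
    o_donors: list[int]
    n_ax: list[int]
    n_eq: list[int]
    h_triplets: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, grp in (("o_donors", self.o_donors), ("n_ax", self.n_ax), ("n_eq", self.n_eq)):
            if len(grp) != 3:
                raise ValueError(f"{name} must have exactly 3 members, got {len(grp)}")
        for name, grp in self.h_triplets.items():
            if len(grp) != 3:
                raise ValueError(f"H triplet {name} must have exactly 3 members")
        if len(set(self.all_indices())) != len(self.all_indices()):
            raise ValueError("donor-map indices must be distinct")

    def donor_group(self, group: str) -> list[int]:
        try:
            return {"O": self.o_donors, "N_ax": self.n_ax, "N_eq": self.n_eq}[group]
        except KeyError:
            raise ValueError(f"unknown donor group {group!r}; expected O, N_ax or N_eq")

    def all_indices(self) -> list[int]:
        out = [self.metal, *self.o_donors, *self.n_ax, *self.n_eq]
        for grp in self.h_triplets.values():
            out.extend(grp)
        return out

    def validate_against(self, n_atoms: int) -> None:
        bad = [i for i in self.all_indices() if not 0 <= i < n_atoms]
        if bad:
            raise ValueError(f"donor-map indices {bad} outside atom count {n_atoms}")

    def to_dict(self) -> dict:
        return {
            "metal": self.metal,
            "o_donors": list(self.o_donors),
            "n_ax": list(self.n_ax),
            "n_eq": list(self.n_eq),
            "h_triplets": {k: list(v) for k, v in self.h_triplets.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DonorMap":
        return cls(
            metal=int(d["metal"]),
            o_donors=[int(i) for i in d["o_donors"]],
            n_ax=[int(i) for i in d["n_ax"]],
            n_eq=[int(i) for i in d["n_eq"]],
            h_triplets={str(k): [int(i) for i in v] for k, v in d.get("h_triplets", {}).items()},
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "DonorMap":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _parse_time(comment: str) -> float | None:
    m = _TIME_RE.search(comment)
    if m is None:
        return None
    return float(m.group(1).replace("D", "e").replace("d", "e"))


def read_xyz_trajectory(
    path: str | Path,
    stride: int = 1,
    dt_fs: float | None = None,
) -> Trajectory:
    """Read a (multi-frame) XYZ file, keeping frames 0, stride, 2·stride, …

    Frame times are taken from a ``time=…`` field on the comment line when
    present; otherwise, if ``dt_fs`` is given, ``index·dt_fs`` is assumed.
    """
    if stride < 1:
        raise ValueError("stride must be ≥ 1")
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[Frame] = []
    pos = 0
    frame_no = 0
    while pos < len(lines):
        if not lines[pos].strip():  # tolerate trailing blank lines
            pos += 1
            continue
        try:
            n = int(lines[pos].strip().split()[0])
        except (ValueError, IndexError):
            raise XYZParseError(
                f"{path}: frame {frame_no}: expected atom count, got {lines[pos]!r}"
            )
        if pos + 2 + n > len(lines):
            raise XYZParseError(
                f"{path}: frame {frame_no}: header declares {n} atoms but file ends early"
            )
        comment = lines[pos + 1]
        elements: list[str] = []
        coords = np.empty((n, 3))
        for j in range(n):
            parts = lines[pos + 2 + j].split()
            if len(parts) < 4:
                raise XYZParseError(
                    f"{path}: frame {frame_no}: atom line {j} has "
                    f"{len(parts)} fields (need ≥ 4): {lines[pos + 2 + j]!r}"
                )
            try:
                coords[j] = [float(x) for x in parts[1:4]]
            except ValueError:
                raise XYZParseError(
                    f"{path}: frame {frame_no}: unparseable coordinates on atom line {j}"
                )
            elements.append(parts[0])
        if frame_no % stride == 0:
            t = _parse_time(comment)
            if t is None and dt_fs is not None:
                t = frame_no * dt_fs
            frames.append(Frame(index=frame_no, elements=elements, coords=coords, time=t))
        pos += 2 + n
        frame_no += 1
    return Trajectory(frames=frames, source=str(path), stride=stride)


def write_xyz_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """Write standard XYZ blocks; coordinates printed to 8 decimal places."""
    if len(traj) == 0:
        raise ValueError("refusing to write an empty trajectory")
    path = Path(path)
    chunks: list[str] = []
    for fr in traj:
        comment = f"frame={fr.index}"
        if fr.time is not None:
            comment += f" time_fs={fr.time:.6f}"
        body = "\n".join(
            f"{el:<3s} {x:18.8f} {y:18.8f} {z:18.8f}"
            for el, (x, y, z) in zip(fr.elements, fr.coords)
        )
        chunks.append(f"{fr.n_atoms}\n{comment}\n{body}")
    path.write_text("\n".join(chunks) + "\n")
    return path


def substitute_element(
    traj: Trajectory, from_symbol: str, to_symbol: str
) -> tuple[Trajectory, int]:
    """Relabel every ``from_symbol`` atom as ``to_symbol``.

    Coordinates are untouched. Returns the new trajectory and the number of
    substituted atoms per frame; zero occurrences is a warning, not an error.
    """
    if not from_symbol or not to_symbol:
        raise ValueError("element symbols must be non-empty")
    count = traj.elements.count(from_symbol) if len(traj) else 0
    if count == 0:
        logger.warning("substitute_element: no %s atoms found; trajectory unchanged", from_symbol)
        return traj, 0
    new_frames = []
    for fr in traj:
        elements = [to_symbol if el == from_symbol else el for el in fr.elements]
        new_frames.append(Frame(fr.index, elements, fr.coords.copy(), fr.time))
    return Trajectory(new_frames, source=traj.source, stride=traj.stride), count
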