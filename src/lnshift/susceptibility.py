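"""Magnetic susceptibility tensors and pseudocontact shifts.

The pseudocontact (dipolar) shift of a nucleus at position **r** relative to
the paramagnetic metal is computed from the traceless part χ̃ of the molecular
susceptibility tensor with the point-dipole expression

    δ_pc = 10⁶ · (1/(4π r⁵)) · rᵀ χ̃ r            (χ̃ in m³ per molecule, r in m)

or equivalently, in the principal axis system (PAS),

    δ_pc = 10⁶ · (1/(12π r⁵)) · [Δχ_ax (3z² − r²) + (3/2) Δχ_rh (x² − y²)].

Both code paths are evaluated and asserted mutually consistent. Bleaney's
simplified one-parameter model, δ ∝ C_J·B₂⁰·(3cos²θ−1)/(r³T²), is provided
for comparison; only its ratios, nulls and scalings are physically meaningful
here because its absolute prefactor is a convention.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import BLEANEY_CJ, CHI_CGS_MOLAR_TO_SI_MOLECULE
from .trajectory_io import DonorMap, Trajectory

__all__ = [
    "CGS_MOLAR",
    "SI_MOLECULE",
    "ChiTensor",
    "ChiDecomposition",
    "BleaneyParams",
    "ShiftSeries",
    "convert_chi_units",
    "decompose_chi",
    "pcs_full_tensor",
    "pcs_bleaney",
    "pcs_trajectory",
    "load_chi_series",
    "save_chi_series",
]

CGS_MOLAR = "cgs_molar_cm3_per_mol"
SI_MOLECULE = "si_molecular_m3"
_UNITS = (CGS_MOLAR, SI_MOLECULE)

ANGSTROM = 1e-10  # m


@dataclass
class ChiTensor:
    """3×3 symmetric magnetic susceptibility with an explicit unit flag."""

    matrix: np.ndarray
    units: str = CGS_MOLAR
    temperature: float = 298.0  # K

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("χ must be 3×3")
        if self.units not in _UNITS:
            raise ValueError(f"unknown unit flag {self.units!r}")
        scale = max(np.abs(self.matrix).max(), 1e-300)
        if np.abs(self.matrix - self.matrix.T).max() > 1e-10 * scale:
            raise ValueError("χ must be symmetric")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("χ must be finite")
        # symmetrize exactly so downstream eigh sees a clean input
        self.matrix = 0.5 * (self.matrix + self.matrix.T)

    @property
    def iso(self) -> float:
        return float(np.trace(self.matrix) / 3.0)

    def traceless(self) -> np.ndarray:
        return self.matrix - self.iso * np.eye(3)


@dataclass
class ChiDecomposition:
    iso: float
    eigenvalues: np.ndarray      # full-tensor eigenvalues ordered (x, y, z)
    axes: np.ndarray             # 3×3, columns = PAS x, y, z (right-handed)
    dchi_ax: float               # Δχ_ax = χzz − (χxx+χyy)/2
    dchi_rh: float               # Δχ_rh = χxx − χyy
    anisotropy_class: str        # "easy-axis" | "easy-plane"
    units: str = CGS_MOLAR


@dataclass
class BleaneyParams:
    """Inputs of Bleaney's one-parameter shift model."""

    b20: float                       # axial CF parameter, cm⁻¹
    ion: str = "Dy"
    cj: float | None = None          # defaults to the bundled table (C_Dy = −100)
    temperature: float = 298.0       # K
    prefactor: float = 1.0           # absolute-scale convention hook

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.cj is None:
            if self.ion not in BLEANEY_CJ:
                raise ValueError(f"no bundled Bleaney constant for {self.ion!r}")
            self.cj = BLEANEY_CJ[self.ion]


def convert_chi_units(chi: ChiTensor, target: str) -> ChiTensor:
    """cgs molar (cm³ mol⁻¹) ↔ SI per-molecule (m³); χ_SI = χ_cgs·4π×10⁻⁶/N_A."""
    if target not in _UNITS:
        raise ValueError(f"unknown unit flag {target!r}")
    if target == chi.units:
        return ChiTensor(chi.matrix.copy(), chi.units, chi.temperature)
    if target == SI_MOLECULE:
        m = chi.matrix * CHI_CGS_MOLAR_TO_SI_MOLECULE
    else:
        m = chi.matrix / CHI_CGS_MOLAR_TO_SI_MOLECULE
    return ChiTensor(m, target, chi.temperature)


def _canonical_sign(v: np.ndarray) -> np.ndarray:
    """Flip an eigenvector so its largest-|component| entry is positive."""
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


def decompose_chi(chi: ChiTensor) -> ChiDecomposition:
    """Isotropic part, PAS and axial/rhombic anisotropies.

    Axis convention (standard paramagnetic-NMR/Haeberlen ordering of the
    traceless eigenvalues): |χ'zz| ≥ |χ'xx| ≥ |χ'yy|, which guarantees
    |Δχ_rh| ≤ (2/3)|Δχ_ax|; the frame is made right-handed.
    """
    iso = chi.iso
    evals, evecs = np.linalg.eigh(chi.traceless())
    order = np.argsort(np.abs(evals))          # |yy| ≤ |xx| ≤ |zz|
    iy, ix, iz = order
    perm = [ix, iy, iz]                        # columns x, y, z
    vals = evals[perm]
    axes = evecs[:, perm]
    axes = np.column_stack([_canonical_sign(axes[:, k]) for k in range(3)])
    if np.linalg.det(axes) < 0:
        axes[:, 1] = -axes[:, 1]
    dchi_ax = 1.5 * vals[2]
    dchi_rh = vals[0] - vals[1]
    klass = "easy-axis" if vals[2] > 0 else "easy-plane"
    return ChiDecomposition(
        iso=iso,
        eigenvalues=vals + iso,
        axes=axes,
        dchi_ax=float(dchi_ax),
        dchi_rh=float(dchi_rh),
        anisotropy_class=klass,
        units=chi.units,
    )


def pcs_full_tensor(chi: ChiTensor, metal, nucleus) -> float:
    """Point-dipole pseudocontact shift in ppm.

    Positions are in Å; χ is converted internally to SI per-molecule m³.
    Both the coordinate-free and the PAS forms are evaluated and must agree.
    """
    chi_si = convert_chi_units(chi, SI_MOLECULE)
    r_vec = (np.asarray(nucleus, dtype=float) - np.asarray(metal, dtype=float)) * ANGSTROM
    r = np.linalg.norm(r_vec)
    if r < 0.5 * ANGSTROM:
        raise ValueError(
            f"metal–nucleus distance {r / ANGSTROM:.3f} Å too short for the "
            "point-dipole approximation"
        )
    chit = chi_si.traceless()
    delta = 1e6 * (r_vec @ chit @ r_vec) / (4.0 * math.pi * r**5)

    dec = decompose_chi(chi_si)
    x, y, z = dec.axes.T @ r_vec
    delta_pas = (
        1e6
        / (12.0 * math.pi * r**5)
        * (dec.dchi_ax * (3.0 * z**2 - r**2) + 1.5 * dec.dchi_rh * (x**2 - y**2))
    )
    # consistency floor scaled to the intrinsic shift magnitude of the tensor
    scale = max(abs(delta), abs(delta_pas), 1e6 * np.linalg.norm(chit) / (4.0 * math.pi * r**3))
    if abs(delta - delta_pas) > 1e-8 * scale:
        raise AssertionError(
            f"PCS dual-formula mismatch: coordinate-free {delta} vs PAS {delta_pas}"
        )
    return float(delta)


def pcs_bleaney(params: BleaneyParams, theta_deg: float, r_angstrom: float) -> float:
    """Bleaney-model shift, δ ∝ C_J·B₂⁰·(3cos²θ−1)/(r³·T²), convention units."""
    if r_angstrom <= 0:
        raise ValueError("r must be positive")
    geom = (3.0 * math.cos(math.radians(theta_deg)) ** 2 - 1.0) / r_angstrom**3
    return float(params.prefactor * params.cj * params.b20 * geom / params.temperature**2)


@dataclass
class ShiftSeries:
    """Per-frame, per-proton pseudocontact shifts plus triplet/time averages."""

    per_atom: pd.DataFrame              # columns like H1_a/H1_b/… (ppm)
    triplet: pd.DataFrame               # columns H1, H2, H3 (ppm)
    times: np.ndarray                   # fs
    atom_indices: dict[str, list[int]] = field(default_factory=dict)
    solvent: str | None = None

    @property
    def time_average(self) -> pd.Series:
        return self.triplet.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        out = pd.concat([self.per_atom, self.triplet], axis=1)
        out.insert(0, "time_fs", self.times)
        return out


def pcs_trajectory(
    traj: Trajectory,
    chi_series: list[ChiTensor],
    donors: DonorMap,
    solvent: str | None = None,
) -> ShiftSeries:
    """Full-tensor PCS of the nine pyridyl protons along a trajectory.

    Each frame uses its own metal position and its own tensor; triplet
    averages are the arithmetic mean of the three symmetry-related protons.
    """
    if len(chi_series) != len(traj):
        raise ValueError(
            f"{len(chi_series)} tensors for {len(traj)} frames; one χ per frame required"
        )
    if not donors.h_triplets:
        raise ValueError("donor map defines no H triplets")
    donors.validate_against(traj.n_atoms)
    names = sorted(donors.h_triplets)
    per_atom_cols = {f"{t}_{chr(97 + a)}": np.empty(len(traj)) for t in names for a in range(3)}
    for i, (frame, chi) in enumerate(zip(traj, chi_series)):
        metal = frame.coords[donors.metal]
        for t in names:
            for a, j in enumerate(donors.h_triplets[t]):
                per_atom_cols[f"{t}_{chr(97 + a)}"][i] = pcs_full_tensor(
                    chi, metal, frame.coords[j]
                )
    per_atom = pd.DataFrame(per_atom_cols)
    triplet = pd.DataFrame(
        {t: per_atom[[f"{t}_{chr(97 + a)}" for a in range(3)]].mean(axis=1) for t in names}
    )
    return ShiftSeries(
        per_atom=per_atom,
        triplet=triplet,
        times=traj.times,
        atom_indices={t: list(v) for t, v in donors.h_triplets.items()},
        solvent=solvent,
    )


def save_chi_series(series: list[ChiTensor], path: str | Path) -> None:
    """JSON list of frames: {frame, T_K, units, chi: 3×3}."""
    payload = [
        {"frame": i, "T_K": c.temperature, "units": c.units, "chi": c.matrix.tolist()}
        for i, c in enumerate(series)
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def load_chi_series(path: str | Path) -> list[ChiTensor]:
    payload = json.loads(Path(path).read_text())
    return [
        ChiTensor(np.array(rec["chi"]), rec.get("units", CGS_MOLAR), rec.get("T_K", 298.0))
        for rec in payload
    ]
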