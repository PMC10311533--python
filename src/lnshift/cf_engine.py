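"""Crystal-field surrogate for the lanthanide electronic structure.

Desk-scale replacement for the ab initio (CASSCF-SO) stage: the ground
multiplet |J, mJ⟩ of the Ln(III) ion is split by a crystal-field (CF)
Hamiltonian H = Σ_{k,q} B_k^q O_k^q built from Stevens operator equivalents,
with the coefficients B_k^q obtained from a point-charge electrostatic model.
The magnetic susceptibility tensor then follows from Van Vleck statistical
mechanics, χ ∝ −∂²F/∂B∂B at B → 0.

This engine makes no claim of quantitative agreement with multireference
calculations; it reproduces the mechanisms that matter for the analysis:
the (3cos²θ−1)/R³ dependence of B₂⁰ with its magic-angle null, the
axial/equatorial cancellation, sign-driven easy-axis ↔ easy-plane switching,
and the exact Curie limit at zero CF.

Rank-k operator sets are built by ladder-operator recursion from (J₊)^k and
rescaled per rank to the Stevens normalization (O₂⁰ = 3Jz² − J(J+1) exactly);
the charge-side tesseral harmonics use the matching real combination, so the
whole chain is rotationally equivariant by construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import yaml
from scipy.special import sph_harm_y

from .constants import (
    BOHR_RADIUS_ANGSTROM,
    CM1_TO_J,
    DY_RADIAL_EXPECTATION_A0,
    DY_STEVENS_THETA,
    E2_OVER_4PI_EPS0_CM_ANGSTROM,
    K_B_CM_PER_K,
    MU_B_CM_PER_T,
    XI_SI_TO_CHI_CGS_MOLAR,
)
from .susceptibility import CGS_MOLAR, ChiTensor
from .trajectory_io import DonorMap, Frame

__all__ = [
    "SpinSystem",
    "CFParameters",
    "ChargeSet",
    "stevens_operator",
    "tesseral_harmonic",
    "point_charge_cf",
    "cf_hamiltonian",
    "vanvleck_chi",
    "vanvleck_chi_sos",
    "charges_from_frame",
    "default_ak",
]

_RANKS = (2, 4, 6)


@dataclass(frozen=True)
class SpinSystem:
    """Ground multiplet: total angular momentum J and Landé factor gJ.

    Defaults describe Dy(III), 4f⁹, ⁶H₁₅/₂ (J = 15/2, gJ = 4/3, 16 states).
    """

    J: float = 7.5
    gJ: float = 4.0 / 3.0

    def __post_init__(self) -> None:
        dim = 2 * self.J + 1
        if abs(dim - round(dim)) > 1e-12 or dim < 2:
            raise ValueError("2J+1 must be a positive integer ≥ 2")
        if self.gJ <= 0:
            raise ValueError("gJ must be positive")

    @property
    def dim(self) -> int:
        return int(round(2 * self.J + 1))

    @property
    def mj(self) -> np.ndarray:
        """mJ values, descending J … −J."""
        return self.J - np.arange(self.dim)

    def jz(self) -> np.ndarray:
        return np.diag(self.mj).astype(complex)

    def jplus(self) -> np.ndarray:
        m = self.mj
        out = np.zeros((self.dim, self.dim), dtype=complex)
        for i in range(1, self.dim):
            out[i - 1, i] = math.sqrt(self.J * (self.J + 1) - m[i] * (m[i] + 1))
        return out

    def jminus(self) -> np.ndarray:
        return self.jplus().conj().T

    def jvec(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        jp, jm = self.jplus(), self.jminus()
        return (jp + jm) / 2.0, (jp - jm) / 2.0j, self.jz()


def _stevens_q0_diagonal(system: SpinSystem, k: int) -> np.ndarray:
    """Closed-form diagonal Stevens operators O_k^0 in the |J,mJ⟩ basis."""
    m = system.mj
    x = system.J * (system.J + 1)
    if k == 2:
        d = 3 * m**2 - x
    elif k == 4:
        d = 35 * m**4 - (30 * x - 25) * m**2 + 3 * x**2 - 6 * x
    elif k == 6:
        d = (
            231 * m**6
            - (315 * x - 735) * m**4
            + (105 * x**2 - 525 * x + 294) * m**2
            - 5 * x**3
            + 40 * x**2
            - 60 * x
        )
    else:  # pragma: no cover - guarded by caller
        raise ValueError(f"unsupported rank k={k}")
    return d


@lru_cache(maxsize=32)
def _ito_tensors(J: float, gJ: float, k: int) -> tuple[np.ndarray, ...]:
    """Irreducible tensor operators T_kq, q = −k…k, from downward recursion
    starting at T_kk = (J₊)^k. Satisfy T_kq† = (−1)^q T_k,−q."""
    system = SpinSystem(J, gJ)
    jm = system.jminus()
    t: dict[int, np.ndarray] = {k: np.linalg.matrix_power(system.jplus(), k)}
    for q in range(k, -k, -1):
        norm = math.sqrt((k + q) * (k - q + 1))
        t[q - 1] = (jm @ t[q] - t[q] @ jm) / norm
    return tuple(t[q] for q in range(-k, k + 1))


@lru_cache(maxsize=32)
def _stevens_scale(J: float, gJ: float, k: int) -> float:
    """Per-rank scalar mapping the recursion's T_k0 onto the Stevens O_k0."""
    system = SpinSystem(J, gJ)
    t0 = np.real(np.diag(_ito_tensors(J, gJ, k)[k]))
    o0 = _stevens_q0_diagonal(system, k)
    return float(np.dot(o0, t0) / np.dot(t0, t0))


def stevens_operator(system: SpinSystem, k: int, q: int) -> np.ndarray:
    """Hermitian Stevens operator-equivalent matrix O_k^q ((2J+1)×(2J+1)).

    q = 0 uses the exact closed-form diagonal (O₂⁰ = 3Jz² − J(J+1), …);
    |q| > 0 are the real (cosine/sine) combinations of the ladder-recursion
    tensors, on the same per-rank Stevens scale.
    """
    if k not in _RANKS:
        raise ValueError(f"rank k must be one of {_RANKS}, got {k}")
    if abs(q) > k:
        raise ValueError(f"|q| must not exceed k, got q={q}, k={k}")
    if k > 2 * system.J:
        raise ValueError(
            f"rank k={k} exceeds 2J={2 * system.J:g}: operator vanishes identically"
        )
    if q == 0:
        return np.diag(_stevens_q0_diagonal(system, k)).astype(complex)
    t = _ito_tensors(system.J, system.gJ, k)
    s = _stevens_scale(system.J, system.gJ, k)
    m = abs(q)
    tp, tm = t[k + m], t[k - m]  # T_k,+m and T_k,−m
    if q > 0:
        op = (tm + (-1) ** m * tp) / math.sqrt(2.0)
    else:
        op = 1j * (tm - (-1) ** m * tp) / math.sqrt(2.0)
    return s * op


# Per-rank scale turning orthonormal real harmonics into the Stevens-classical
# normalization: z_k0(θ) = {3cos²θ−1, 35c⁴−30c²+3, 231c⁶−315c⁴+105c²−5}.
_Z_SCALE = {2: 2.0, 4: 8.0, 6: 16.0}


def tesseral_harmonic(k: int, q: int, theta: float, phi: float) -> float:
    """Real tesseral harmonic z_kq matching the Stevens operator convention
    (z₂₀ = 3cos²θ − 1)."""
    if k not in _RANKS or abs(q) > k:
        raise ValueError(f"invalid (k, q) = ({k}, {q})")
    nk = _Z_SCALE[k] * math.sqrt(4.0 * math.pi / (2 * k + 1))
    if q == 0:
        val = sph_harm_y(k, 0, theta, phi).real
    else:
        m = abs(q)
        y = sph_harm_y(k, m, theta, phi)
        val = math.sqrt(2.0) * (-1) ** m * (y.real if q > 0 else y.imag)
    return nk * float(val)


@dataclass
class CFParameters:
    """Crystal-field coefficients B_k^q (cm⁻¹), real tesseral convention."""

    coefficients: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (k, q), v in self.coefficients.items():
            if k not in _RANKS or abs(q) > k:
                raise ValueError(f"invalid CF index (k={k}, q={q})")
            if not np.isfinite(v):
                raise ValueError(f"non-finite B_{k}^{q}")

    def get(self, k: int, q: int) -> float:
        return self.coefficients.get((k, q), 0.0)

    def to_json(self, path: str | Path) -> None:
        payload = [{"k": k, "q": q, "value": v} for (k, q), v in sorted(self.coefficients.items())]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CFParameters":
        payload = json.loads(Path(path).read_text())
        return cls({(int(r["k"]), int(r["q"])): float(r["value"]) for r in payload})


def default_ak() -> dict[int, float]:
    """Order-of-magnitude Dy(III) radial prefactors A_k (cm⁻¹·Å^{k+1}).

    Folds the Stevens factor θ_k, the ⟨r^k⟩ radial expectation and the
    classical point-charge geometric prefactor (1/2, 1/8, 1/16) together with
    e²/(4πε₀); the sign convention is such that a negative ligand charge on
    the +z axis yields B₂⁰ < 0 (easy-axis ground doublet for oblate Dy(III)).
    """
    geom = {2: 0.5, 4: 0.125, 6: 0.0625}
    return {
        k: -DY_STEVENS_THETA[k]
        * DY_RADIAL_EXPECTATION_A0[k]
        * BOHR_RADIUS_ANGSTROM**k
        * E2_OVER_4PI_EPS0_CM_ANGSTROM
        * geom[k]
        for k in _RANKS
    }


@dataclass
class ChargeSet:
    """Point charges (units of e) at positions (Å) relative to the metal,
    plus per-rank radial scale factors A_k."""

    charges: list[tuple[float, np.ndarray]]
    a_k: dict[int, float] = field(default_factory=default_ak)

    def __post_init__(self) -> None:
        cleaned = []
        for qval, pos in self.charges:
            pos = np.asarray(pos, dtype=float)
            if pos.shape != (3,):
                raise ValueError("charge positions must be 3-vectors")
            if np.linalg.norm(pos) < 1e-10:
                raise ValueError("point charge at the metal position")
            cleaned.append((float(qval), pos))
        self.charges = cleaned
        for k in _RANKS:
            if not np.isfinite(self.a_k.get(k, 0.0)):
                raise ValueError(f"A_{k} must be finite")

    def rotated(self, rot: np.ndarray) -> "ChargeSet":
        return ChargeSet([(q, rot @ p) for q, p in self.charges], dict(self.a_k))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ChargeSet":
        d = yaml.safe_load(Path(path).read_text())
        a_k = {k: float(d.get(f"A{k}", default_ak()[k])) for k in _RANKS}
        charges = [(float(c["q"]), np.array([c["x"], c["y"], c["z"]], float)) for c in d["charges"]]
        return cls(charges, a_k)


def point_charge_cf(charges: ChargeSet, system: SpinSystem) -> CFParameters:
    """B_k^q = A_k · Σ_i q_i · z_kq(θ_i, φ_i) / R_i^{k+1}.

    A single charge contributes A₂·q·(3cos²θ−1)/R³ to B₂⁰, which vanishes at
    the magic angle θ = arccos(1/√3). Ranks with k > 2J are omitted.
    """
    if not charges.charges:
        raise ValueError("empty charge set")
    coeffs: dict[tuple[int, int], float] = {}
    for k in _RANKS:
        if k > 2 * system.J:
            continue
        ak = charges.a_k.get(k, 0.0)
        for q in range(-k, k + 1):
            total = 0.0
            for qval, pos in charges.charges:
                r = np.linalg.norm(pos)
                theta = math.acos(np.clip(pos[2] / r, -1.0, 1.0))
                phi = math.atan2(pos[1], pos[0])
                total += qval * tesseral_harmonic(k, q, theta, phi) / r ** (k + 1)
            coeffs[(k, q)] = ak * total
    return CFParameters(coeffs)


def cf_hamiltonian(params: CFParameters, system: SpinSystem) -> np.ndarray:
    """H = Σ_{k,q} B_k^q O_k^q, Hermitian, in cm⁻¹."""
    h = np.zeros((system.dim, system.dim), dtype=complex)
    for (k, q), b in params.coefficients.items():
        if b != 0.0 and k <= 2 * system.J:
            h += b * stevens_operator(system, k, q)
    return 0.5 * (h + h.conj().T)


def _check_hermitian(h: np.ndarray) -> np.ndarray:
    h = np.asarray(h, dtype=complex)
    scale = max(np.abs(h).max(), 1.0)
    if np.abs(h - h.conj().T).max() > 1e-10 * scale:
        raise ValueError("Hamiltonian must be Hermitian")
    return h


def _magnetization(
    h: np.ndarray, system: SpinSystem, temperature: float, b_field: np.ndarray
) -> np.ndarray:
    """Thermal-equilibrium moment ⟨μ⟩ (J T⁻¹) at field B via the
    Hellmann–Feynman trace M = −Tr(ρ ∂H/∂B)."""
    jx, jy, jz = system.jvec()
    zee = system.gJ * MU_B_CM_PER_T * (b_field[0] * jx + b_field[1] * jy + b_field[2] * jz)
    evals, vecs = np.linalg.eigh(h + zee)
    beta = 1.0 / (K_B_CM_PER_K * temperature)
    w = np.exp(-beta * (evals - evals[0]))
    w /= w.sum()
    out = np.empty(3)
    for a, j in enumerate((jx, jy, jz)):
        jd = np.real(np.einsum("in,ij,jn->n", vecs.conj(), j, vecs))
        out[a] = -system.gJ * MU_B_CM_PER_T * float(np.dot(w, jd))
    return out * CM1_TO_J


def vanvleck_chi(
    h: np.ndarray,
    system: SpinSystem,
    temperature: float,
    delta_b: float = 1e-3,
    check: bool = True,
    check_tol: float = 1e-6,
) -> ChiTensor:
    """Equilibrium susceptibility tensor (cgs molar, cm³ mol⁻¹) at T.

    χ_αβ = −μ₀N_A ∂²F/∂B_α∂B_β at B = 0, evaluated as a symmetric central
    finite difference of the analytic magnetization M = −∂F/∂B (step δB,
    default 1 mT), with a Richardson step-halving consistency pass. A
    sum-over-states Van Vleck evaluation (`vanvleck_chi_sos`) serves as the
    independent oracle; disagreement beyond ``check_tol`` raises.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    h = _check_hermitian(h)

    def fd(step: float) -> np.ndarray:
        xi = np.empty((3, 3))
        for b_ax in range(3):
            bv = np.zeros(3)
            bv[b_ax] = step
            xi[:, b_ax] = (
                _magnetization(h, system, temperature, bv)
                - _magnetization(h, system, temperature, -bv)
            ) / (2.0 * step)
        return xi

    xi_full = fd(delta_b)
    xi_half = fd(delta_b / 2.0)
    xi = (4.0 * xi_half - xi_full) / 3.0  # Richardson on the O(δ²) error
    xi = 0.5 * (xi + xi.T)
    chi = ChiTensor(XI_SI_TO_CHI_CGS_MOLAR * xi, CGS_MOLAR, temperature)
    if check:
        ref = vanvleck_chi_sos(h, system, temperature)
        num = np.linalg.norm(chi.matrix - ref.matrix)
        den = np.linalg.norm(ref.matrix)
        if den > 0 and num / den > check_tol:
            raise FloatingPointError(
                f"finite-difference susceptibility deviates from sum-over-states "
                f"oracle by {num / den:.3e} relative (tolerance {check_tol:g})"
            )
    return chi


def vanvleck_chi_sos(
    h: np.ndarray,
    system: SpinSystem,
    temperature: float,
    degeneracy_tol_cm: float = 1e-8,
) -> ChiTensor:
    """Sum-over-states (Kubo/Van Vleck) susceptibility at B = 0.

    Levels closer than ``degeneracy_tol_cm`` share the Curie-type (first-order
    Zeeman) weight β·p_n; all other pairs carry the temperature-independent
    (second-order) weight (p_n − p_m)/(E_m − E_n), evaluated with expm1 for
    numerical stability. Output in cgs molar units.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    h = _check_hermitian(h)
    evals, vecs = np.linalg.eigh(h)
    beta = 1.0 / (K_B_CM_PER_K * temperature)
    p = np.exp(-beta * (evals - evals[0]))
    p /= p.sum()
    gap = evals[:, None] - evals[None, :]          # E_n − E_m
    same = np.abs(gap) < degeneracy_tol_cm
    pn = np.broadcast_to(p[:, None], gap.shape)
    pm = np.broadcast_to(p[None, :], gap.shape)
    w = np.empty_like(gap)
    w[same] = beta * pn[same]
    # (p_n − p_m)/(E_m − E_n): expm1 form for near-degenerate pairs (avoids
    # cancellation), direct form for well-separated levels (avoids overflow)
    close = ~same & (beta * np.abs(gap) < 0.01)
    far = ~same & ~close
    w[close] = pn[close] * (-np.expm1(beta * gap[close])) / (-gap[close])
    w[far] = (pn[far] - pm[far]) / (-gap[far])
    jx, jy, jz = system.jvec()
    mu = [
        -system.gJ * MU_B_CM_PER_T * (vecs.conj().T @ j @ vecs) for j in (jx, jy, jz)
    ]
    mean = np.array([float(np.dot(p, np.real(np.diag(m)))) for m in mu])
    xi = np.empty((3, 3))
    for a in range(3):
        for b in range(a, 3):
            term = float(np.sum(w * np.real(mu[a] * mu[b].T)))
            xi[a, b] = xi[b, a] = term - beta * mean[a] * mean[b]
    xi *= CM1_TO_J  # (cm⁻¹ T⁻²)·(J/cm⁻¹) → J T⁻²
    return ChiTensor(XI_SI_TO_CHI_CGS_MOLAR * xi, CGS_MOLAR, temperature)


def charges_from_frame(
    frame: Frame,
    donors: DonorMap,
    group_charges: dict[str, float],
    a_k: dict[int, float] | None = None,
) -> ChargeSet:
    """Place the configured donor-group charges at the donor positions of one
    frame, relative to the metal."""
    donors.validate_against(frame.n_atoms)
    metal = frame.coords[donors.metal]
    charges: list[tuple[float, np.ndarray]] = []
    for group, qval in group_charges.items():
        for i in donors.donor_group(group):
            charges.append((qval, frame.coords[i] - metal))
    return ChargeSet(charges, dict(a_k) if a_k is not None else default_ak())
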