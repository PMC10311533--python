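# Methods

## Scope and model chain

`lnshift` analyses how the internal geometry dynamics of a C3-symmetric
tricapped lanthanide complex (metal + three arms, each carrying a carboxylate
O, a TACN axial N, a pyridyl equatorial N and three pyridyl protons) drive
fluctuations in the magnetic susceptibility tensor and in the pseudocontact
NMR shifts of the protons. The chain is

trajectory → pseudo-C̃₃ axis and donor angles → crystal-field surrogate →
Van Vleck χ(T) → point-dipole δ_pc → time/triplet averages and statistics.

Two cluster-scale stages of the original workflow are replaced by desk-scale
components: solution ab initio MD by a stochastic geometry generator, and
multireference (CASSCF-SO) electronic structure by a point-charge
crystal-field model on the ground multiplet. Both replacements are
mechanism-faithful, not quantitatively predictive; everything downstream of
them (geometry, tensor algebra, shift formulas, statistics) is exact.

## Geometry

The instantaneous pseudo-threefold axis C̃₃ is the normalized average of the
unit normals of the three donor planes (O, N_ax, N_eq triplets). Normals are
oriented toward the N_ax hemisphere using the O-centroid → N_ax-centroid
vector as reference; this reproduces the conventional regime (O angles ≈ 52°,
N_ax ≈ 39°, N_eq ≈ 90°). The axis is recomputed for every frame — the large
reported per-frame oscillations imply a frame-local axis, and a frozen
frame-0 axis would conflate internal motion with tumbling. Donor–metal–axis
angles are arccos of unit-vector dot products, in degrees; no mass weighting
is used anywhere.

Degenerate inputs (collinear triplets, zero bond vectors, an orientation
reference orthogonal to a plane normal) raise typed geometry errors naming
the offending donor group and frame.

## Susceptibility tensors and pseudocontact shifts

χ is handled in two unit conventions: cgs molar (cm³ mol⁻¹, the convention
of quantum-chemistry outputs) and SI per-molecule volume (m³), with
χ_SI = χ_cgs·4π×10⁻⁶/N_A. Decomposition diagonalizes the traceless part;
the principal axes follow the standard paramagnetic-NMR (Haeberlen) ordering
|χ'_zz| ≥ |χ'_xx| ≥ |χ'_yy|, which guarantees |Δχ_rh| ≤ (2/3)|Δχ_ax|; the
frame is made right-handed, and eigenvector signs are fixed by making the
largest-magnitude component positive. χ'_zz > 0 is classed easy-axis,
χ'_zz < 0 easy-plane.

The full-tensor point-dipole shift is evaluated in two algebraically
equivalent forms — coordinate-free, δ_pc = 10⁶·rᵀχ̃r/(4πr⁵), and the
principal-axis form in Δχ_ax/Δχ_rh — and the two are asserted mutually
consistent on every call (tolerance 10⁻⁸ relative to the intrinsic shift
scale of the tensor). Distances below 0.5 Å are rejected as outside the
point-dipole regime. Bleaney's one-parameter model
δ ∝ C_J·B₂⁰·(3cos²θ−1)/(r³T²) is provided with a bundled C_J table
(normalization C_Dy = −100) and a configurable absolute prefactor; because
the prefactor is a convention, only ratios, nulls and scalings of this model
are meaningful, and only those are asserted in tests.

## Crystal-field surrogate

The ground multiplet |J, mJ⟩ (Dy(III): J = 15/2, g_J = 4/3, 16 states) is
split by H = Σ_{k,q} B_k^q O_k^q with k ∈ {2, 4, 6}. The q = 0 Stevens
operators use exact closed-form diagonals (O₂⁰ = 3J_z² − J(J+1), …); the
|q| > 0 operators are real cosine/sine combinations of irreducible tensor
operators built by ladder recursion from (J₊)^k, rescaled per rank to the
Stevens normalization. The charge-side real tesseral harmonics z_kq use the
matching combination and the matching per-rank scale (z₂₀ = 3cos²θ−1), so
Σ_q B_k^q O_k^q is rotationally invariant by construction and the whole
charges → B_k^q → H → χ chain is equivariant (tested at 10⁻⁸ relative).

Point charges (units of e) at donor positions give
B_k^q = A_k Σ_i q_i z_kq(θ_i, φ_i)/R_i^{k+1}. The per-rank radial factors
A_k fold the Stevens factor θ_k, the radial expectation ⟨r^k⟩
(Freeman–Watson values for Dy³⁺), e²/4πε₀ and the classical geometric
prefactors 1/2, 1/8, 1/16. They are order-of-magnitude defaults with a
config hook — the surrogate claims no quantitative agreement with ab initio
tensors, and no test depends on their absolute values, only on signs, nulls
and ratios. Default group charges are O −0.8 e, N_ax −0.49 e, N_eq −0.40 e,
a sign pattern under which the axial and equatorial rank-2 contributions
oppose and the O contribution crosses zero at the magic angle — the
near-cancellation that makes these complexes anomalous.

The susceptibility is χ_αβ = −μ₀N_A ∂²F/∂B_α∂B_β at B → 0 with
F = −k_BT ln Tr e^(−H(B)/k_BT) and Zeeman coupling g_J μ_B **B**·**J**.
Numerically, the outer derivative is a symmetric central finite difference
(step δB = 1 mT, with a Richardson step-halving pass) applied to the
*analytic* magnetization M = −∂F/∂B, evaluated as the Hellmann–Feynman
thermal trace. Differencing F itself twice would lose ~10 significant digits
at 1 mT (F ≈ −574 cm⁻¹ changes by ~10⁻⁸ cm⁻¹), whereas differencing M is
accurate to ~10⁻¹¹ relative. An independent sum-over-states (Kubo/Van Vleck)
evaluation — Curie-type weights β·p_n for level pairs closer than 10⁻⁸ cm⁻¹,
(p_n−p_m)/(E_m−E_n) otherwise, with expm1-stabilized Boltzmann differences —
is computed alongside every call and a disagreement beyond 10⁻⁶ relative
raises a numerical-stability error. The zero-CF limit reproduces the Curie
law N_A g_J² μ_B² J(J+1)/(3k_BT) (0.0476 cm³ mol⁻¹ for Dy(III) at 298 K) to
10⁻⁸ relative, and a strong easy-axis doublet reproduces the Ising limit
N_A(g_J·J·μ_B)²/(k_BT). Constants are CODATA; energies are cm⁻¹ internally
with k_B = 0.6950348 cm⁻¹ K⁻¹; temperature defaults to 298 K.

## Synthetic trajectories

The template places the metal at the origin and three identical arms at
azimuths 0/120/240°: O at 2.35 Å/52°, N_ax at 2.65 Å/39° (with a 20° TACN
azimuthal twist), N_eq at 2.55 Å/90.5°, and three pyridyl protons per arm.
Proton sites follow the ligand's connectivity — the 6-carboxypyridin-2-yl
ring spans the region between the carboxylate O (θ ≈ 52°) and the N_eq
plane (θ ≈ 90°) — giving H1 (4.6 Å, 62°), H2 (6.3 Å, 74°), H3 (5.4 Å, 88°).

Dynamics: each donor polar angle follows an independent Ornstein–Uhlenbeck
process (exact discretization, stationary start), a bounded mean-reverting
Gaussian model chosen because the reference dynamics show large but bounded
oscillations with no published dynamical model. Defaults: σ_O = 8°,
σ_Nax = σ_Neq = 5° (matching the reported ±10–20° and ±7–14° excursions),
correlation time τ = 100 fs (free parameter; gives trace roughness similar
to the published time series), timestep 1 fs, 10⁴ frames (10 ps). Protons
inherit the O-angle deviation of their arm (the arm moves as a unit); bond
lengths get i.i.d. jitter σ_r = 0.02 Å; an optional rigid-rotation random
walk emulates tumbling (off by default). A single seeded RNG stream makes
runs bit-reproducible.

What the generator does *not* emulate: explicit solvent, hydrogen bonding,
arm–arm coupling, anharmonic/asymmetric angle distributions, and realistic
vibrational spectra. Tests passing on this generator therefore validate the
analysis chain and its mechanisms, not force-field realism.

One measurement subtlety: angles referenced to the per-frame C̃₃ axis absorb
common-mode arm motion, so their apparent standard deviation is ~18% smaller
than the generating OU σ (the mean is unbiased). OU parameter recovery is
therefore checked on lab-frame polar angles — the generator's actual
contract — while the C̃₃-referenced series is checked for mean recovery and
excursion amplitude.

## Statistics and averaging

Descriptive statistics report population standard deviation (divide by n),
appropriate for a complete trajectory; "±" values quoted next to averages
are this population σ. Angle summaries pool all three arms and all frames,
with per-arm series available separately. Histograms use uniform bins
spanning [floor(min), ceil(max)] in units of the bin width (defaults: 5 ppm
for shifts, 1° for angles), half-open with the last bin closed. The average
structure aligns every frame onto frame 0 with a Kabsch (proper-rotation)
superposition of all atoms, unweighted, then averages coordinates and
reports per-atom RMSF. Correlations are Pearson product-moment; the pipeline
reports the correlation between the per-frame mean O angle and each triplet
shift series.

## Problem sizes and orchestration

The end-to-end default is 10⁴ frames at 1 fs with susceptibility evaluated
every 30th frame (334 tensor evaluations), mirroring the sampling cadence of
the workflow it emulates; a full run takes ~10 s on one core. The
acceptance script uses 5000 frames. Each tensor evaluation is 13
diagonalizations of a 16×16 matrix (six field displacements at two Richardson
steps plus the sum-over-states check).

The pipeline writes frames.xyz, donors.yaml, per-group angle CSVs, chi.json,
shifts.csv, report.json, avg.xyz and a manifest recording the config hash
and seed; stage failures propagate with the stage name attached.

## Known limitations

* Ground-multiplet-only electronic model: no excited multiplets,
  intermultiplet mixing, covalency or solvent electrostatics; B_k^q scale
  factors are order-of-magnitude defaults.
* Surrogate shift amplitudes are a few times larger than the reference
  solution-MD scale at the default A_k; ratios, signs, correlations and
  nulls are the validated quantities.
* The template-plus-OU generator keeps azimuths fixed and arms independent;
  it cannot produce correlated arm motions or solvent-exchange events.
* Contact shifts are neglected throughout (appropriate for the distant
  pyridyl protons); fitting tensors from observed shifts is out of scope.
* Periodic-boundary unwrapping is not performed; the complex must be whole
  in every frame, and solvent atoms, if present, are ignored via the donor
  map.
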