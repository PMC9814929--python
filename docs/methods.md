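# Methods

This note documents the models implemented in `oligofib`, the numerical
choices behind them, what the synthetic data emulate, and the limits of what
the tests demonstrate.

## FCS forward model and calibration

The autocorrelation of a fluorescent species diffusing in three dimensions
through a Gaussian confocal volume is modelled as

    G(τ) = Σᵢ αᵢ (1 + τ/τ_{D,i})⁻¹ (1 + τ/(γ²τ_{D,i}))⁻¹ᐟ²,

with relative amplitudes αᵢ, diffusion times τ_{D,i} (seconds) and focal
aspect ratio γ (dimensionless, default 6 — typical for a confocal
microscope). Curves are treated as amplitude-normalized (G(0⁺) = 1); a
`normalized` flag records this, and un-normalized amplitudes simply scale
the αᵢ. Triplet blinking, when enabled, multiplies the diffusion sum by the
standard correction 1 + T/(1−T)·e^(−τ/τ_T); the functional form is the one
conventional fitting software uses, with T = 0 disabling it.

Diffusion times map to coefficients through D = w²ₓᵧ/(4τ_D). The lateral
focal radius w_xy is calibrated by fitting a single-component model to a
reference-dye curve (Alexa-647, D = 330 µm²/s at 25 °C) and inverting the
same relation. The fit is a least-squares over (amplitude, ln τ_D) with
τ_D initialized at the lag of half amplitude — a deterministic, robust
start. On the noiseless synthetic dye curve the round trip returns
w_xy = 299.9 nm.

Internal units throughout: seconds for lags and diffusion times, µm for
w_xy, µm²/s for D. File readers convert on ingest.

## Maximum-entropy inversion

Rather than fixing a component count, the curve is expanded over a
log-spaced grid of N diffusion times (default N = 100 spanning 1 µs–1 s,
which brackets free dye through large oligomers for w_xy ≈ 0.3 µm). The
detection probability of grid species j is

    ρⱼ = αⱼτ_{D,j} / Σᵢ αᵢτ_{D,i},

and the MEM solution maximizes S = −Σ ρⱼ ln ρⱼ subject to χ² ≤ target.
The default χ² target is the number of fitted points — the conventional
"χ² per point of one" criterion. For noiseless inputs a tighter target is
appropriate and exposed as a parameter.

The optimizer solves min ½χ² − µS over non-negative amplitudes:

* the weighted design matrix is column-normalized (the per-point standard
  deviations span several orders of magnitude, and the scaling keeps the
  quadratic term well conditioned);
* the µ → 0 endpoint is an exact non-negative least-squares solve
  (active set), which sets the reachable χ² floor;
* µ then walks up a fixed geometric ladder (57 half-decade steps,
  10⁻⁸–10⁶), each inner problem warm-started from the previous solution and
  solved with L-BFGS-B and an analytic gradient
  (∂S/∂αⱼ = (τⱼ/Z)(−ln ρⱼ − S));
* the feasible solution (χ² ≤ target) of maximal entropy encountered along
  the ladder and a subsequent bisection of the crossing bracket is
  returned. If even the least-squares floor exceeds the target, the NNLS
  solution is returned flagged `converged=False`.

The scheme is deterministic for identical inputs, and entropy is
non-decreasing in the χ² target by construction of the ladder. When a curve
carries no per-point standard deviations a constant σ = 0.01 (1% of a
normalized amplitude) is assumed and logged; the synthetic generator always
attaches its exact noise model as weights.

Population summaries integrate ρ above and below the monomer/oligomer
cutoff D = 150 µm²/s and report the modal diffusivity (grid point of
maximal ρ) per population, with ties broken toward slower diffusion (larger
species). Because ρ weights amplitudes by residence time, slow species
dominate the reported fractions; the modal diffusivities are the robust
recovery targets. Modal values are quantized to the grid (±7% at N = 100
over six decades). Mode detection uses local maxima with prominence ≥5% of
the distribution maximum.

## Cross-β lattice models

Ideal strands are built by internal-coordinate (NeRF) chain extension with
standard trans-peptide bond lengths and angles (N–Cα 1.458 Å, Cα–C
1.525 Å, C–N 1.329 Å; ω = 180°), canonical β dihedrals φ = −139°,
ψ = +135° by default, carbonyl O placed anti to the next amide nitrogen,
and a Cβ pseudo-atom standing in for the side chain. The strand is
re-oriented into a canonical frame: chain axis along y, in-plane backbone
zigzag along x, smallest backbone extent along z. Consecutive Cα–Cα
distances come out at 3.80 Å and the heptapeptide Cα(1)–Cα(6) span at
17.4 Å — inside the 15–18 Å window characteristic of an extended
β-strand, which is what makes terminal-label contact experiments
conclusive about strand alignment (see below).

The lattice tiles this strand on two axes: strands every 5 Å along the
fibril axis (x) within a sheet, sheets every 10 Å along z; default 36
strands as 2 sheets × 18. Antiparallel alternation rotates odd strands
180° about the fibril axis. A per-strand twist about x (negative =
left-handed, the sense expected for L-amino-acid fibrils) is supported; the
magnitude in relaxed fibrils is not fixed by theory and is left
configurable. An `interdigitated` option register-shifts alternate sheets
by half the intra-sheet spacing along the fibril axis, the steric-zipper
arrangement; it is **off by default** because the model is backbone-only —
there are no side chains to interlock — and the unshifted stack keeps the
nearest inter-sheet distance at exactly the sheet spacing, which is the
property the starting-model RDF is validated against. Construction fails
loudly on intermolecular heavy-atom clashes (<1.5 Å) at zero twist.

**Alignment classification.** Distance-bounded polarization transfer sees
intermolecular ¹³C–¹³C contacts out to ~8 Å. With labels on the
N-terminal (residues 1–2) and C-terminal (residues 6–7) ends of the
hydrophobic tail, antiparallel neighbours produce N↔C ("cross") contacts
while parallel in-register neighbours produce like↔like contacts; the
intramolecular Cα(i)–Cα(i+5) span of 15–18 Å keeps same-strand label
pairs silent. The classifier counts both classes over all intermolecular
residue pairs below threshold and requires one class to exceed the other by
a margin factor (default 1.5); otherwise it returns `indeterminate`. It is
exact on built dimers and full lattices for twists up to at least
3°/strand in both topologies.

## Pair-distance metrics

`radial_distribution` histograms pair distances of any labeled point set,
with pair selection by label (intermolecular / intramolecular / all). Bins
are uniform and **centered on integer multiples of the bin width** (default
0.1 Å, enough to resolve 4.7 vs 5.0 Å), so exact lattice distances fall on
bin centers. Two normalizations: a raw distance density (counts per pair
per Å — appropriate for finite clusters, which have no bulk density; the
default, and the mode used for peak finding) and an ideal-gas g(r)
(counts over the expected shell count n·4πr²Δr/V, requiring a box volume),
under which homogeneous points give g ≈ 1 at mid-range. Raw counts are kept
alongside so mass conservation (Σ counts = number of selected pairs) is
exact.

**Characteristic spacings are measured between strand backbone centroids**
(equivalently, strand axes), not between individual backbone atoms. On a
perfectly regular lattice the atom-level pair histogram fragments into
sharp sub-spacing peaks — idealized hydrogen-bond-like O···N contacts at
2–4 Å between adjacent strands — which bury the packing spacings;
thermal averaging smears these in real trajectories but not in an ideal
model. The centroid-level RDF of the default untwisted lattice peaks at
exactly 5.0 Å, and at 10.0 Å when pairs are restricted to strands in
different sheets, matching the cross-β signature (~4.7 Å inter-strand,
~9–11 Å inter-sheet). The atom-level RDF remains available through the
same function by passing atom coordinates and strand labels.

Bragg conversion d = λ/(2 sin(2θ/2)) uses the Co-Kα wavelength
1.79026 Å by default; the 4.70 Å reflection corresponds to 2θ = 21.98°.

## Jarzynski PMF estimation

Each pulling trace records time (ps), the pulled particle position (nm) and
the spring force (kJ/mol/nm), with the protocol's spring constant
(default 1000 kJ/mol/nm²) and pull rate (default 0.01 nm/ps) attached.
Work is accumulated by trapezoidal integration of force along the **moving
spring reference** λ(t) = r₀ + v·t — the coordinate conjugate to a
moving-harmonic-constraint protocol, for which the Jarzynski equality holds
exactly. Integrating against the particle position instead (available as an
option for traces without a known rate) samples the work at first-crossing
times and demonstrably biases the exponential average low over steep
regions; the running-maximum resampling it uses still handles thermal
back-steps gracefully and warns when they exceed tolerance.

The PMF is ΔG(r) = −k_BT ln[(1/M) Σₘ e^(−Wₘ(r)/k_BT)] with
k_B = 0.0083145 kJ/mol/K, T = 300 K by default, evaluated with
log-sum-exp stabilization. Single trajectories return their work profile
exactly; the estimator is invariant under trajectory reordering and
balanced duplication, and obeys the Jensen bound ΔG ≤ ⟨W⟩ pointwise.

The dissociation energy is the mean PMF over a plateau window (default:
the last 10% of the range) minus the global PMF minimum. A slope test
(mean |dΔG/dr| above 5 kJ/mol/nm) flags non-plateaued profiles with a
warning rather than refusing a value. The stability ratio is the plain
quotient of fibril and oligomer dissociation energies.

## Synthetic data

The generators are pure functions of (specification, seed).

* **FCS curves**: forward-model evaluation at preset components plus
  multiplicative Gaussian noise with per-point σᵢ = noise·Gᵢ/√(i+1) —
  shorter correlator lags average more samples, hence the decay with lag
  index. The exact σ is attached to the curve as weights (floored at 10⁻⁵
  so noiseless curves remain usable as χ² weights). Presets: `alexa647`
  (single 330 µm²/s species), `slp1_like` (0.4 monomer at 200 µm²/s +
  0.6 oligomer at 2 µm²/s), `slp3_like` (0.6 at 200 + 0.4 at 20),
  `slp4_like` (one broad population near 100 µm²/s, straddling the
  cutoff). The presets encode the qualitative contrasts of interest — a
  ~10-fold oligomer-diffusivity separation between two- and three-charge
  variants, and a merged monomer/oligomer population for the weakly
  assembling variant; the absolute diffusivities are generator choices, not
  measured values. Default noise level 2%.
* **Pulling traces**: overdamped (Brownian) Langevin integration,
  x ← x + (F_spring − U′(x))Δt/ζ + √(2k_BTΔt/ζ)·η, of a particle on an
  analytic landscape dragged by the default spring and rate. Landscape
  forms: a smoothstep well-to-plateau rise (dissociation costs exactly the
  prescribed depth), a harmonic well, and a flat control. Presets
  `fibril_like` (30 kJ/mol) and `oligomer_like` (10 kJ/mol) fix a 3:1
  depth contrast. The synthetic reaction coordinate spans 2 nm (not the
  9 nm of a full fibril pull-out) with friction ζ = 100 kJ·ps/mol/nm² —
  sizes chosen so 50-trajectory ensembles integrate in seconds while
  keeping the dissipated work (≈ζvL) well below the landscape depth at the
  slow rate (0.002 nm/ps) used for recovery studies. The integrator
  refuses time steps with Δt·k_eff/ζ > 0.5.
* **Lattice perturbation**: seeded isotropic Gaussian displacement;
  σ = 0 is the identity. Atom-level noise averages out in strand
  centroids (σ/√n_atoms), so centroid RDF peaks are stable for σ ≤ 0.3 Å
  while first-shell distance spreads grow monotonically with σ.

What passing tests do **not** show about real data: the FCS noise model has
no afterpulsing, detector dead-time or photophysics beyond the optional
triplet factor; the Langevin pulls have no orthogonal degrees of freedom or
position-dependent friction, so they validate the estimator, not any force
field; and the ideal lattice has no side-chain packing, twist relaxation or
solvent, so RDF agreement there validates geometry and bookkeeping, not
energetics.

## Pipeline

`run_pipeline` executes simulate → fcs-fit → build-fibril → rdf → pmf from
a single validated configuration (unknown keys rejected by name, YAML
round-trip lossless). Every artifact is hashed (sha256) into the summary
manifest; reruns at the same seed are hash-identical. Stage failures are
logged and skip their dependents; resolved parameters are echoed to the log
as an audit trail. The default demo configuration (two FCS presets, the
36-strand lattice, 12 pulling traces per landscape at 0.002 nm/ps) runs in
well under a minute on one CPU.

## Known limitations

* MEM modal diffusivities are grid-quantized; sub-grid precision would need
  local refinement, which is out of scope.
* The χ²-target bisection returns the best feasible iterate; for extremely
  ill-conditioned weight profiles the reported entropy can sit slightly
  below the true constrained maximum (the monotonicity tests bound this).
* The alignment classifier assumes terminally labeled residues and a
  roughly in-register lattice; staggered registries would need a richer
  contact model.
* Jarzynski estimates from few, fast pulls are biased low by finite
  sampling of the work distribution (the Gaussian-limit test quantifies the
  σ²/2k_BT correction); the slow-rate defaults keep this within the stated
  recovery tolerances.
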