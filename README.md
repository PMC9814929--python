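# oligofib

Quantitative analysis tools for peptide self-assembly studies that link
headgroup charge and β-sheet propensity to oligomer size and fibrillization
yield. The package covers three measurement chains that are usually scattered
across ad-hoc scripts:

1. **FCS → size distributions.** Fluorescence correlation spectroscopy curves
   are modelled as a sum of 3D-diffusion components,

   G(τ) = Σᵢ αᵢ (1 + τ/τ_{D,i})⁻¹ (1 + τ/(γ²τ_{D,i}))⁻¹ᐟ²,

   and inverted with the **maximum-entropy method (MEM)**: among all
   quasi-continuous distributions over a log-spaced τ_D grid whose forward
   model fits the curve to a prescribed χ², the one maximizing the
   Shannon–Jaynes entropy S = −Σ ρⱼ ln ρⱼ (with
   ρⱼ = αⱼτ_{D,j} / Σᵢ αᵢτ_{D,i}) is selected — the broadest distribution the
   data allow. Diffusion times convert to diffusion coefficients through the
   calibrated focal volume, D = w²ₓᵧ/(4τ_D), and the distribution is split
   into monomer (D > 150 µm²/s) and oligomer (D < 150 µm²/s) populations.

2. **Cross-β fibril models → RDF/XRD cross-validation.** An idealized
   36-peptide antiparallel cross-β lattice (strands 5 Å apart within a
   β-sheet, sheets 10 Å apart, optional twist and inter-sheet register shift)
   is built from standard backbone geometry. Radial distribution functions of
   inter-strand distances expose the characteristic 5 / 10 Å packing
   spacings, and Bragg's law d = λ/(2 sin θ) links them to powder-diffraction
   reflections (Co-Kα, λ = 1.79026 Å). A contact-based classifier
   reproduces the ssNMR logic that discriminates parallel from antiparallel
   strand alignment from ≲8 Å intermolecular contacts between terminally
   labeled residues.

3. **Steered pulling → dissociation energies.** Work accumulated while
   dragging one peptide out of an aggregate is combined across trajectories
   with the **Jarzynski equality**,

   ΔG(r) = −k_BT ln ⟨exp(−W(r)/k_BT)⟩,

   to give the potential of mean force; the plateau height above the minimum
   is the dissociation energy ΔG_d, and the fibril/oligomer ratio
   ΔG_d/ΔG_d′ quantifies the relative stability of the two states.

A seeded synthetic-data module generates every input the chains consume
(noisy multi-component FCS curves, overdamped-Langevin pulling traces on
prescribed landscapes, thermally perturbed lattices), so the full pipeline is
exercisable and testable without any experimental data.

## Worked example

```bash
python examples/fcs_mem_size_distributions.py
```

```
slp1_like: monomer fraction 0.01, oligomer fraction 0.99, modal D oligomer 1.96 um^2/s (entropy 0.83, chi^2 154)
slp3_like: monomer fraction 0.12, oligomer fraction 0.88, modal D oligomer 20.98 um^2/s (entropy 1.73, chi^2 128)

oligomer diffusivity ratio (3 charges / 2 charges): 10.7x
```

The two presets emulate peptides with two vs. three charged headgroup
residues. MEM inversion recovers each generator's slow (oligomer) component
at its modal diffusivity — 1.96 vs. 20.98 µm²/s — reproducing the ~10-fold
size contrast between weakly and strongly charged variants. Note that the
fractions are detection probabilities ρ (amplitude-weighted by residence
time), so slow species dominate them even at moderate amplitude.

The other examples follow the same pattern:

* `examples/focal_volume_calibration.py` — fits the reference-dye curve and
  returns w_xy = 299.9 nm.
* `examples/fibril_lattice_and_rdf.py` — builds the 36-strand lattice,
  classifies it antiparallel from 272 labeled contacts, and finds RDF peaks
  at 5.0 and 10.0 Å.
* `examples/pulling_pmf_stability.py` — recovers ΔG_d = 29.0 and
  ΔG_d′ = 9.2 kJ/mol from 25 pulling trajectories each (prescribed depths
  30 and 10), a stability ratio of 3.15.

## Command line

A thin CLI wraps the same functions:

```bash
oligofib demo --seed 1 --out demo_run          # full synthetic pipeline
oligofib simulate fcs --preset slp1_like --seed 2 --out curve.csv
oligofib fcs-fit --input curve.csv --gamma 6 --grid-n 100 --cutoff-d 150
oligofib build-fibril --n 36 --intra 5 --inter 10 --antiparallel --out fibril.pdb
oligofib rdf --pdb fibril.pdb --bin 0.1 --rmax 20
oligofib pmf --traces 'demo_run/pull_fibril_like_*.xvg' --temp 300
```

`oligofib demo` writes per-stage artifacts plus `summary.json` (with a
sha256 manifest — reruns at the same seed are hash-identical) and a
human-readable `report.txt`.

## Layout

```
src/oligofib/
  fcs.py        FCS forward model, triplet correction, calibration
  mem.py        maximum-entropy inversion and population summaries
  fibril.py     ideal strand + cross-beta lattice builder, alignment classifier
  metrics.py    RDF, peak detection, Bragg 2θ↔d conversion
  pmf.py        work accumulation, Jarzynski PMF, dissociation energies
  synthetic.py  seeded generators for curves, pulling traces, perturbed lattices
  pipeline.py   stage orchestration, YAML config, manifest hashing
  io.py         correlation CSV / XVG / PDB / JSON readers and writers
  cli.py        click-based command line
```

See `docs/methods.md` for the models, parameter choices and limitations.
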