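# hexbind

Analysis pipeline for insulin-hexamer / small-ligand studies: it
classifies the conformational state of hexamer crystal structures,
assigns phenolic ligands (phenol, serotonin, dopamine) to their binding
sites, estimates binding free energies from molecular-simulation output
(thermodynamic integration and umbrella sampling), and fits
chromophore-reported titration curves with the Hill model.  A
synthetic-data module generates every input the pipeline consumes, so
the whole analysis runs and is tested without any structure downloads or
simulation engines.

## Background

Zinc-insulin hexamers occur in three conformational families that differ
in the fold of the B-chain N-terminus: **T** (B1–B6 extended, followed
by a B7–B10 type II′ β-turn into the invariant B9–B19 helix), **R**
(one continuous B1–B19 helix) and **Rf** (helix from B3, with B1–B2
frayed).  Hexamer states combine six monomer labels — T₆, T₃Rf₃, T₃R₃,
R₆.  The octahedral Zn²⁺ shell (three His B10 imidazoles + three
waters) marks the T-state; a tetrahedral shell with an axial anion
(e.g. Cl⁻) marks Rf/R.  Phenolic ligands bind the internal **site I**
pocket (anchored by hydrogen bonds to the Cys A6 carbonyl and Cys A11
amide) and the surface **site III** between three-fold-related dimers
(a Tyr A14 / Leu A13 hydrophobic clamp with Glu A17 hydrogen bonds).

The package implements three quantitative stages around these
structures:

1. **Geometric classification** — per-monomer T/Rf/R assignment from
   backbone (φ, ψ) windows, hexamer-state labelling, Zn²⁺ coordination
   geometry, hydrogen-bond / π-contact detection, contact-fingerprint
   ligand-site assignment, and Kabsch superposition r.m.s.d.
2. **Binding free energies** — thermodynamic integration
   ΔG = ∫₀¹ ⟨∂U/∂λ⟩ dλ (trapezoid, with SEM propagation) and the
   umbrella-sampling route: WHAM-unbiased potential of mean force W(x),
   well depth W₀, then

       ΔG_b° = W₀ + ΔG_symm + ΔG_vol,   K_d = exp(ΔG_b° / RT)

   with ΔG_symm = −RT ln n for n equivalent sites (override available)
   and ΔG_vol = −RT ln(v_bound / V₀), V₀ = 1660.539 Å³ (1 M standard
   state); the bound volume comes from the Gaussian covariance
   estimator v = (2πe)^{3/2}|Σ|^{1/2}.
3. **Titration analysis** — difference absorbance at 444 nm of the
   R-state-specific 4H3N chromophore versus ligand concentration, fitted
   per replicate with the one-site Hill-slope model
   ΔA = B_max·cʰ/(K_dʰ + cʰ) and summarised as mean ± SD.

## Worked example

Build the serotonin-loaded T₃R₃ hexamer test article and classify it:

```sh
$ hexbind simulate fixture spec.yaml -o insser.pdb   # see YAML below
$ hexbind classify insser.pdb
monomer  chains  state  helix_start
AB       A/B     T      9
CD       C/D     T      9
EF       E/F     T      9
GH       G/H     R      2
IJ       I/J     R      2
KL       K/L     R      2
# hexamer_state  T3R3

$ hexbind zinc insser.pdb
zn  coordination  geometry     axial
0   4             tetrahedral  CL
1   4             tetrahedral  CL

$ hexbind sites insser.pdb | cut -f1,2
ligand     site
serotonin  I
serotonin  I
serotonin  I
serotonin  III
serotonin  III
serotonin  III
```

Three monomers carry a continuous B-chain helix from B2 (R state, the
B1 torsion being undefined at a chain start), three have the extended
B1–B6 head with the helix starting at B9 (T state): a T₃R₃ hexamer with
six serotonins — three in the internal site I, three at surface site
III — and two tetrahedral Zn²⁺ ions with axial chloride.  The fixture
YAML:

```yaml
monomer_states: [T, T, T, R, R, R]
ligands:
  - {name: serotonin, site: I, monomer: 3}
  - {name: serotonin, site: I, monomer: 4}
  - {name: serotonin, site: I, monomer: 5}
  - {name: serotonin, site: III, monomer: 0}
  - {name: serotonin, site: III, monomer: 1}
  - {name: serotonin, site: III, monomer: 2}
zinc:
  - {geometry: tetrahedral, axial: CL}
  - {geometry: tetrahedral, axial: CL}
seed: 1
```

Free-energy arithmetic — a site III decomposition and a ΔG→K_d
conversion at 300 K:

```sh
$ hexbind decompose --w0 -1.83 --symm -0.36 --vol 1.38
{
  "W0_kcal_mol": -1.83,
  "dG_symm_kcal_mol": -0.36,
  "dG_vol_kcal_mol": 1.38,
  "dG_total_kcal_mol": -0.81,
  "Kd_M": 0.2569957703064485,
  ...
}
$ hexbind kd --dg -4.49
{
  "dG_kcal_mol": -4.49,
  "Kd_M": 0.0005359149106156777,
  "temperature_K": 300.0
}
```

A well depth of −1.83 kcal/mol, a three-site symmetry term of −0.36 and
a volume-entropy penalty of +1.38 combine to ΔG_b° = −0.81 kcal/mol,
i.e. K_d ≈ 0.26 M (weak surface binding); a site I affinity of
−4.49 kcal/mol corresponds to K_d ≈ 5.4 × 10⁻⁴ M.

Titration round trip — simulate four noisy replicates at phenol-like
Hill parameters and refit them:

```sh
$ hexbind simulate titration --kd 0.86 --bmax 0.17 --h 2.22 \
      --replicates 4 --seed 1 -o curves.csv
$ hexbind fit-hill curves.csv
# Kd 0.887 ± 0.047 mM | Bmax 0.173 ± 0.002 | h 2.18 ± 0.06 (n=4)
```

The mean fitted K_d (0.887 mM) recovers the generating 0.86 mM within
the replicate scatter.

## Library layout

| module | contents |
| --- | --- |
| `hexbind.io` | PDB/mmCIF reading (gemmi), altloc policy, PDB writing |
| `hexbind.monomers` | A/B-chain pairing via the A20–B19 disulfide, (φ, ψ) |
| `hexbind.states` | T/Rf/R monomer and hexamer-state classification |
| `hexbind.sites` | Zn²⁺ geometry, H-bond/π contacts, site fingerprints |
| `hexbind.superpose` | Kabsch superposition and fixed-frame r.m.s.d. |
| `hexbind.free_energy` | TI, WHAM, W₀, standard-state corrections, K_d |
| `hexbind.titration` | Hill model, per-replicate fits, summaries |
| `hexbind.synthetic` | seeded generators for every pipeline input |
| `hexbind.tables` | TSV/CSV readers and writers |
| `hexbind.cli` | `hexbind` command-line application |

See `docs/methods.md` for the models, parameter defaults and the scope
of the synthetic generators.
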