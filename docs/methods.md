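# Methods

## Conformational-state classification

A residue is called helical when its backbone torsions fall in the
α-basin window φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°], and a helical run
must contain at least four consecutive helical residues.  The state of
an insulin monomer is read off the longest helical run of its B-chain
that ends at or beyond B17:

| helix start | label | rationale |
| --- | --- | --- |
| B1–B2 | R | full B1–B19 helix (φ of B1 is undefined at a chain start, so an R helix is detected from B2) |
| B3–B4 | Rf | frayed N-terminus, helix from B3 |
| ≥ B7 with non-helical B1–B6 | T | extended N-terminus ahead of the invariant B9–B19 helix |
| anything else | undetermined | flagged, never silently binned |

Helix starts at B5–B6 are deliberately left `undetermined` rather than
forced into Rf or T.  Hexamer labels require all six monomers
determined: six T → T6, six R → R6, 3T+3R → T3R3, 3T+3Rf → T3Rf3,
otherwise `mixed`.  All criteria are internal (torsions, distances), so
every classification is invariant under rigid motion of the structure;
the tests assert this property explicitly.

Monomers are assembled by pairing each 21-residue chain (A) with the
30-residue chain (B) whose Cys B19 Sγ is nearest its Cys A20 Sγ, under
a 3.0 Å S–S cutoff.  Chains whose author numbering does not start at 1
are renumbered to the canonical A1..A21 / B1..B30 scheme by offset.

## Zinc coordination

Ligand atoms are N/O/S/halide atoms within 2.8 Å of a zinc.  The
geometry label uses the coordination number together with inter-ligand
angle statistics at the metal: four ligands with mean angle within 15°
of 109.47° → `tetrahedral`; five or six ligands whose pairwise angles
all lie within 20° of 90° or 180° → `octahedral`; anything else →
`other`.  The axial species is the unique non-His ligand anti-aligned
(cosine < −0.5) with the vector sum of the His-nitrogen directions —
a frame-independent formulation of "the non-His ligand on the
three-fold axis".  The labels are stable under ±0.05 Å coordinate
jitter (tested over seeded replicates).

## Contacts and ligand-site assignment

Hydrogen bonds use the heavy-atom distance criterion only: N/O pairs
within 3.6 Å, excluding covalently bonded and 1–3 pairs (bond graph
inferred from inter-atomic distances below 1.9 Å).  No angle term is
applied by default, since the reference distances this cutoff is meant
to capture (2.4–3.6 Å) are reported without angles.  π-contacts are
N/O atoms within 3.8 Å of a 5- or 6-membered aromatic ring centroid;
rings come from per-residue-name templates (Tyr/Phe/His/Trp and the
ligand residues), not from on-the-fly perception.  Contact lists are
monotone in the cutoff by construction.

Ligand poses are assigned by contact fingerprints over canonical
residues within 4.0 Å of any ligand heavy atom:

* site I — {A6, A9, A11, B5, B17, B21}
* site II — {B9, B12, B16, B17}
* site III — {A13, A14, A17, B22}

The site with the highest matched fraction wins provided at least half
the fingerprint is hit; ties are left unassigned.  The 50% threshold
tolerates missing side-chain atoms in real depositions.

## Superposition

`superpose` is the SVD form of the Kabsch algorithm restricted to
proper rotations (reflection branch corrected by the determinant sign),
returning rotation, translation and the post-fit r.m.s.d.; it is tested
against a brute-force numerical minimiser over the six rigid degrees of
freedom.  `rmsd_fixed` evaluates r.m.s.d. without fitting, the form
used for per-ligand displacement series over the frames of a
multi-model file.

## Free energies

**Thermodynamic integration.** ΔG = ∫₀¹ ⟨∂U/∂λ⟩ dλ by trapezoidal
quadrature (exact for integrands piecewise-linear on the λ-grid); the
uncertainty propagates the per-point SEMs through the trapezoid
weights.  Gas constant R = 1.98720 × 10⁻³ kcal/(mol·K); default
T = 300 K, giving RT = 0.59616 kcal/mol.

**WHAM.** For windows i with bias U_i(x) = ½k_i(x−c_i)², samples are
pooled into equal-width bins spanning the sampled range (default 100)
and the window shifts f_i are iterated through the standard
self-consistent equations

    p_j = M_j / Σ_i N_i exp[(f_i − U_i(x_j)) / RT]
    f_i = −RT ln Σ_j p_j exp(−U_i(x_j) / RT)

until the maximum relative change in f is below 1e-8 (at most 1e5
iterations; non-convergence raises with the last residual).  The PMF
−RT ln p_j is referenced so the mean over a user-specified unbound
plateau range is zero (minimum-to-zero when no plateau is given).
Empty bins interior to the sampled range are returned as NaN and
flagged.  Per-bin uncertainty is the Poisson counting estimate
RT/√M_j, which halves by √2 exactly when the sample count doubles.
The solver is verified against an independent plain-Python fixed-point
iteration on a small two-window problem (shifts agree to 1e-10).

**Standard-state corrections.** W₀ is the PMF minimum over the bound
range minus the plateau mean.  ΔG_symm defaults to −RT ln n for n
equivalent symmetric sites, with a verbatim override for workflows
whose symmetry estimate comes from elsewhere (the reference table
prints −0.36 kcal/mol for three sites, which is not −RT ln 3; the
override reproduces that arithmetic exactly).  ΔG_vol =
−RT ln(v_bound/V₀) with V₀ = 1660.539 Å³ per molecule at 1 M; the
bound volume estimator is the Gaussian covariance volume
v = (2πe)^{3/2}|Σ|^{1/2}, with a configuration path to supply v_bound
directly when an external estimate is preferred.  ΔG_b° is the exact
sum of the three components, K_d = exp(ΔG_b°/RT), component
uncertainties combine in quadrature and the K_d uncertainty uses the
first-order delta method.

## Titration analysis

ΔA(c) = B_max·cʰ/(K_dʰ + cʰ) — the standard "one-site specific binding
with a Hill slope" parameterisation, with concentrations in mM taken as
dispensed (no ligand-depletion correction).  Each replicate curve is
fitted by bounded least squares (K_d ∈ (0, 100] mM, B_max ∈ [0, 1] AU,
h ∈ (0, 20]; bounds prevent divergence on flat curves), auto-initialised
at K_d = concentration at half-maximal observed ΔA, B_max = max ΔA,
h = 1.  Standard errors come from the Gauss–Newton covariance
(JᵀJ)⁻¹·RSS/(n−3).  A fit is flagged unconverged when the optimiser
fails or when B_max < 1e-4 AU, where K_d and h are unidentifiable.
Replicate summaries are per-parameter means and SDs (n−1 denominator)
over converged fits, matching the per-curve-fit-then-summarise reading
of the experimental protocol.  `difference_absorbance` evaluates
A_bound − A_free at 444 nm with linear interpolation between tabulated
wavelengths.

## Synthetic data: what it emulates and what it does not

The generators provide seeded, bit-reproducible inputs paired with
their analytic ground truth; every downstream estimator has a test
consuming exactly that pairing.

**Hexamer fixtures** are geometric test articles, not physical models.
Backbones are built by sequential torsion geometry (N–CA 1.458 Å,
CA–C 1.525 Å, C–N 1.329 Å; trans peptides) from per-state recipes:
helix (−57°, −47°), extended (−120°, +120°), and type II′ β-turn
torsions at B7–B8 of the T recipe.  The A-chain uses the two-helix
insulin fold (helix A1–A8, extended A9–A11 linker, helix A12–A21): the
linker frees the A6 and A11 carbonyls that anchor site I ligands — in a
uniform ideal helix those oxygens are occupied by the helix's own
i→i+4 hydrogen bonds and the crystallographic anchor distances cannot
be met.  Six monomers are arranged in two three-fold-related trimers;
monomer placement is deliberately wider than a real hexamer so that
classification tests are about geometry criteria, not packing.  Only
the side-chain atoms the classifiers read are present (Cys A20/B19
sulfurs for pairing, His B10 Nε2 for the Zn shell, His B5 Nε2 for the
site I π-contact, the site I/III fingerprint side chains, a full Tyr
A14 ring); Leu A13's terminal carbon is placed across the Tyr A14 ring
face so the site III clamp has a geometrically consistent slot.  Zinc
shells are ideal polyhedra at 2.1 Å (axial species at 2.2 Å).  Ligands
are docked as rigid aromatic scaffolds satisfying the requested anchor
distances exactly (serotonin O5 2.42 Å from the Cys A6 carbonyl;
His B5 Nε2 3.50 Å from the pyrrole centroid; site III hydroxyl 3.2 Å
from Glu A17 Oε1 with the ring between Tyr A14 and Leu A13), with the
aminoethyl tail built flexibly through clearance-aware multi-start
least squares; any non-bonded approach below 1.8 Å is an error.
Docking restarts draw from a fixed internal random stream, so the
placed geometry is identical across fixture seeds and the seed controls
only a final uniform jitter (default amplitude 0.002 Å) — two seeds
give the same atoms with coordinates differing well below any
classification tolerance.  Consequences for interpretation: passing
classification tests demonstrates correctness of the torsion windows,
coordination rules and fingerprint logic on ideal geometry; they say
nothing about robustness to real crystallographic noise beyond the
±0.05 Å jitter tests, alternate rotamers, or missing density.

**Umbrella windows** draw exact Boltzmann samples from
p(x) ∝ exp(−[U(x) + ½k(x−c)²]/RT) by inverse-CDF on an 8001-point grid
(padded by 6√(RT/k) around the centers; tabulated PMFs are sampled only
on their support, and a spring too weak to confine the density inside
the grid is an error).  Available forms: harmonic (½a(x−x₀)², for PMF
recovery tests), Gaussian well (−D·exp(−(x−x₀)²/2σ²), a bound well
decaying to a flat plateau — the full binding-chain benchmark, with
analytic W₀ = −D), double well, and tabulated.  These are ideal
uncorrelated samples; real simulation time series carry
autocorrelation, so the counting uncertainties here are a best case.

**λ-series**: ⟨∂U/∂λ⟩ = a + bλ + c·sin(πλ) with analytic integral
a + b/2 + 2c/π and optional Gaussian noise per point.

**Titration curves**: Hill model plus additive Gaussian noise on ΔA
(default SD 0.005 AU, about 3% of the phenol-regime B_max); replicate i
uses sub-seed seed + i, so replicate sets are stable under extension.

**Bound-state clouds**: multivariate Gaussian positions with the
analytic effective volume (2πe)^{3/2}|Σ|^{1/2} returned alongside.

## Problem sizes used in tests and the acceptance script

Hill-fit recovery uses 50 replicates × 12 log-spaced concentrations per
regime.  WHAM accuracy uses 17 windows × 20 000 samples (harmonic
recovery) and 31 windows × 50 000 samples (full chain to K_d); the
two-window oracle comparison uses 800 samples and 10 bins.  Volume and
window-width closed forms use 10⁵ samples.  These sizes put the
stochastic checks comfortably inside their tolerances (0.1 kcal/mol for
the PMF, 10% for the chained K_d, 2 SEM for titration K_d) while the
whole suite stays fast.

## Known limitations

* No molecular dynamics, force-field evaluation, or charge derivation:
  the package analyses simulation *output* formats, it does not produce
  them.
* WHAM only (no MBAR); trapezoid TI only (Gauss–Legendre grids can be
  integrated externally and fed in as a λ-series).
* H-bond detection is distance-only by default; angle screening is not
  implemented.
* Site assignment trusts residue-name recognition for ligands (IPH/PHN,
  SRO/5HT, LDP, hetero ARG); exotic ligand naming requires extending
  the map.
* The r.m.s.d. of structures against published comparator depositions
  depends on unstated atom selections and is out of scope; `superpose`
  provides the primitive.
* Mixed hexamers (e.g. 4T+2R) are reported as `mixed`; whether such
  assemblies are physically meaningful for real data is an open
  question the classifier does not resolve.
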