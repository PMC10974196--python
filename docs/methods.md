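# Methods

## Model

The acid dissociation of a monocarboxylic aromatic acid is treated as the
explicit reaction with hydroxide in water,

RCO2H·(H2O)2 + OH⁻·(H2O)2 ⇌ RCO2⁻·(H2O)2 + H2O·(H2O)2,

all species solvated (SMD continuum in the intended engine settings) and
each carrying two explicit water molecules at the reaction center. The
reaction free energy is the difference of the four per-species Gibbs free
energies, ΔG_dep = G_base + G_water − G_hydroxide − G_acid, converted from
Hartree with 1 Eh = 2 625 499.6 J/mol, and mapped to acidity by

pKa = ΔG_dep / (2.302·R·T) + 15.74,

with R = 8.31446 J mol⁻¹ K⁻¹ and T = 298.15 K. The additive constant is
the pKa of water at that temperature, so ΔG_dep = 0 corresponds to an acid
exactly as strong as water; one pKa unit corresponds to
2.302·R·T ≈ 5 706.6 J/mol. The method's deliberate austerity — no
empirical correction factors, no fitted coefficients, no experimental H⁺
free energy — is part of the model: reliability is assessed afterwards,
statistically, against experimental reference values.

Assumptions worth keeping in mind: the two explicit waters stand in for
the entire first solvation shell; the four-species reaction implies equal
standard states on both sides (no concentration correction is applied);
and the conversion constant 15.74 is valid at 298.15 K only — requesting
another temperature triggers a warning rather than a silent extrapolation.

## Numerical constants and the 2.302 choice

The decadic factor is carried as the conventionally printed 2.302 rather
than ln 10 = 2.302585…; across this panel's pKa range the two differ by
less than 0.005 pKa units, below the 0.01 reporting grain. Every
conversion function accepts `log10_factor=math.log(10)` for the exact
value. All constants (`GAS_CONSTANT`, `HARTREE_TO_J_PER_MOL`,
`LOG10_FACTOR`, `PKA_WATER`) are exported.

## Cluster construction

Solute coordinates come from RDKit ETKDGv3 distance-geometry embedding
with a fixed seed (default 1255, overridable) followed by an MMFF94
relaxation; the same compound and seed give bitwise-identical
coordinates. The relaxation reproduces the expected carboxyl rotamer:
coplanar with the ring for unhindered acids, twisted well out of plane
(> 45°) for the 2,6-dimethyl compound, where both ortho positions are
occupied. The conjugate base reuses the acid geometry minus the acidic
hydrogen (charge −1); no re-relaxation is attempted because the engine is
expected to optimize anyway.

Water placement is purely geometric, with monomer geometry
r(OH) = 0.9572 Å and ∠HOH = 104.52°, hydrogen-bond contacts of 1.85 Å and
linear donor–H···acceptor arrangements — a typical neutral H-bond prior
for a starting structure. For the acid, one water accepts from the acidic
H (contact *b*) and one donates to the carbonyl O (contact *a*); for the
base, each water donates one H to one carboxylate oxygen (contacts *a′*,
*a″*). The two waters are placed independently (they do not bridge each
other); directions are derived exclusively from solute atoms, which makes
placement rigid-transform covariant. The compound-independent
OH⁻·(H2O)2 and (H2O)3 species are fixed literal templates: a chain
arrangement with both waters donating to the hydroxide oxygen, and a
cyclic trimer with 2.8 Å O···O edges. Only monocarboxylic acids are
accepted; polyacids raise immediately.

## Engine contract

An engine optimizes a cluster under `QMSettings` (functional label, basis
default 6-311+G(d,p), solvation default SMD/water, temperature default
298.15 K) and returns a `QMResult`: final structure, Gibbs free energy in
Hartree, signed harmonic wavenumbers, a convergence flag and the wall time
in minutes. Structures whose frequency spectrum contains any value ≤ 0
fail the true-minimum check and are excluded from the thermochemistry
(zero is conservatively treated as non-minimum). The Gaussian-dialect
parser takes the *last* "Sum of electronic and thermal Free Energies"
line and the last orientation block, since multi-step logs re-print both;
absent fields are reported absent, truncated logs yield
`converged=False` with partial data, and line-ending style or trailing
whitespace does not matter.

## The mock engine as synthetic-data generator

The mock engine realizes a prescribed pKa table as species free energies
by inverting the pKa equation. Gauge freedom is fixed by pinning
G(acid) = −650 Eh for every compound, and per-functional
G(OH⁻·(H2O)2) and G((H2O)3) near −228.5/−229.1 Eh (offset 0.001 Eh per
functional so functionals are distinguishable); G(base) then absorbs
ΔG_dep. Frequencies are synthetic all-positive spectra of the correct
3N−6 count (an explicit list of species can be given one imaginary mode
to exercise the exclusion path), and wall times default to per-functional
constants whose acid+base pair sums equal the benchmark's average costs
(52, 35, 30, 31, 49, 51 minutes). Two cells of the built-in table are
missing — their printed source values are corrupt — and are treated as
unavailable species, so those functionals' statistics run over ten
compounds.

What this emulates, and what it does not: the mock reproduces the
*bookkeeping* of a DFT benchmark (energies, spectra, timings, failure
modes) exactly, but its geometries are the initial templates, not
optimized structures. Passing tests therefore demonstrate the pipeline's
arithmetic, filtering, statistics and I/O on realistic magnitudes; they
say nothing about any functional's actual accuracy, which requires real
engine logs through the log-ingestion path.

## Geometry diagnostics

All metrics are selected by role labels, never atom indices, and are
invariant under rigid transforms and atom reordering. For role-free
structures (parsed logs), roles are inferred from connectivity with a
covalent-radius cutoff scaled by 1.2: the carboxyl carbon is the carbon
bonded to two non-water oxygens, waters are oxygens bonded to exactly two
hydrogens, protonation state decides acid vs carboxylate.

The carboxyl–ring twist is the ortho-C → ipso-C → carboxyl-C → carboxyl-O
torsion folded into [0°, 90°] (f(θ) = f(−θ) = f(180° − θ)); the ortho
carbon is the lower-index one, which the folding makes immaterial, and a
best-fit-plane variant is available via `method="plane"`. Acid/base pair
averages use absolute (folded) angles. For the base, the two carboxylate
oxygens are symmetric; water↔oxygen contact assignment minimizes the
total contact length, ties broken by ascending atom index. Δ_length
reports signed per-label differences against a reference functional
(default CAM-B3LYP, the most reliable one), flagging |Δ| > 0.25 Å — the
empirical envelope of inter-functional scatter — as outliers.

## Statistics and reporting

MAE, signed ΔpKa (with the worst-predicted compound exposed), and
ordinary least squares of calculated on reference pKa (slope, intercept,
Pearson r, r²; orientation switchable) are computed at full precision and
rounded only at rendering (two decimals, the conventional pKa grain). The
MAE row of any rendered table is recomputed from that table's own columns,
never copied in, so reports are self-consistent by construction. No
outliers are excluded by default. Computational cost is the mean over
compounds of the acid+base pair wall-time sum, per functional.

## Pipeline behaviour

Hydroxide and water-trimer energies are computed once per functional and
reused across compounds. Per-species failures (engine errors,
non-convergence, imaginary frequencies) are logged with reasons and leave
the affected table cells empty — the run continues, since per-compound
discrepancies are themselves of interest; only a run in which *every*
species fails raises. Identical configurations produce byte-identical
reports (no timestamps; sorted keys).

## Problem sizes

The default suite and the acceptance script run the full panel — 11
compounds × 6 functionals, 24 distinct clusters of 9–24 atoms, 268 mock
engine evaluations — which completes in a few seconds; regression
property checks use 8–31-point synthetic data. These sizes exercise every
code path at full fidelity because the mock's cost is independent of
basis-set size.

## Known limitations

- No conformer search and no more than two explicit waters; the initial
  carboxyl rotamer is the single MMFF94 guess.
- Substituent position maps are carried for the built-in panel but not
  re-derived from SMILES for user CSV compounds.
- The regression statistics printed for the built-in mock run describe
  the stored benchmark table; published fits based on other point sets or
  weightings will differ.
- Real-engine adapters (Psi4, xtb, live Gaussian) are out of scope; the
  contract plus the log-directory engine is the integration surface.
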