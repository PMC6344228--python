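# Methods

`kinland` compares cyclin-free and cyclin-bound CDK1/CDK2 along two axes:
conformational metrics computed from heavy-atom coordinates, and binding
thermodynamics fitted from titration-type experiments. This note records
the models, the parameters that matter, the numerical choices, and what
the synthetic data do and do not establish.

## Structural model and element annotation

Coordinates are read with gemmi (PDB/mmCIF), author numbering preserved.
Standard filtering keeps heavy atoms only and collapses alternate
locations to the highest-occupancy conformer (ties: lexicographically
first altloc). All metrics run on the kinase chain alone; waters, ligands
and partner chains (cyclin, Cks) are excluded unless explicitly selected.
When a file holds several copies, the first kinase chain by chain-id sort
order is analysed — copies are never averaged.

An `ElementMap` partitions the chain into named inclusive residue ranges.
CDK1 defaults: P loop 11–17, hinge 81–84 (the E81/L83 main-chain
hydrogen-bonding stretch), activation segment 146–173 (DFG→APE), C helix
46–56, gatekeeper F80, P-loop tyrosine Y15, activation-segment glutamate
E163. CDK2 values follow via the one-residue offset that appears between
the hinge and the catalytic loop (DFG D145, E162). The lobe split is a
design choice the literature leaves open: N-lobe = chain start to the
residue before the hinge, C-lobe = after the hinge to the chain end; both
are config-overridable, as are the spans of the β-sheet base
([4–12] ∪ [66–80]) and the extended hinge, which no primary source pins
down to exact residues. Spine residue lists follow the standard
protein-kinase hydrophobic-spine assignment (R-spine: β4 leucine, αC L55,
DFG phenylalanine, HRD histidine; C-spine: V18/A31 adenine sandwich, β7
triplet, αF methionine). The HRD histidine position is inferred from the
offset (CDK1 H126/CDK2 H125) and shipped as overridable configuration.

## Conformational metrics

**Superposition.** Kinase chains are paired by global sequence alignment
(match +1, mismatch 0, gap −1; Biopython `PairwiseAligner`), so shifted
author numbering cannot mis-pair residues; only pairs with Cα atoms on
both sides are kept. The least-squares rigid transform is the Kabsch
solution via SVD with the reflection branch rejected (det R = +1 always).
The default atom set is one Cα per paired residue — the "global
superposition" convention, insensitive to side-chain disorder; an
all-heavy-atom variant matches atoms by name within paired residues.
Collinear point sets (second singular value < 1e−8 of the first) raise a
degenerate-geometry error rather than returning an arbitrary rotation.

**Contact census.** A contact is an unordered heavy-atom pair with one
atom in an N-lobe element and one in a C-lobe element at distance
strictly below the cutoff (default 4.0 Å; a pair at exactly the cutoff
does not count). Intra-lobe and intra-element pairs are never counted.
`lobe_vs_lobe` mode uses the whole lobes; `element_pairs` mode restricts
to the four interface elements (hinge and activation segment on the
C-lobe side, C helix and β-sheet base on the N-lobe side). Neighbour
search uses a k-d tree but is required — and tested — to equal the
all-pairs double loop exactly.

**Spines.** For each consecutive pair of spine residues the metric is the
minimum distance between side-chain heavy atoms (backbone N/CA/C/O/OXT
excluded). A link is broken when the gap exceeds the threshold (default
4.5 Å, roughly the upper edge of van der Waals contact between aliphatic
carbons); a residue with no side-chain heavy atoms breaks its links. The
spine is assembled iff no link is broken.

**P-loop tyrosine pose.** The classifier measures two distances from the
tyrosine hydroxyl: to the activation-segment glutamate carboxylate
(OE1/OE2 minimum) and to a ligand-independent ATP-pocket reference — the
centroid of the gatekeeper side chain plus the hinge Cα atoms, computable
for apo structures. The pose is "popped-out" when the hydroxyl sits
closer to the glutamate and within the coordination threshold (3.5 Å,
hydrogen-bond range); "tucked-in" when it sits closer to the pocket and
within 6 Å of the reference; otherwise indeterminate. Both thresholds are
parameters.

## Binding thermodynamics

**ITC forward model.** The one-set-of-sites isotherm. The default
schedule mirrors the standard protocol: 200 µL cell at 10 µM titrand,
100 µM titrant, one 0.5 µL priming injection then 19 × 2 µL, 30 °C. Each
injection of volume dV first expels the fraction dV/V0 of the pre-mixing
cell content (perfusion displacement), dilutes titrand and prior titrant,
adds fresh titrant, then re-equilibrates via the single-site quadratic
with site concentration n·[M]. Differential heat per injection is
ΔH·V0·(B_i − B_{i−1}(1 − dV/V0)) plus a constant dilution baseline, in
µcal. An independent bisection solver on free ligand cross-checks the
quadratic to 1e−10.

**ITC fit.** Nonlinear least squares (lmfit, Levenberg–Marquardt) over
(log10 Kd, ΔH, n, baseline); the priming injection is simulated but
excluded from the residuals, the universal treatment. n can be fixed at
its initial value (whether the original fits floated n is unknowable from
the outputs, so both modes are exposed). When the Wiseman c-value
(n·[M]/Kd) is below 1 or the fitted Kd exceeds half the total titrant
concentration probed, the isotherm no longer determines Kd and the result
is flagged as a lower bound, rendered "> limit" in tables and excluded
from fold arithmetic. Initialisation: n = 1, ΔH from the sign of the
largest heat × 5 kcal/mol, Kd at a tenth of the cell concentration —
all overridable; fits are deterministic given data and initialisation.

**Signatures and selectivity.** ΔG = RT ln Kd with R = 1.9872e−3
kcal/(mol·K), default T = 303.15 K; −TΔS = ΔG − ΔH, so the decomposition
is exact by construction. Selectivity is the plain Kd ratio with optional
reporting conventions (nearest ten, one significant figure) matching how
fold differences are quoted.

**Companion fits.** DSF melts use the Boltzmann sigmoid
F(T) = F_min + (F_max − F_min)/(1 + exp((Tm − T)/s)); the whole 25–95 °C
curve is fitted because the generator emulates a clean two-state melt
(instrument curves that roll over after the transition can be windowed).
ΔTm is the signed difference against the apo melt. SPR steady-state
responses fit R(C) = R_max·C/(Kd + C); a fitted Kd beyond half the top
concentration is flagged as unbounded by the data. Activity curves fit
Y = 1/(1 + 10^((logIC50 − x)·N)) with x = log10 concentration — the only
dimensionally consistent reading of the conventional printed form — so
Y = 0.5 at the IC50 for any slope; zero concentrations cannot enter the
log transform and are dropped.

## Synthetic data

Generators emulate the statistical structure of each experiment: the ITC
schedule above with i.i.d. Gaussian heat noise; 1 °C-step melts over
25–95 °C; an SPR four-fold dilution ladder (blank + ten steps to
12 500 nM); a 12-point 0–6 µM activity titration with two-fold dilutions.
Noise is additive Gaussian throughout, seeded via
`numpy.random.default_rng`; a fixed seed reproduces outputs
byte-identically, and every generator emits a truth record (sidecar
`<output>.truth.json` on disk).

Toy structures are two spatially separated blocks of alanine-like
5-heavy-atom residues with an exactly planted number of inter-lobe
contacts: each contact is a dedicated atom pair facing across the gap at
cutoff − 0.7 Å, bridges on a 6 Å lateral grid so every non-planted
inter-lobe pair stays ≥ 0.5 Å beyond the cutoff (verified against the
all-pairs oracle). Rigid copies apply a proper rotation + translation
with optional jitter whose parameter is the RMS atomic displacement in Å
(per-coordinate σ/√3), so a single-sided jittered copy superposes at
RMSD ≈ σ.

What the toys do not emulate: real packing density, secondary structure,
side-chain chemistry, crystallographic disorder, or instrument baselines
and drift. Passing tests therefore establish the correctness of the
counting, superposition and fitting machinery and of the end-to-end
plumbing — not that the shipped element-map calibration reproduces counts
on any particular deposited structure, which requires the real
coordinates as input.

## Problem sizes and determinism

Default test and acceptance sizes: toy structures of 1 200–2 000 atoms
per state; 100 random census fixtures of 10–500 atoms; 100 ITC replicates
at 2%-of-peak noise and 50 IC50 replicates at 2% noise; a 62 832-point
rotation grid for the superposition oracle. All Monte-Carlo assertions
use fixed seeds; pipeline reports are byte-identical for identical
config + seed (sorted JSON keys, 6-significant-figure values).

## Known limitations

* The element-map defaults for the β-sheet base, extended hinge and HRD
  histidine are reasoned configuration, not fitted calibration; analyses
  of deposited structures should treat them as starting points.
* The ITC model is strictly one-set-of-sites: no competitive,
  multi-site, or kinetic models, and no dilution-heat blank subtraction
  beyond the constant baseline.
* SPR analysis is steady-state only (no k_on/k_off), with no solvent or
  DMSO correction.
* At high c-values (tight binding relative to the cell concentration) a
  single noisy isotherm constrains Kd only loosely; replicate medians are
  the stable summary, as in practice.
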