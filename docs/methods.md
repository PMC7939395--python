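# Methods

This note documents the models, numerical choices, and synthetic-data design
behind `sas6screen`, and what the test suite does and does not demonstrate.

## Scientific setting

SAS-6 head domains dimerize by inserting the tip of the β6-β7 loop — a single
apolar residue — into a hydrophobic pocket of the partner domain, with
backbone hydrogen bonds between the loop and the α1-α2 rim of the pocket
completing the interface. Because this interaction is weak (tens of μM) and
geometrically simple, it is a tractable target for low-molecular-weight
inhibitors: a ligand only needs to occupy the pocket and satisfy one or two
rim hydrogen bonds to compete with the loop. The package covers the four
computational stages of that campaign: pharmacophore screening, NMR
chemical-shift-perturbation (CSP) read-out, titration affinity estimation,
and trajectory-based pose analysis.

## Structure handling

PDB IO is a purpose-built fixed-column reader/writer rather than a wrapper
around a general parser, because the pipeline's contracts require (a) parse
errors that name the offending line, (b) author residue numbering preserved
exactly, and (c) value-stable round-trips — the CSP mapper writes Δδ into the
B-factor column and the annotation must survive re-reading. Alternate
locations keep the highest-occupancy copy (ties to first in file); insertion
codes fold into residue identity; "heavy atom" means element ≠ H/D
everywhere.

Superposition is closed-form least-squares (Kabsch via SVD, determinant
corrected to +1). For collinear point sets the SVD still returns the optimal
proper rotation about the determined axes. Cross-species Cα RMSD pairs
residues by global sequence alignment (BLOSUM62, gap open −11 / extend −1,
free end gaps) of CA-bearing residues; the alignment protocol behind the
published comparison numbers is not recoverable, so those numbers are matched
with a tolerance band rather than exactly.

## Pharmacophore model and fitting

`derive_model` reduces a two-chain interface to typed features: hydrophobic
features at centroids of apolar (C/S) side-chain atoms within 4.5 Å of
receptor apolar atoms; donor features at ligand N-H/O-H hydrogens whose donor
heavy atom is within 3.5 Å of a receptor acceptor (direction toward the
acceptor); acceptor features symmetric to that; exclusion spheres with
element van der Waals radii on receptor heavy atoms within 5 Å of the ligand.
Same-kind features closer than the minimum feature distance (1.5 Å default)
merge to their centroid with the larger radius. Default tolerance radii are
1.5 Å (hydrophobic/aromatic) and 1.0 Å (donor/acceptor); hydrogen-bond
directions must agree within 45°. All of these are exposed parameters; none
has a published value, and the defaults are ordinary contact-geometry
choices.

Sub-models are all feature subsets of size ≥ `min_match` (default 5) that
contain the mandatory core (by default the two deepest hydrophobic/aromatic
features plus the first donor — the pocket insertion plus one rim hydrogen
bond). Enumeration is deterministic (size, then lexicographic) with an
optional cap. The manual selection of feature combinations used historically
in commercial software is not recoverable; exhaustive enumeration is the
reproducible replacement.

Fitting is exact rather than heuristic: for each sub-model the search
enumerates every type-compatible injective mapping of ligand feature points
onto model features (aromatic points may satisfy hydrophobic features but not
vice versa), pruned only by the lossless pairwise-distance criterion
|d_ligand − d_model| ≤ r_i + r_j, and evaluates each mapping with a
closed-form rigid superposition. A mapping is valid when every residual lies
within the feature radius, directional features agree within tolerance, and
no ligand heavy atom enters an exclusion sphere. The score is
Σ exp(−d²/(2(r/2)²)) over matched pairs — bounded by the matched count,
strictly decreasing in any residual, and rigid-invariant. The fit-value
formula used by the original commercial screening engine is proprietary;
this score is defined bit-exactly in its place. Exactness is verified against
a pruning-free brute-force oracle on desk-scale cases.

## Chemistry

Molecules are RDKit `Mol` objects; SD files (V2000) are the interchange
format with conformers grouped by shared title. Donor counting is a direct
atom scan (N/O/S bearing ≥1 implicit or explicit H) to match the
OpenBabel-style definition used for library filtering, and aromatic groups
are counted as SSSR rings whose bonds are all aromatic. Fingerprints are
Morgan radius-2 / 2048 bits — the de-facto standard behind Tanimoto
diversity analysis — and diversity picking is the greedy leader walk over the
score-ranked list with a configurable threshold (default 0.6); the original
workflow's cutoff and subsequent manual visual inspection are not
reproducible and are replaced by this deterministic rule.

## NMR statistics

The combined CSP is Δδ = √((ΔδH² + 0.14·ΔδN²)/2); a residue is notable when
Δδ > max(2σ, 2σ_exp) with σ the untrimmed standard deviation over all matched
residues and σ_exp = 0.01 ppm (spectral digital resolution). Peaks match by
assignment label only — automated peak tracking is out of scope.

Titrations are fitted with the single-site fast-exchange 1:1 isotherm, with a
global Kd (log-space, bounds 10⁻⁷–1 M, three log-spaced deterministic starts)
and per-residue Δδmax via `scipy.optimize.least_squares`. The saturation flag
is false when the fitted Kd exceeds the top ligand concentration — the
signature of a millimolar binder titrated to 2 mM. On noise-free generator
data the fit recovers Kd and Δδmax to <1% (the model is exactly
identifiable).

Site mapping writes Δδ into B-factors and classifies the binding mode:
non-binder (no notable residues), site-binder (≥50% of notable residues
within 8 Å CA–CA of the target site), off-site binder otherwise, with a
one-sided hypergeometric enrichment probability over the assigned residues.
The 8 Å radius and 50% majority rule are stated choices for a read-out that
is qualitative in practice.

HetNOE comparison flags residues whose ratio difference exceeds 3× the
quadrature-combined uncertainty. This controls the per-residue false-positive
rate (~0.3%); family-wise, the "no significant change" verdict is reliable
only for comparisons of up to ~20 resolved residues, which is the regime the
calibration test uses.

## Trajectory analysis

Frames are engine-agnostic (multi-model PDB). Ligand RMSD superposes each
frame on the reference using protein CA atoms, then measures ligand heavy
atoms without refitting, so genuine excursions survive. Pose classes:
stable when ≥80% of frames are below 2.0 Å, unstable below 40%, semi-stable
between — invented numeric bounds mirroring qualitative
stable/semi-stable/unstable language, exposed as configuration. Hydrogen
bonds use the standard 3.5 Å donor–acceptor / 30°-from-linear criterion.
Contact maps count frames in which a ligand heavy atom is within 4.0 Å of any
heavy atom of a residue and divide by the maximum count, so the most frequent
contact is 1.

## Synthetic data: what it emulates, what it does not

The generators are pure functions of a `SyntheticSpec` (seed + counts +
effect and noise parameters); identical specs give bit-identical outputs.

* The toy interface plants exact geometry: an apolar loop tip 3.3 Å from
  pocket atoms, an N-H···O=C rim pair at 2.9 Å donor–acceptor distance, and a
  rim amide accepting a ligand carbonyl, producing a five-feature model.
* Library binders place feature points on model centers with ≤0.25 Å jitter
  (capped at half the radius) under a random rigid transform; decoys carry no
  donor point and therefore fail the mandatory core structurally, not
  probabilistically.
* Titration peak lists follow the fast-exchange isotherm at Kd = 2 mM,
  Δδmax = 0.15 ppm, protein 0.1 mM, ligand 0.125–2 mM, with the combined
  effect split ΔδH:ΔδN = 1:2 ppm and Gaussian noise of 2% of Δδmax on site
  residues (0.005 ppm combined on off-site residues).
* Trajectories use 100 frames by default: stable = 0.5 Å ligand jitter,
  semi = two-state hopping (4 Å displacement, 60% bound occupancy),
  unstable = steady 0.6 Å/frame drift out of the pocket; protein jitter
  0.1 Å.

These inputs have the statistical and geometric structure each operator
assumes — nothing more. Passing tests demonstrate correctness of the
algorithms and statistics (planted-effect recovery, oracle equivalence,
determinism), not performance on real spectra or force-field trajectories:
real data add peak overlap and exchange broadening, conformational strain in
ligands, and correlated protein motions that no generator here models.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale by design: libraries of
1–2 binders + 20 decoys × 2 conformers, 50-residue peak lists, 100-frame
trajectories, 100 random fit-oracle cases, and a two-stage (4° then 0.25°)
Euler-grid superposition oracle on 4-point sets. All randomness flows through
seeded `numpy` generators; CLI reruns with the same config and seed are
byte-identical, which the test suite asserts.

## Known limitations

* Conformer generation, docking pose generation, and MD production are out of
  scope; the pipeline consumes precomputed conformers and frames.
* `derive_model` on hydrogen-free crystal structures falls back to donor
  heavy atoms, losing donor directionality precision.
* Ligand feature typing uses simple rules (no SMARTS pharmacophore
  definitions, no charged-group features); sufficient for fragment-like
  molecules, coarse for complex heterocycles.
* The exhaustive correspondence search is exponential in sub-model size; it
  is exact and fast for ≤10-feature models with ≤250 conformers per compound,
  but it is not engineered for million-compound production screens.
* Cross-species RMSD values depend on deposited coordinates that must be
  fetched once with network access (`scripts/fetch_pdb.py`).
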