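# Methods

This note documents the models, conventions and numerical choices behind
`xlcal`, in the order of the pipeline.

## Structure model and PDB I/O

Structures are chains of residues of atoms. Author residue numbering is
preserved verbatim (1-based, gaps allowed, insertion codes carried):
crosslink positions arrive in full-protein coordinates, and any renumbering
would silently break the mapping between identification tables and models.
Only ATOM records of the 20 standard amino acids are modelled; HETATM
records are ignored, since the models being scored are protein-only.
Alternate locations are collapsed at read time, by default keeping the
highest-occupancy conformer (ties resolve to file order); parsing is
delegated to gemmi behind a pre-scan that reports malformed coordinate
fields with their line numbers. Writing emits fixed-column ATOM records
(`%8.3f` coordinates), restricting chain identifiers to one character —
the classic PDB dialect.

## Crosslink tables and deduplication

Search engines report one row per peptide-spectrum match (PSM); a single
lysine–lysine crosslink is typically supported by several PSMs, often at
different charge states. `dedupe_to_residue_pairs` canonicalises pair
orientation ((protein, position) lexicographic order), counts supporting
PSMs, unions charge states, and classifies pairs as intra- or
inter-molecular. Link positions are full-protein 1-based coordinates; a
column-map dialect adapts third-party export layouts to the documented CSV
schema. When peptide placement in a sequence is ambiguous (multiple exact
substring matches) and no explicit position is given, the record is
rejected and logged — never guessed. Lysine validation against supplied
sequences is advisory by default, because protein N-terminal amines also
react with the crosslinker; strict mode excludes non-lysine links.
Upstream identification and FDR control (e.g. a 1% target–decoy filter)
are consumed, not recomputed: tables are assumed pre-filtered, and the
optional q-value cutoff defaults to keeping everything.

## Restraint policy

DSSO's spacer arm is ~10 Å, so an intramolecular crosslink implies the two
lysine N-ζ atoms were within reach: the restraint is one-sided, [0, 10 Å],
not a band. Intermolecular crosslinks used as docking restraints carry the
conventional [10, 20 Å] band; distances below 10 Å are reported as
lower-bound violations and flagged separately, since a short distance does
not contradict the chemistry the way an over-stretched one does. Predicted
models often truncate lysine side chains, so when either N-ζ is missing,
evaluation falls back to Cα–Cα with bounds widened by a configurable pad —
default 13 Å, approximately two extended lysine side chains, giving a
0–23 Å intramolecular window. Restraints whose residues cannot be found at
all are reported as "missing" and excluded from sums: missingness is data,
not failure. All thresholds live in `RestraintPolicy` and are recorded in
outputs.

## Decoy ranking and the consistency loop

"Select the model with minimal distances between the crosslinked lysines"
is interpreted as the minimal **sum** of restrained distances over
evaluated restraints — scale-continuous, unlike a count of satisfied
restraints; the mean is available as an alternative key for decoy sets
with unequal evaluable-restraint counts. Ties break on fewer violations,
then smaller maximum violation, then input order. Models with unevaluable
restraints rank after fully-evaluated ones but are not disqualified. The
consistency verdict — the artifact handed back to an external modelling
round — is PASS when every evaluated restraint's violation is within a
tolerance (default 0 Å; a flag allows slack), FAIL otherwise with the
violated restraints listed largest-first.

## Superposition and RMSD

`kabsch` computes the closed-form least-squares proper rotation via SVD
with a determinant correction (reflections excluded); collinear inputs are
flagged, not rejected. Residues between models of different constructs are
paired by Needleman–Wunsch global alignment of the extracted one-letter
sequences (identity scoring, gap open 10, extend 0.5 — only the pairing
topology is consumed, never the scores); all-atom mode pairs
identically-named atoms within aligned residues, so side-chain-less
residues contribute backbone atoms only.

Two reporting modes mirror the two conventions in circulation:

- *no outlier rejection* — one Kabsch pass over all pairs;
- *refined* — iterate: superpose, drop pairs with residual greater than
  `cutoff_sigma` × the RMS residual, re-superpose; stop when nothing is
  dropped or after `max_cycles`. Defaults are 2.0 σ and 5 cycles,
  matching common molecular-graphics alignment defaults; both are
  configurable and reported. The RMS residual (not the standard deviation
  of the residual norms) is the rejection scale: residual norms of a 3D
  Gaussian error are Rayleigh-distributed, and a norm-std cutoff would
  mass-reject well-fit pairs. The loop stops early when residual spread
  falls to numerical noise (< 1e-8 Å). Refinement can only shrink the
  fitted set's residual, which the tests assert over random perturbation
  fixtures.

A two-stage convention — fit on Cα pairs, report RMSD over all paired
atoms — is exposed via `rmsd_atoms="all_atom"`, since "all-atom RMSD after
Cα alignment" is a common way of reporting model differences.

## Solvent-accessible and buried surface area

SASA uses Shrake–Rupley sphere-point sampling with a deterministic
generalized-spiral (Fibonacci) lattice: the method and its parameters
(probe 1.4 Å, 960 points, Bondi-type radii) are conventions of this
package, configurable and recorded in every result. The lattice is
oriented in the molecule's principal-axis frame with deterministically
fixed signs, which makes total SASA exactly invariant under rigid motion
of the input — a world-fixed lattice would be only statistically
invariant. Models are assumed hydrogen-free; per-residue SASA sums heavy
atoms. Buried surface area of a component is its SASA computed in
isolation minus its SASA within the complex, so per-component burials sum
exactly to (Σ isolated − complex). The burial-vs-affinity check uses
Spearman rank correlation with an exhaustive permutation p-value for n ≤ 8
and 10,000 seeded resamples otherwise.

At 960 points the sampling error against a 10,000-point run is below 2% on
random 20-atom clusters, and a single isolated atom is exact to the
analytic sphere area up to lattice quantisation (< 0.5%).

## Insert regions, hydropathy, charge

Insert regions are maximal alignment-column runs (≥ `min_length`, default
5) in which a proper nonempty subset of members is gap in every column and
each remaining member is ≥ `min_occupancy` non-gap (default 0.9). This
formalises what one finds by eye in a Clustal alignment of a paralog
family — e.g. a 21-residue loop present in two members and absent in two
others. Coordinates are converted between alignment columns and 1-based
sequence positions, with a round-trip identity on non-gap columns.

Hydropathy uses the Kyte–Doolittle scale (shipped in-module and
cross-checked in tests against an independent published copy) with a
centered sliding window, odd width, default 9; termini use shrinking
windows rather than padding. Net charge is a Henderson–Hasselbalch sum
over D, E, H, K, R side chains at pH 7.4 (pKa 3.65/4.25/6.00/10.53/12.48),
termini excluded by default since regions are internal spans. This is a
deliberate sequence-level **proxy** for electrostatic character, not a 3D
potential map. Region comparison reports mean-hydropathy delta, net-charge
delta and global-alignment identity over alignment columns.

One construct-bookkeeping note: truncation variants in the literature of
this problem family are sometimes stated inconsistently (an N-terminal
deletion given as 21 residues in one place and 20 in another). Both are
representable as `SequenceRegion`s; the package takes no position on which
is canonical.

## SPR 1:1 kinetics

The simulator and fitter share one closed-form 1:1 Langmuir model
(association `R(t) = Req(1 − e^{−(C·ka+kd)t})` with
`Req = C·ka·Rmax/(C·ka+kd)`; dissociation `R(t_a)·e^{−kd(t−t_a)}`).
Mass-transport-limited and bivalent-analyte models are deliberately out of
scope. Fitting is global nonlinear least squares over all curves sharing
(ka, kd, Rmax), on log-scale parameters (positivity without active
bounds), initialised from the dissociation log-slope (kd), the largest
observed plateau (Rmax) and the equilibrium relation (ka), with a small
multistart over the ka guess. Non-convergence is flagged in the result.
Synthetic titrations default to 0.1/0.3/1/3/10 × KD — a five-point series
of the kind used for KD determination — with 4-minute association and
dissociation windows at 1 s resolution. The fit report carries asymptotic
standard errors (delta method from the log-scale covariance); when
averaging KD over replicate experiments, an SEM across fits is the other
convention, and both can be computed from the per-fit results.

Blocking-assay normalization divides a test trace pointwise by a
negative-control trace (control linearly resampled onto the test grid);
control points below a floor are masked, never divided. Fold-differences
between KD values are reported both as the exact ratio and rounded to one
significant figure, the precision at which such comparisons are quoted.

## Synthetic fixtures

Fixtures emulate the *shape* of real inputs, not their physics: ideal
α-helices (rise 1.5 Å, 100°/residue, Cα radius 2.3 Å, giving the 3.8 Å
Cα–Cα spacing) with a pseudo-NZ placed 6.4 Å radially outward from the Cα
of each lysine — a documented geometric stand-in for a flexible side
chain. The canonical `lobster_model` fixture is a 160-residue single-chain
bundle of 4 major (32-residue) and 4 short (8-residue) helices with
lysines every 4th residue along the major helices, providing > 14
intra-chain lysine pairs within the 10 Å reach; crosslink tables sampled
from it dedupe back to their planted pair count and are satisfied with
zero violation by construction (planted-truth closure). Decoy sets apply
proper rigid transforms to one chain. Sensorgram sets are exact closed
forms plus seeded Gaussian noise. Every generator is a pure function of
its arguments and seed, and the tests assert byte-identical reruns.

What passing tests on these fixtures do **not** show: robustness to real
side-chain conformational variability, to wrong identifications surviving
FDR control, to instrument drift/baseline artefacts in SPR traces, or to
genuinely ambiguous peptide placements in repetitive sequences. Those
require real data.

## Problem sizes

The test suite and the acceptance script use deliberately small problem
sizes — 100 random restraint fixtures, 20 seeded decoy series, 25
superposition cases, 20-atom SASA clusters, 50 noiseless + 20 noisy
kinetic fits at 2 s / 1 s sampling — chosen so the whole suite runs in
seconds while still exercising every code path and oracle comparison at
full numerical precision.

## Known limitations

- mmCIF, hydrogens, crystallographic symmetry and bond topology are out of
  scope of the structure model.
- Restraint export formats for specific docking/refinement servers are
  plain CSV/JSON only; no server APIs are called.
- The SASA radii set covers the elements of hydrogen-free protein models;
  exotic elements raise a clear error rather than guessing a radius.
- The insert-region detector assumes a trustworthy input alignment; it
  does not realign.
- Kinetic fitting assumes the analyte concentration series is accurate;
  concentration error propagates directly into ka (and hence KD).
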