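# Methods

This note documents the models, conventions and numerical choices behind
dockbench, and what its synthetic fixtures do and do not establish about
real crystal structures.

## Structure model and cleaning

Structures are parsed from PDB-format text keeping only ATOM records:
HETATM, ANISOU and water records are dropped, and only the first model of
a multi-model (NMR) file is read.  Benchmark case files are distributed in
exactly this reduced form, so the parser and writer implement the ATOM
subset directly with fixed-column layout (`ATOM`/`TER`/`END`), preserving
chain ids and author residue numbering verbatim.  Residue identity is the
triple (chain id, residue number, insertion code) throughout; nothing
renumbers.

Conventions where the field has no single standard:

- **Alternate locations** — the default policy keeps the altloc with the
  highest occupancy, breaking ties by the alphabetically first altloc id;
  a `first`-wins policy is available.
- **Hydrogens** — parsed and retained in the model, but excluded from all
  distance-based computations (interfaces, contacts, RMSD selections,
  SASA), which operate on non-hydrogen protein atoms only.
- **Nonstandard residues** — MSE and similar parent-mappable residues
  translate to their standard one-letter code for sequence derivation
  (MSE→M, SEC→C, …) and stay in the structure; unknowns become `X`.

Unbound chains often carry extra domains or expression tags; truncation
keeps only the unbound residues aligned to bound positions under a global
pairwise alignment (BLOSUM62, gap open −10, extend −0.5) with free end
gaps, retaining match/mismatch columns only.  The same alignment builds
the bound↔unbound residue maps used by every RMSD.

## Unbound-structure screening

A sequence-search hit qualifies a candidate unbound structure iff

    identity > 93 %,  coverage > 80 %,  E-value < 10⁻⁵

with all three inequalities strict: a hit exactly at a boundary fails.
BLAST tabular output carries no coverage column, so coverage is computed
as the aligned query span (qend − qstart + 1) over the full query (bound
chain) length.  Identity arrives as a percentage and is stored as a
fraction.  A heavy+light antibody requires each chain to pass
independently; assembling unbound H and L chains from different database
entries is out of scope.  Per-side completeness yields the pairing state:
UU (both sides have unbound structures), UB (antibody only), BU (antigen
only), BB (neither).

## Conformational-change metrics

**Superposition.**  Rigid fits use the Kabsch algorithm (SVD of the
cross-covariance matrix with the usual sign correction, so the rotation is
always proper).  At least three non-collinear points are required;
collinear sets leave a rotation degree of freedom undetermined and are
rejected rather than silently resolved.

**Interfaces and contacts.**  A residue is an interface residue when any
of its heavy atoms lies within 10 Å of any heavy atom of the binding
partner; contacts use the same construction at 5 Å and are recorded as
residue pairs.  Neighbour search uses a k-d tree (scipy `cKDTree`); the
results are required — and tested — to equal an all-pairs O(N²) scan
exactly at the stated cutoffs.

**I-RMSD.**  Cα RMSD over the bound interface residues after fitting the
unbound structure onto the bound one *on those same interface Cα atoms*.
Per-side values fit and measure one component; the entire-interface value
fits each component on its own interface Cα set and pools the squared
deviations over both sides in the bound frame.  The fitting protocol for
the entire-interface value is a declared convention of this package, not
an inference.

**f_non-nat.**  Each unbound component is placed in the bound frame by
its interface fit; the contacts of the resulting model pair at 5 Å are
translated to bound numbering through the residue maps and compared with
the native contact set.  The reported value is
|model contacts ∖ native| / |model contacts| — the denominator is the
model contact count.  Residues with no bound counterpart can only
contribute non-native contacts.  A superposed pair forming no contact at
all returns 1.0 by convention, with a warning, rather than 0/0.

**ΔASA.**  Solvent-accessible surface area is computed with the
Shrake–Rupley method (via biotite, element-based van der Waals radii,
probe 1.4 Å, 960 sphere points per atom by default).  ΔASA =
SASA(antibody) + SASA(antigen) − SASA(complex), with the components taken
in their bound conformation.  Numerical SASA differs from other
implementations' radii sets by a few percent; ΔASA feeds no
classification threshold, so this affects reporting only.  A single
isolated atom recovers the analytic sphere area 4π(r + 1.4)² (exactly,
for any point count, since every sample point is accessible).

**CDR RMSD.**  CDR boundaries follow a Chothia-style numbering annotation
supplied as input (TSV: chain, cdr, start, end); the toolkit never infers
numbering from sequence.  The unbound antibody is fitted on the framework
(non-CDR) Cα atoms and each CDR's Cα RMSD is measured in that frame
without refitting.  A CDR unresolvable in the unbound structure is
reported missing; the others are still computed.  The framework "block"
ranges used to mask antibody framework residues during docking are
heavy 6–22, 39–46, 81–91, 106–end and light 7–20, 38–44, 76–85, 101–end
(Chothia numbering).

## Difficulty classification

    Rigid      iff  I-RMSD < 1.5 Å  and  f_non-nat < 0.40
    Difficult  iff  I-RMSD > 2.2 Å
    Medium     otherwise

using the entire-interface I-RMSD.  All inequalities are strict as
printed; the three regions partition the quarter-plane, so boundary
values (1.5, 2.2, 0.40) fall to Medium.  When a case has several unbound
structures, classification uses the primary (first-listed) pair.
Composition percentages are reported to two decimals with half-up
rounding; note that 175→230 then gives 31.43 %, whereas some published
tables print 31.42 — truncation and half-up rounding differ in the second
decimal for this single figure.

## Redundancy removal

Two complexes are redundant iff *every* corresponding chain type (heavy,
light, antigen — matched by role, not chain id) passes identity > 60 %
with E-value < 10⁻³⁰ (strict), **and** the whole-complex Cα RMSD after
least-squares superposition over the mapped residues is < 5 Å.  High
sequence identity alone is insufficient: near-identical sequences can
adopt markedly different quaternary structures, so when the sequence
criteria pass, the structural comparison is mandatory (a missing RMSD is
an error, not a pass).  The Cα atom selection for this RMSD is this
package's choice.

Redundant pairs are edges of an undirected graph over case ids.  Pruning
repeatedly deletes a node of maximum degree (with its incident edges)
until every degree is 0; survivors form an independent set of the input
graph.  The greedy heuristic is implemented as specified — it does not
guarantee a maximum independent set.  Ties among maximum-degree nodes are
broken lexicographically by default so results are reproducible; a
seeded uniform-random tie-break is available as an opt-in.

Incremental update: new cases (already screened for unbound
availability) are compared against the stored, edge-free set and against
each other.  A case similar to nothing establishes its own non-redundant
group and is added; a case similar to some joins their connected
component, and pruning is re-run on that component's subgraph only.
Because node degrees depend only on a node's own component, per-component
pruning with the lexicographic tie-break provably yields the same
retained set as re-pruning the full graph.  A failure while computing a
pairwise verdict flags the new case unresolved and withholds it rather
than silently adding it.

## Synthetic fixtures

Toy complexes are idealized poly-alanine α-helices (1.5 Å rise, 2.3 Å
radius, 100°/residue; N, C, O, CB at fixed local offsets) — 60 residues
per chain by default, with the antigen helix parallel at a 4.5 Å
surface-to-surface approach so a genuine 5 Å contact interface exists.
Defaults were chosen once to resemble a small single-domain
antibody–antigen pair; overlapping geometry (clash closer than 1.2 Å) is
rejected.  All randomness (sequence mutations, the global rigid motion
applied to every unbound copy) derives from the spec seed; identical
specs yield byte-identical files.

The central construction is the *rigid-mode-orthogonal displacement
field*: interface residues are displaced along a fixed direction by
per-residue signed amounts c_i with Σc_i = 0 and Σc_i·x̃_i = 0 (x̃_i the
centered interface Cα coordinates).  These constraints keep the Kabsch
cross-covariance matrix symmetric positive-definite, so the identity
transform is the *exact* optimal superposition and the post-fit RMSD
equals RMS(c) — the requested magnitude — analytically.  (A literal rigid
translation of an unbound component would be absorbed entirely by the
superposition and read as 0; the fixture enum keeps the name
`rigid_shift` for the user-facing intent, but the implementation is this
displacement field.)  The same construction at whole-complex scale, with
one shared field scaled per family member, makes pairwise structural
RMSDs within a redundancy family exactly |r_i − r_j|.  By default the
shift is applied to both interface sides, so the per-side and
entire-interface I-RMSD all equal the magnitude; single-side perturbation
gives the entire-interface value magnitude·√(n_side/n_total).

Hinge rotations turn the distal half of the antibody chain about a hinge
residue (magnitude in degrees); CDR displacement translates the CDR3
range rigidly, so after framework superposition the CDR3 RMSD equals the
magnitude exactly while CDR1/2 stay at 0.

Redundancy families never run a sequence search: emitted hits carry
synthetic E-values (10⁻⁸⁰ within a family) and identities computed from
the actual mutated sequences.

**What the fixtures do not show.**  They emulate the *data shape* and the
*metric definitions*, not protein physics: no side-chain chemistry, no
realistic packing or loop geometry, no crystallographic noise, no
numbering irregularities (insertion-code-rich CDR loops), and sequence
identity in families is controlled by uniform random mutation rather than
evolutionary divergence.  Passing tests establish that the pipeline
computes the declared quantities correctly and reproducibly — not that
the thresholds themselves are optimal for real antibodies.

## Problem sizes and numerical tolerances

Test fixtures use 25–60 residues per chain; the exhaustive pruning check
enumerates every labelled graph on ≤ 7 nodes (≈ 2.1 M graphs) against an
independent re-implementation; metric oracles run 100 random fixtures
against O(N²) scans; parameter recovery checks displacement magnitudes
0.5/1/2/3 Å over 10 seeds within 5 % (the construction is exact; the
margin covers floating-point and alignment edge effects).  Superposition
degeneracy uses a relative singular-value threshold of 1e-8; SASA
convergence is verified by doubling the point count (< 0.5 % change).
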