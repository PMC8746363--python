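# Methods

This note documents the models, parameters and design choices behind
`gpcrpocket`, and what the synthetic benchmark does and does not show.

## Structure handling

Input structures are parsed with gemmi. Only the first model of
multi-model files is kept (crystal conformers are scored singly);
hydrogens are discarded because crystal structures rarely resolve them and
no protonation protocol is assumed — polar-hydrogen geometry is inferred
at scoring time. Waters are excluded. Alternate locations resolve to the
highest-occupancy conformer, ties to file order. For mmCIF, author
(auth_) numbering is used so anchors written against PDB-format files
transfer unchanged. Noncanonical peptide residues are handled by typing
only: a user-supplied map renames a residue to its canonical parent (for
example ornithine → lysine-like typing), optionally renames atoms, deletes
capping groups and records omitted covalent links; coordinates are never
rebuilt. This supports natural-backbone analogs of peptidomimetic
complexes without any remodeling step.

## Generic numbering

Ballesteros–Weinstein numbers are assigned from user-supplied anchors
rather than detected by alignment: each helix t has one x.50 anchor
residue, and other residues get t.(50+Δ) where Δ is the author-sequence
offset. Gaps therefore consume labels, which keeps anchored labels stable
in partially resolved structures. Loops use the GPCRdb convention, 23.x
for ECL1 anchored at the conserved tryptophan (23.50) and 45.x for ECL2
anchored at the conserved cysteine (45.50), with positions N-terminal of
the anchor decrementing. The config template documents the standard
anchor motifs (N1.50, D2.50, R3.50, W4.50, P5.50, P6.50, P7.50, C45.50)
as guidance. Structure-based numbering corrections for helix bulges are
out of scope.

## Superposition and the membrane frame

Receptors are aligned on Cα atoms of shared TM BW positions with a
least-squares rigid fit restricted to proper rotations (SVD-based; a
reflection is never returned, preserving chirality). Unresolved selected
positions are skipped with a warning; fewer than three shared positions is
an error. The extracellular membrane boundary is not computed by an
external embedding service; it is approximated from the TM geometry: each
helix axis is estimated from the difference of its half-trace Cα
centroids (exact for an ideal helix and insensitive to the phase-dependent
tilt a plain PCA picks up on short spirals), the bundle axis is the
sign-consistent mean oriented toward the extracellular loops, and the
boundary plane passes through the centroid of each helix's most
extracellular Cα. An explicit plane can be supplied instead when a
membrane embedding is available. Peptide penetration depth — the signed
distance of the deepest peptide heavy atom below that plane — is a
reporting quantity only.

## Interface energy model

The per-residue ΔΔG of a receptor residue is the weighted sum over all
peptide residues of five two-body terms evaluated over heavy-atom pairs.
The full pair energy is credited to the receptor residue (no halving).
Weights default to fa_atr 1.0, fa_rep 0.55, fa_sol 1.0, fa_elec 1.0,
hbond 1.0. One-body and intra-residue terms are intentionally absent:
the score is an inter-chain interaction measure, not a folding energy.

* **fa_atr / fa_rep** — a 12-6 Lennard-Jones potential with combined
  minimum at d_min = r_i + r_j and depth √(ε_i ε_j), split at d_min into
  an attractive branch (clamped at −ε inside the minimum) and a repulsive
  branch; the repulsive wall is linearized below 0.6·d_min to avoid the
  singularity, and the attractive tail is multiplied by a cubic smoothstep
  from 4.5 Å to zero at 6.0 Å.
* **fa_sol** — Lazaridis–Karplus Gaussian-exclusion desolvation: each
  atom's solvation free energy is attenuated by the partner's volume at
  distance r with decay λ = 3.5 Å, symmetric in the pair, switched to
  zero with the same smoothstep.
* **fa_elec** — Coulomb electrostatics with united-atom partial charges
  (polar-hydrogen charge folded into the carrier heavy atom; charged
  sidechains carry net ±1, amide nitrogens +0.30 with the carbonyl pair
  balancing to a neutral group), a dielectric ramping linearly from 4 to
  80 across the 5.5 Å cutoff, an inner plateau below 1.45 Å, a shift and a
  1 Å smoothstep making the term exactly zero at the cutoff.
* **hbond** — donors and acceptors are flagged heavy atoms; the polar-H
  direction is inferred from the donor's bonded base atoms (antecedent/
  bisector rule listed per donor class in the parameter table). The energy
  is −depth · W(d) · A(θ) with W a piecewise quartic well in the
  donor–acceptor distance (zero at 2.4 and 3.6 Å with zero slope, 1 at
  2.8 Å), A a quadratic ramp in the D–H…A angle from 120° to 180°, and
  depth 2.4 in score units — a strong-hydrogen-bond scale for this merged
  backbone/sidechain hydrogen-bond class. Donors with missing base atoms
  are skipped with a warning, never fatally.

All terms are exactly zero beyond their cutoffs and continuous there
(|E| < 10⁻⁶ within 10⁻⁴ Å of each cutoff), symmetric under argument swap,
and invariant under joint rigid motion; the weighted total decomposes
exactly into the per-term values. The parameter table ships as plain-text
TSVs covering the 20 canonical residues with Lennard-Jones,
Lazaridis–Karplus, charge and donor/acceptor entries per atom. The values
are this package's own parameterization with term semantics modeled on
modern all-atom score functions; units are kcal/mol-equivalent score
units and **no numerical equivalence with any external implementation is
claimed**. Side-chain repacking, minimization and relax protocols are out
of scope; scoring is performed on the input coordinates.

## Contacts and consensus selection

A contact is a (receptor residue, peptide residue) pair with minimum
heavy-atom distance ≤ 4.5 Å — a standard interface criterion, exposed as
a flag since the underlying definition is a convention. Per-complex
tables list every contacting receptor residue with its BW label and ΔΔG.
Aggregation assembles per-complex ΔΔG by BW label (blank where a position
does not contact the peptide), with contact count, sum and average over
the contacting complexes, sorted ascending by average. Selection uses the
dual threshold: average ΔΔG strictly below −1 and contact in at least 7
of 9 complexes. The threshold is interpreted on the cross-complex
average (the table is sorted and colored by average); a per-complex
reading — ΔΔG below the threshold in at least min_count individual
complexes — is implemented as an alternative mode. Externally produced
tables (e.g. docking ensembles) are ingested from TSV; multiple models of
one complex are averaged per position before aggregation (unweighted
mean). Report tables carry a color bin on the figure scale: −1 and below
darkest blue, 0 white, +1 and above darkest red, linear in between.

The ECL1 motif scan matches the five-residue pattern [Y or H], any, W,
any, F and its relaxed four-residue form xWxF, with overlapping matches
reported at 0-based offsets. Containment guarantees that every strict
match implies a relaxed match.

## The synthetic ensemble

The generator builds a schematic class A receptor: seven ideal helices
(1.5 Å rise, 100° twist, 2.3 Å radius; 36 residues each) on an 11 Å
circle with alternating topology, arched loops joining the helix ends,
backbone + Cβ pseudo-atoms, and anchors at each helix and loop midpoint.
A peptide chain is attached whose "fingers" contact a planted set of BW
positions: the target residue grows a short amide-tipped pseudo-sidechain
along its Cβ direction and the finger residue stacks head-on against it,
donating one linear hydrogen bond at 3.1 Å with its carbon atoms packed
near the Lennard-Jones minimum. Placement honors hard contracts — at
least one peptide atom 3.5–4.0 Å from each target, no receptor–peptide
pair under 3.0 Å, every non-target receptor residue at least 6.5 Å from
the peptide — searched over a deterministic grid of sidechain kinks with
seeded random extras, so planted contacts are favorable by construction
(ΔΔG ≈ −1.2 to −1.5 per position) and ground truth is unambiguous.
Remaining peptide residues are stacked as inert filler above the bundle.

Ensemble defaults are the study conditions: nine complexes; fourteen
planted positions whose composition mirrors the observed shared pocket
(two on TM2, one on TM3, three on TM6, five on TM7, and the conserved
ECL2 triplet 45.50–45.52), restricted to positions the toy twist geometry
exposes to a finger — the toy anchors sit at helix midpoints, so very
extracellular labels such as 7.28 are not constructible and near
equivalents stand in; two noise contacts per complex at globally distinct
labels (so no noise position can reach the count threshold); ECL1
sequences reproducing the observed class A motif distribution (four
receptors with [Y/H]xWxF, eight with xWxF, one with neither); and a
random rigid transform per complex to exercise superposition. All
randomness flows from one seed and re-runs are byte-identical.

What passing shows — and does not. The planted-recovery benchmark
demonstrates that numbering, superposition, scoring, aggregation and
selection compose correctly and that the dual threshold separates a
planted consensus from per-complex noise under favorable, noise-free
geometry. It does not validate the energy model against experimental
affinities or against the original analysis of the real nine crystal
structures: toy residues have pseudo-sidechains, contacts are designed,
and no conformational heterogeneity, resolution noise or missing density
is simulated. Reproducing the published pocket requires downloading the
nine PDB entries and is sensitive to the re-implemented scoring; that run
is a benchmark, not part of the test suite.

## Numerical choices and edge cases

* Kabsch RMSD is recomputed from the fitted transform rather than taken
  from the SVD residual, avoiding cancellation near zero; identity-level
  checks use a 10⁻⁶ Å floor.
* Altloc ties, duplicate BW labels, overlapping segments, missing anchors
  and malformed external tables are hard errors; untypeable atoms and
  unresolved selection positions are skipped with warnings (strict modes
  upgrade them to errors).
* Selection uses strict inequality at the ΔΔG threshold; a position at
  exactly −1 is not selected.
* The pipeline is fail-fast by default; `keep_going` skips failing
  complexes but records them and keeps judging the contact-count
  threshold against the configured ensemble size, so a dropped complex
  can only lose positions, never promote them.
* Problem sizes: the shipped analyses and the acceptance script run the
  nine-complex ensemble (~285 receptor residues per complex), which
  completes in a few seconds on one CPU.
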