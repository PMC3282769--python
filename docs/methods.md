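# Methods

This note documents the models behind `ptcsig`, the parameter choices
that matter, what the synthetic fixtures do and do not emulate, and the
numerical decisions a maintainer would want written down.

## Classification model

The classifier is deliberately rule-based rather than statistical: the
traits separating putrescine transcarbamylases (PTC) from ornithine
transcarbamylases (OTC) are few, discrete and structurally
interpretable, so an evidence-per-rule report is more useful to a
curator than a score from a trained model.

**Anchors.** STRT (carbamylphosphate binding) and HCLP (amine binding)
are invariant in both families and define the frame of reference. They
are searched as a pair whose spacing `hclp_start − strt_start` must lie
in **[190, 240]** residues: the *E. faecalis* PTC spacing is 216
(268 − 52), and the window is generous enough for family variation
while excluding coincidental distant matches. If several pairs qualify,
the leftmost STRT then leftmost HCLP wins (deterministic). The HPXQ
motif, shared by both families, is located between the anchors and
reported as evidence only; it never affects the verdict.

**lysine_upstream.** OTCs keep a lysine two residues upstream of STRT
that ion-pairs the α-carboxylate of ornithine; putrescine has no
carboxylate and PTCs replace the lysine (glutamine in *E. faecalis*).
The rule reads one residue at `strt_start − 2`: K ⇒ otc_like, anything
else ⇒ ptc_like, and it is inapplicable when STRT starts before
position 3.

**loop230.** The amine-specificity loop sits roughly 40 residues
upstream of HCLP: `(Y/W)(G/W)(V/L/I)X` in PTCs versus `xSMG` in OTCs.
The search window requires the pattern start at **28–50 residues
upstream of HCLP** (the *E. faecalis* offset is 38; the width allows
indel drift on either side). Finding the PTC pattern without SMG is
ptc_like; SMG without the PTC pattern is otc_like; both or neither is
reported as absent rather than guessed.

**cterm_extension.** PTCs carry a ~20-residue C-terminal extension
relative to OTCs. Measured as `len(seq) − (hclp_start + 3)`, the tail
is ptc_like at **≥ 60** and otc_like at **≤ 55** (the *E. faecalis* PTC
tail is 69; OTC tails are about 20 shorter). The 56–59 band is declared
ambiguous (absent) rather than thresholded in the middle, because the
two distributions approach each other there.

**helix13.** Within the extension PTCs carry the C-terminal-helix
signature `(L/f/v/i/m)XX(F/Y/L/M/v)(L/i/m)`. The field prints the
first position both with and without the low-frequency `m`; we adopt
the permissive union. The rule scans the last **30** residues and
additionally requires a helix-favoring context: the mean Chou–Fasman
helix propensity over a **15-residue window covering the match** must
exceed **1.05**. A full secondary-structure predictor would be opaque
and non-deterministic across versions; the Chou–Fasman P_α constants
are published, embedded, and sum to a mean of exactly 1.00 over the 20
residues, making "above 1.05 over a helix turn's worth of residues" a
simple, citable criterion. With several matches the one with the
highest primary fraction, then leftmost, is reported.

**Verdict policy (configurable, defaults documented in the CLI).**
No anchor pair ⇒ NOT_TRANSCARBAMYLASE. All five rules ptc_like ⇒ PTC.
The three OTC-discriminant rules (lysine_upstream, loop230,
cterm_extension) otc_like ⇒ OTC — helix-signature absence is expected
in OTCs, so it is not required as positive OTC evidence. Everything
else ⇒ TRANSCARBAMYLASE_UNCLASSIFIED with the full evidence attached.
The strict all-five policy for PTC trades recall for precision: the
point of the signature is unambiguous annotation.

## Motif notation semantics

Capitals are predominant residues, lower case lower-frequency ones,
`X` any residue, `(A/b/c)` an alternative group. A position is
satisfied by its primary ∪ secondary set — the notation distinguishes
predominance but does not say low-frequency residues fail, so matching
is permissive and each match carries `primary_fraction` (share of
non-wildcard positions satisfied by the primary set) for downstream
ranking. An `X` in the *sequence* satisfies only wildcard positions.
All matches at distinct starts are reported; tie-breaking is the
caller's job.

## Pairwise alignment

Global Needleman–Wunsch (Biopython's `PairwiseAligner`) with BLOSUM62,
gap open 10, gap extend 0.5 (the first gapped position costs the open
penalty; end gaps are penalized identically). Percent identity counts
identical non-X aligned pairs and percent similarity counts pairs with
positive substitution score, both over aligned residue pairs; "identity
+ similarity" figures in the literature rarely state their matrix, so
these definitions are pinned here and configurable. The X row/column of
the matrix is zeroed: unknown residues neither reward nor penalize.
Consequence: self-identity is 100% for X-free sequences only. The
implementation is validated against a brute-force affine-gap oracle on
short sequences.

## Synthetic fixtures

The generators emulate the *trait layout* of each family, not its
evolution: a uniform random 20-letter background (seeded,
`numpy.random.default_rng`) with the traits implanted at the
*E. faecalis* coordinates — Q/K at 50, STRT at 52, DVWYGLY at 227–233
or VSMG at 230–233, HCLP at 268, total length 340 (PTC) or 320 (OTC).
Backgrounds are rejected and redrawn (max 100 attempts) when they
contain a spurious second anchor, a competing loop motif in the 230
window, or an unintended helix-signature match in the C-terminal
region, so every fixture is unambiguous by construction.

Two layout choices keep ablations single-trait. First, the helix
context implanted at 302–320 is poly-alanine: alanine is strongly
helix-favoring (P_α 1.42) yet can never match the signature's first
position, so the implanted LAAFL is provably the region's only match
and scrambling it to poly-A flips exactly the helix rule. Second, the
signature sits at 312, near the start of the tail, so the
stop-codon-style truncation after residue 317 (the construct used
experimentally to delete the C-terminal helix) shortens the tail to 46
residues — flipping the tail rule — while the signature survives inside
the new C-terminal window. In real PTCs the signature lies at ~330,
at the far end of the tail; the fixture trades that positional realism
for orthogonal, independently testable traits.

What the fixtures do **not** emulate: residue composition bias,
phylogenetic correlation, indels, partial or fragmented sequences, and
eukaryotic targeting peptides. Passing the closed loop therefore shows
the rules and their windows are implemented coherently — not that the
classifier's error rate on real database sequences is zero. Real-world
validation requires the accessions the signature was derived from,
which the library deliberately never downloads.

## Kinetics

`fit_hyperbola` is plain nonlinear least squares
(`scipy.optimize.curve_fit`, bounded to positive parameters) on
v = V·S/(K+S), with a deterministic initializer: V₀ = 1.2 × max rate,
K₀ = the concentration whose rate is nearest V₀/2. Standard errors come
from the covariance of the linearized problem at the optimum — the same
convention as common fitting software. Catalytic efficiency is V/K with
a significant-figures rounding helper, because printed efficiencies in
the literature are rounded from unrounded fits (e.g. a printed
0.67 U mg⁻¹ mM⁻¹ is not reproducible from the printed V and K alone,
which give 0.659; that figure is accordingly not used as a recovery
target).

Inhibition uses percent = 100/(1 + ([I]/IC₅₀)^h). The underlying
model for bisubstrate-analog inhibition curves is rarely stated, so the
Hill slope is free by default with an option to pin h = 1; a dataset
whose upper-half concentrations do not show lower mean activity than
its lower half is rejected as "no inhibition detected" before fitting.

Equilibrium conversion solves x² = K(a₀−x)(b₀−x) in closed form
(quadratic; linear at K = 1) and returns x/min(a₀, b₀), the converted
fraction of the limiting substrate. With K = 81 and 10 mM + 10 mM this
gives exactly 0.90 — the observed equilibrium point when ornithine is
carbamylated, which is what establishes ornithine as a genuine
substrate. The solver is monotone in K and symmetric in (a₀, b₀).

## Structural geometry

**PDB input** goes through gemmi; coordinate columns are pre-validated
so malformed fields raise with a line number, and alternate locations
resolve to the highest-occupancy conformer.

**Kabsch superposition** is the standard SVD solution with the
determinant sign correction, so the rotation is always proper. Inputs
with fewer than 3 points or with collinear (rank < 2) centered
coordinates are rejected rather than silently returning an unstable
rotation. Validated against numeric minimization over rotation vectors.

**SASA** is Shrake–Rupley with a 1.4 Å probe and a deterministic
golden-spiral quadrature (default **960 points/atom**; no RNG, so
results are byte-reproducible; quadrature error on spheres is well
under 1%). Van der Waals radii are an embedded standard set (C 1.70,
N 1.55, O 1.52, S 1.80, Ni 1.63 Å, …). Tools differ slightly in radius
sets, so absolute areas agree with other software only to a few
percent. Interface burial is SASA(partner alone) − SASA(partner in the
a+b complex), per partner; waters participate only when explicitly
selected. Note the spiral is fixed in space: mirror-image partners
agree to quadrature accuracy, not exactly, and the agreement tightens
with the point count.

**Metal sites** take all non-metal atoms within **2.6 Å** (typical
Ni–N/O coordination) of the metal; geometry is "octahedral" only for
exactly 6 ligands whose 15 inter-ligand angles partition into 12
near-90° and 3 near-180° within **±20°**. This census cleanly separates
octahedral from tetrahedral or planar arrangements without fitting.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on generated
inputs: 50 fixtures per class for the closed loop, 25 seeds × 4 rules
for ablation specificity, 1,000 random sequences (length ≤ 200) for
scanner equivalence, and small constructed atom sets for the geometry
oracles — sizes chosen so the whole acceptance run completes in
seconds while every rule and branch is exercised. All randomness flows
from explicit seeds; repeated runs are identical.

## Known limitations

* The classifier is motif-relative, so absolute numbering in reports is
  raw-sequence numbering; eukaryotic OTC precursors with targeting
  peptides classify correctly but their reported positions include the
  presequence.
* Thresholds (tail lengths, propensity cutoff, windows) are calibrated
  to the *E. faecalis* layout and documented defaults, not fitted to a
  curated corpus; they are all configurable.
* No multiple-sequence alignment, profile/HMM search, or oxamate
  transcarbamylase detection (no published signature to implement).
* SASA and burial are single-conformer, no symmetry expansion; mmCIF is
  not parsed.
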