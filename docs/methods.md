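# Methods

`polyq_eval` evaluates ensembles of predicted protein structures for a short
polyglutamine construct against partially resolved experimental reference
chains.  This note documents the models and procedures implemented, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## The construct and its regions

The default construct is the 60-residue huntingtin exon-1 fragment with 17
glutamines (HTT17Q-EX1): a 17-residue amphipathic head (positions 1–17), the
poly-Q tract (18–34, all glutamine), and a proline-rich C-terminus (35–60).
Construct positions are 1-based and region intervals inclusive; the three
regions must tile the sequence exactly and every tract position must be Q —
this is validated at construction.  Crystallographic chains of this
construct are expressed as maltose-binding-protein fusions, so author
numbering is mapped onto construct positions by an explicit per-file integer
offset, validated residue-by-residue against the construct sequence.  A
wrong offset fails loudly as a sequence mismatch rather than silently
producing a shifted chain.

"Resolved" means a CA coordinate is present — that is all that alignment and
overlap scoring need.  Secondary-structure assignment additionally requires
N, C and O; residues missing those are CA-only: usable for superposition,
reported as missing (M) in secondary-structure strings.

## Superposition and TM-score

Rigid superposition is the closed-form Kabsch solution (SVD with the
determinant sign correction, so reflections are never returned).  The
TM-score of a residue correspondence of length L over a normalisation
length L_N is

    TM = (1/L_N) Σ_i 1 / (1 + (d_i/d0)²),
    d0 = 1.24 (L_N − 15)^(1/3) − 1.8,

with L_N floored at 17 and d0 floored at 0.5 Å to avoid the cube-root
blow-up on short chains.  The score is maximised over superpositions with
the standard fragment-seeded search: seeds are the full pairing, its halves,
and every 7-residue window; each seed is refined by iterating {superpose on
the current subset → re-select pairs within a distance cut (starting at d0,
relaxed in 0.5 Å steps until at least three pairs qualify)} until the subset
repeats.  The search is deterministic and, by construction, scores at least
as high as an exhaustive pass over all 7-residue seed windows (a property
the tests assert).

Normalisation: model-vs-reference scoring normalises by the reference's
resolved length (panel averages must be comparable across references);
model-model reproducibility scoring normalises by the shorter chain, which
makes it symmetric.  Both are exposed as a `normalize_by` switch.

## Sequence-independent alignment

The aligner follows the TM-align scheme rather than reproducing any
particular implementation bit-for-bit.  Initial correspondences come from
(i) gapless threading at every offset (the best two by a quick superposition
score), (ii) Needleman–Wunsch over coarse CA-geometry secondary-structure
strings, and (iii) a combined distance + secondary-structure score after
superposing on the SS seed.  Each seed is refined by alternating
{superpose on current pairs with the TM-score search → build the pair score
matrix S_ij = 1/(1 + d_ij²/d0²) → global dynamic programming} until the pair
set repeats, with a cap of 30 iterations; the gap penalty is 0.6 (opening
only, no extension), ties in the DP traceback resolve toward the diagonal,
so results are deterministic.  The pairing with the highest TM-score wins.
Unresolved reference residues never enter the alignment.  Alignments are
strictly monotone (no crossing pairs) by construction of the DP.

The reported RMSD is the least-squares RMSD over the aligned CA pairs; the
stored rotation/translation is the TM-score-optimal transform, which is also
the frame used for exact-match distance classification.

## Exact structure overlap

With resolved lengths Lm (model) and Le (reference) and alignment length
L(A):

    SO   = 100 · L(A)  / min(Lm, Le)
    ESO  = 100 · L(EA) / min(Lm, Le)
    ESOP = 100 · L(EAQ)/ min(LQm, LQe)

An aligned pair is an *exact* match when both residues occupy the same
construct position (with sequence-validated input this implies the same
residue type).  Exact pairs are stratified by the CA–CA distance in the
alignment frame: "close" (< 5 Å by default — the stratum the ESO/ESOP
definitions use) and "other" (≥ 5 Å); "all" is their union.  L(EAQ) counts
exact close matches at positions inside the poly-Q tract.  LQm and LQe are
the numbers of *resolved* glutamines in the tract — a reference resolving
only 10 of 17 Qs is scored against those 10, which is what makes a perfect
ESOP of 100 attainable against partially resolved chains.  The "total Qs"
panel counts take every aligned Q–Q pair in a stratum with no
position-equality requirement, the most literal reading consistent with
those counts exceeding the exact-Q counts; the distinction is labelled
explicitly in the output columns.

The point of the exact scores is register sensitivity: renumbering an
otherwise identical chain by +1 leaves SO near 100 but sends ESO and ESOP to
exactly 0.  The tests assert this identity.

## Secondary structure

Assignment implements the Kabsch–Sander rules from backbone coordinates.
The amide hydrogen is placed 1.0 Å from N along the reversed C→O direction
of the preceding residue (chain starts and prolines do not donate).  The
hydrogen-bond energy is the electrostatic model

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)  kcal/mol,

with a bond below −0.5 kcal/mol.  n-turns (n = 3, 4, 5) come from i+n → i
bonds; two consecutive 4-turns make an α-helix (H), analogously G and I;
β-bridges from the parallel/antiparallel bond patterns, laddered bridges
become E; leftover turn interiors are T; a bend (S) is a CA chain-direction
change above 70°; the rest is coil, emitted as "C" rather than blank for
machine readability.  Overlaps resolve with precedence H > E > B > G > I >
T > S.  Positions without a full backbone are "M" (missing), a first-class
state so that profiles over crystal ensembles show where resolution decays.
Agreement with an independent DSSP implementation (mdtraj) on an
ideal-geometry mixed fixture is asserted at ≥ 95% of resolved positions
(H/G/E/B compared directly, the remaining loop states pooled — turn/bend
boundaries differ legitimately between implementations at helix termini).

Profiles are position × state count matrices over an ensemble of SS
strings, row-normalised to frequencies (the numeric content of a sequence
logo; graphical rendering is out of scope).

## Ensemble studies

Reproducibility: all C(n,2) model pairs are scored (50 models → 1225
values), the rank-1 models of the 10 runs give 45 pairs, and run-level
tables count, for each unordered run pair, how many of the m² cross-run
model pairs exceed a TM cutoff of 0.5 (strict inequality).  Validity: every
model is aligned to every usable reference (50 × 10 → 500 records) and the
metric panel (TM, RMSD, aligned length, sequence identity, six stratified
match counts plus their "all" sums, ESO, ESOP) is summarised.

References are usable when at least 9 consecutive glutamines of the tract
are resolved — more than half of 17.  The filter is idempotent and monotone
in its threshold.

Statistics policy: each sample is Shapiro–Wilk-tested at 0.05 (the
normality test itself was an open choice; Shapiro–Wilk is the default
omnibus test at these sample sizes).  Normal samples are reported as
mean ± sd and compared with Student's t-test; anything else as 25%/75%
quantiles with the Wilcoxon rank-sum test — rank-sum, not signed-rank,
because the two model sets are independent, unpaired samples.  Constant
samples are treated as non-normal (Shapiro–Wilk is undefined on them) and
compared by rank-sum, which correctly reports no difference.  α = 0.05
throughout; no multiple-testing correction is applied across the panel.

## Synthetic generation

The generator replaces predictor output and crystal references so the
pipeline can be exercised with known ground truth.

Chains are built by NeRF internal-to-Cartesian construction with ideal
geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; angles 111.2°, 116.2°,
121.7°; ω = 180°; carbonyl O in the peptide plane), giving trans-peptide
CA–CA spacings of 3.80 Å.  Per model, each region draws one conformational
state — head: helix 0.9 / coil 0.1; tract: helix 0.45 / coil 0.40 / strand
0.15; C-terminus: coil 0.9 / helix 0.1 — mirroring the crystal-chain
observation of a reliably helical head, a conformationally variable tract,
and a coil-dominated proline-rich tail.  Helix is (−57°, −47°), strand
(−135°, 135°); coil draws per-residue φ/ψ from a six-entry library spanning
the coil-accessible map.  Ensemble variability beyond state sampling is
isotropic Gaussian coordinate noise (default σ = 1 Å for model ensembles,
0.3 Å for references) applied after construction — Cartesian rather than
dihedral noise keeps the ground-truth correspondence trivially known.  The
synthetic confidence score is a monotone decreasing function of the realised
noise mapped into (−5, 2), imitating a predictor confidence score so
selection policies are exercisable.

Reference chains emulate partial crystal resolution: the head is always
resolved, the tract keeps a consecutive run of glutamines from its start,
and the C-terminus is unresolved from a drawn position onward.  The default
21-chain set fixes the resolved-Q counts from a table emulating the
deposited HTT17Q-EX1 crystal chains (three construct copies per crystal):
ten chains at 10–17 resolved Qs pass the 9-consecutive-Q filter, eleven
poorly resolved chains (1–8 Qs) do not.

What the generator does *not* emulate: real predictor error modes
(template bias, fragment-library artefacts, register shifts within the
tract), side chains, crystal contacts, and non-consecutive tract resolution.
Passing tests therefore demonstrate that the measurement machinery is
correct and discriminating on controlled input, not that any particular
predictor is accurate on real data.

## Problem sizes and determinism

The studies run at the design sizes (10 × 5 models, 21 references) where
counts are the point; parameter-recovery simulations use 6-model ensembles
against 2 references over 20 seeds per noise level, enough to resolve the
noise effect cleanly while keeping the suite quick.  All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; identical
seeds give bit-identical chains, and the CLI stamps every output with the
seed and a config hash.

## Known limitations

- The aligner follows the TM-align *scheme*; scores can differ in the
  second decimal from any particular TM-align build, which is why oracle
  tests compare against internal exhaustive searches rather than external
  binaries.
- Unrelated extended random-coil pairs average a TM-score right at the
  0.17 random-alignment level (that level *is* the mean of random pairs),
  so "random" should be read as a distribution around 0.17, not a hard
  ceiling.
- DSSP here implements the classic 8-state rules; π-helix refinements and
  solvent accessibility from newer DSSP versions are out of scope.
- mmCIF input, multi-model NMR entries, ligands and the fusion-partner
  portion of crystal entries are out of scope; chains are extracted from
  PDB-format files only.
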