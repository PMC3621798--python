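# Methods

## Scope and model

`mbnmine` automates an anchor-first strategy for finding methanobactin-like
(Mbn) biosynthetic gene clusters. The underlying biological model: Mbns are
RiPPs whose precursor (MbnA) carries an N-terminal leader and a C-terminal
core; the core's cysteines at C(G|A|S) sites become heterocycle/thioamide
pairs in the mature compound, and the conserved biosynthesis proteins MbnB
(DUF692-like) and MbnC sit immediately downstream of the precursor gene.
Because MbnA genes are too short for reliable direct search, mining anchors
on MbnB homology and then inspects the flanking DNA for candidate small
ORFs.

## Translated anchor search

Seeds are aligned against all six conceptual reading frames of each contig
with full Smith–Waterman dynamics (no heuristic word seeding; desk-scale
inputs make full DP affordable). Scoring is BLOSUM62 with affine gaps of
cost 11 + k for a gap of length k — standard protein-search defaults, since
no specific parameters are implied by the workflow being automated.
Deviations from the stock matrix:

* translations of N-containing codons (`X`) score 0 against everything;
* stop sentinels (`*`) score −1000 against everything, so no local alignment
  crosses an in-frame stop. An alignment that skips a stop with a gap is
  split post hoc into stop-free fragment hits. This reproduces the
  tBLASTn-like behaviour that makes a stop-split gene appear as two hits.

Expectation values use Karlin–Altschul statistics with the standard gapped
BLOSUM62 constants (λ = 0.267, K = 0.041) over a search space of seed length
× total translated frame length. Two decision tiers apply: `E < 1e-20`
(default `e_max`) admits a hit for neighbourhood examination, and
`E < 1e-50` (strict inequality) marks membership of the core MbnB-like
subgroup. The tiers are ~30 orders of magnitude apart, so modest deviations
of this E-value model from any particular BLAST build do not move hits
across tiers.

**Split genes.** Two same-seed, same-strand, same-frame hits that are
collinear in the seed, ≤ 30 nt apart (`max_gap_nt`, configurable) and
separated by exactly one in-frame stop are merged; the merged conceptual
translation replaces the stop with glycine and is re-scored against the
seed. The glycine choice mirrors the conjugate historically used to annotate
the split MbnB gene.

## Precursor criteria and leader/core split

Small ORFs (10–50 aa, ATG/GTG/TTG starts, first in-frame stop; nested starts
sharing a stop collapse to the longest in-bounds start) are enumerated on
both strands of a ±2 kb window around each anchor. A candidate is accepted
iff:

1. ≥ 1 Cys within the last 10 residues (`last_k`);
2. ≥ 2 Lys/Arg within the first 10 residues (`first_k`, `min_kr` — the
   reading of "multiple" as at-least-two);
3. a Lys/Arg within 5 residues upstream of the first cysteine
   (`pre_cys_window`), preceded by ≥ 3 residues from {A,V,L,I,M,F,W,P}
   within a 6-residue window (`min_hydrophobic`, `hydrophobic_window`).

The hydrophobic set includes proline because the canonical OB3b block is
V-L-P-V-I; window and threshold values are explicit assumptions (the source
description is qualitative) and are configurable. The candidate score is
`n_Cys + n_KR(head) + 1 if hydrophobic block`.

The **core starts one residue before the first cysteine**; this single rule
reproduces both experimentally grounded splits (LCGSCYPCSCM and
RCASTCAATNG, each at residue 20 of 30). A first cysteine at position ≤ 2
leaves no room for a leader; the whole peptide is returned as core with a
`no_leader` flag.

**Precursor call per operon.** All accepted candidates are kept in the
report, but each operon's detection call is the single top-ranked candidate.
Ranking uses two family-level plausibility keys before the score: cores of
7–15 aa rank first (the observed range of predicted cores), then cores
containing a C(G|A|S)(S|T) motif (every known core has one), then score,
anchor proximity, leftmost coordinate. Without the plausibility keys,
single-cysteine (Group V style) precursors — whose criterion score is
intrinsically low — are occasionally outranked by chance criterion-passing
ORFs in random DNA.

## Operon assembly and classification

Candidate genes in a ±10 kb anchor window (annotated CDS for GenBank input,
else maximal ORFs ≥ 60 aa) take the role of their best-aligning seed when
that alignment's expectation is below `role_e_max = 1e-10` (no threshold is
prescribed for accessory genes; this value cleanly separates genuine
homologues from background at these protein lengths). TBDTs with ≥ 70
residues upstream of the plug-domain match whose N-terminal segment scores
above the NExT profile threshold are flagged as signalling-competent.

Groups are assigned from sequence and operon features only — taxonomy is
deliberately not a feature, so the classifier generalizes to novel genomes.
Rules fire in fixed priority order (first match wins), and the rationale
string always names the fired rule:

1. **V** — exactly one core Cys, no MbnC, and a non-anchor gene between
   MbnA and MbnB;
2. **I** — 11–15 aa core with four cysteines and a proline, *or* the
   MbnI + MbnR + NExT-bearing-MbnT regulatory signature;
3. **II** — 2–3 core cysteines together with MbnS or MbnF, a CAST-like
   core (literal `CAST`, the conserved threonine), or the Cys-Trp
   subfamily (second cysteine followed by tryptophan);
4. **III** — any cysteine doublet (CC) in the core;
5. **IV** — exactly two non-adjacent core cysteines;
6. otherwise **unclassified** — retained deliberately, since the
   II/III/IV boundaries are heuristic.

## Product prediction

Given a classified precursor: every C(G|A|S) ring site becomes a
thioamide plus a ring (recorded at the cysteine offset); the first ring is a
pyrazinedione in Group II operons and an oxazolone otherwise. The 2-mer
(not the 3-mer) triggers ring formation because the OB3b second ring
cysteine sits in a CSC context. Ring assignment is keyed to Group II rather
than MbnF presence (MbnF also occurs in Group I operons) — an explicit
assumption. Non-ring cysteines pair sequentially into disulfides (odd
leftovers warn; > 2 free cysteines warn, as higher-order pairing is
untestable against known structures). MbnN adds N-terminal transamination;
MbnS sulfonates the first threonine strictly between the first two ring
cysteines. Group II cores are annotated with a variably-lost tail starting
two residues past the last ring cysteine, reproducing the reported −TNG/−NG
losses; the full-length product is always reported as well. Group II
Cys-Trp sites are emitted as rings flagged low-confidence, since the
heterocycle formed in that subfamily is unknown.

## Alignments, profiles, trees

Progressive multiple alignment: pairwise global alignments (BLOSUM62,
affine 11/1, end gaps penalized) give p-distances; a neighbor-joining guide
tree orders profile merges; profiles merge under an affine-gap
profile-profile DP using expected BLOSUM62 column scores. De-gapping any row
reproduces its input sequence.

Profiles are **ungapped position-specific log-odds matrices**, not full
profile HMMs: the detection targets (fixed-length precursor cores, the NExT
segment) do not require gapped search, and the simpler model is exactly
reproducible. Columns with > 50 % gaps are dropped; column probabilities are
`(count + 0.5·bg)/(n + 0.5)` (pseudocount configurable) against a background
uniform over the residues observed in the training alignment; unobserved
residues score a floor of −10 nats. The acceptance threshold is the weakest
training row's self-score, so every training sequence is a hit by
construction. A minimal HMMER3-ASCII emitter is provided for interchange;
parity with hmmbuild is a non-goal.

Neighbor joining uses scikit-bio's implementation for ≥ 3 taxa (negative
branch lengths clamped to zero), with the two-taxon case split evenly in the
wrapper. NJ is exact on additive matrices, which is what the tree tests
exploit.

## Synthetic data

The generator's defaults are the study conditions: 20 kb contigs,
GC 0.63 i.i.d. background, operons planted in the template gene order with
30–80 nt spacers, ≥ 10 decoy small ORFs per genome, amino-acid substitution
at rate 1 − identity drawn uniformly over the 19 alternatives. Each planted
gene is preceded by an in-frame stop so ORF boundaries are unambiguous.
Templates: Group I (OB3b-like, with NExT-bearing MbnT, MbnI/R, MbnN),
Group II (rosea-like, with MbnF/MbnS), Group V (single-cysteine precursor,
unknown gene between MbnA and MbnB, no MbnC).

Precursor mutations emulate purifying selection: the start Met, all
cysteines, head K/R, the pre-core K/R and its hydrophobic block (redirected
within the hydrophobic set), the two residues completing the first
C(G|A|S)(S|T) motif, and core prolines (Group I) are protected, and new
cysteines are never introduced — precisely the positions conserved across
the real precursor family. Accessory and anchor genes mutate uniformly at
the nominal rate. Decoys exercise each rejection path: (a) cysteine-free,
(b) K/R-poor heads, (c) criterion-passing peptides planted > 2 kb from any
anchor.

What the generator does **not** emulate: codon usage and GC structure of
real operons, overlapping genes (real MbnC frequently overlaps MbnB),
sigma-factor-fused precursors (exercised separately via the profile scan),
sequencing error, contig fragmentation and metagenomic chimerism. Passing
the synthetic benchmarks therefore demonstrates correctness of the
detection logic under the stated conditions, not field performance on raw
assemblies.

## Problem sizes and determinism

The recovery benchmark runs 50 genomes (20 kb each, identities drawn from
[0.8, 1.0], ≥ 10 decoys, a stop-split MbnB in one genome out of nine) —
sizes chosen to exercise every template and the split-gene path while
keeping the suite comfortably runnable on a laptop. Mining contains no
randomness: identical inputs give byte-identical JSON reports. All
generator randomness is seeded (`random.Random(seed)` per genome spec).

## Known limitations

* E-values are analytic Karlin–Altschul approximations, not empirically
  calibrated per matrix/gap combination; they are used only against
  thresholds separated by many orders of magnitude.
* Group II/III/IV boundaries are heuristic; ambiguous operons are left
  unclassified rather than forced.
* Fused (sigma-factor) precursors are detectable via `profile-scan` but are
  not folded into the automatic operon call.
* Circular-genome windows wrap, but features spanning the origin itself are
  skipped rather than reported with wrapped coordinates.
* The NExT profile is trained on packaged synthetic variants; real TBDT
  extension detection should rebuild it from a curated alignment
  (`mbnmine profile-build`).
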