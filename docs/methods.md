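# Methods

This note documents the models and procedures implemented in
`mirdiverge`, the parameters that matter, the numerical conventions, and
what the synthetic-data tests do and do not demonstrate about real data.

## Duplex scoring and the consensus rule

A candidate binding site is an ungapped antiparallel duplex over the full
mature miRNA (position *i* from the miRNA 5′ end pairs transcript window
position *L*+1−*i*). Per position the penalty is 0 for a Watson–Crick
pair, `wobble_penalty` (default 0.5) for G:U/U:G, and `mismatch_penalty`
(default 1.0) otherwise; N pairs as a mismatch. A window is a hit when
the summed penalty is at most the profile cutoff. Gaps and bulges are not
modeled: the published point scheme defines only mismatch classes, and an
ungapped full-length duplex is the minimal faithful reading of it.

Three default profiles stand in for the three commonly used plant
prediction tools, whose internals are not reproducible from their
published descriptions; they are emulations by design, not ports:

| profile | cutoff | weighting |
|---|---|---|
| plain | 3.0 | none |
| seed-weighted | 3.5 | all penalties ×2 at miRNA positions 2–13 |
| strict-wobble | 3.0 | wobble counted 1.0 (not 0.5) at positions 2–13 |

The 2–13 window is the region where plant miRNA–target pairing is known
to be least tolerant of mismatches. All profile fields are overridable
(YAML or constructor). An interaction is *consensus* when hits from at
least *k* = 2 of the 3 profiles agree on a site; two hit intervals agree
when they share ≥ 50% reciprocal overlap (for equal-length windows, a
start offset of at most ⌊L/2⌋). A consensus site is reported at the
representative interval of the first listed profile present in the
cluster and scored under the plain unweighted scheme, keeping the
reported interval exactly miRNA-length. Scanning is vectorised (a 5×5
pair-class lookup over a sliding-window view), and a brute-force
re-scorer in the test suite checks it window by window.

## Duplicate/singleton catalogue

Strict inequalities as printed in the source data conventions:
duplicate ⇐ any nonself hit with *E* < 1e-10 **and** query coverage
> 0.5; singleton ⇐ no nonself hit with *E* < 1e-3. The two rules do not
partition the gene universe, so genes between the thresholds form an
explicit `unclassified` class excluded from enrichment tables. Coverage
is aligned length / query length, evaluated in the query direction only
(the common convention for 12/13-column tabular hit files); which
direction the original analyses used is not recoverable, and the choice
is recorded in the catalogue metadata.

## Divergence verdicts

Divergence is defined on miRNA *family* sets per gene (a family is the
miRNA name with arm suffix and trailing variant letter stripped, e.g.
miR842a-5p → miR842): `not_applicable` when no member is targeted,
`same` when all members carry identical nonempty sets, otherwise
`divergent` (subtype `asymmetric` when a member is untargeted,
`different_mirnas` when all are targeted). Family-set equality rather
than site-coordinate identity is used because divergence in the source
analyses is tallied by *which* miRNAs target each paralog; pairs
targeted by the same family at different positions are therefore called
`same` by default. Percentages in summaries are round-half-up to
integer, matching printed-table style.

Triplets with any untargeted member are divergent regardless of the
remaining members' sets ("same" is only defined when all retained copies
are targeted), which mirrors how triplicate cohorts are bucketed by
number of targeted members (1, 2 or 3).

## miRNA ages and attribution

A miRNA is *young* iff it has no homolog hit outside the ingroup
(default *A. thaliana* + *A. lyrata*) with *E* < 1e-10 and coverage
> 0.5, and is not annotation-overridden; otherwise *ancient*. A miRNA
with no rows at all is vacuously young (logged). Attribution of a
divergent pair uses the **symmetric difference** of the members' target
sets: a young family must be among the divergence-causing families, so a
shared ancient family cannot mask a young-driven difference. For
same-verdict groups the tally is "any involved family young", the
natural analogue for a set with no differing families.

## Statistics

* **Pearson correlation** with pairwise deletion of missing values;
  pairs with fewer than 3 complete observations or zero variance are
  excluded (logged), never zero-filled.
* **Group contrasts** (expression *r*, Ks): two-sided Mann–Whitney U.
  The original analyses state significance without naming the test; the
  rank test is the standard choice for bounded, non-normal statistics
  like correlations. Exact enumeration when both groups have ≤ 20
  tie-free observations, otherwise the normal approximation with tie
  correction (scipy backend). Direction is reported alongside p.
* **Chi-square 2×2**: Pearson statistic against χ²(1 df), Yates
  continuity correction off by default (expected counts in all tables
  of interest are large) and available by flag. No multiple-testing
  correction: the pipeline performs at most four planned tests, reported
  individually.

## Ka/Ks (NG86)

The original analyses used PAML's yn00; here Ka/Ks is computed with the
Nei–Gojobori (1986) method, implemented in full and verified against an
independent brute-force implementation — a deliberate substitution,
stamped into output metadata. Group-level conclusions rest on relative,
not absolute, Ks, for which NG86 is adequate. Conventions:

* Per-codon synonymous sites: at each position, the fraction of the 3
  possible changes that preserve the amino acid, excluding changes to
  stop codons from the synonymous count; S is summed over positions and
  N = 3 − S, so stop mutations fall on the nonsynonymous side. Site
  counts are averaged over the two sequences.
* Differences: pathway averaging over orderings of the differing
  positions of each codon pair; orderings passing through a stop codon
  are excluded, and if every ordering is blocked the average is taken
  over all orderings with through-stop steps counted nonsynonymous.
* Correction: Jukes–Cantor, d = −(3/4) ln(1 − (4/3) p); p ≥ 3/4 is
  flagged `saturated` and the corresponding estimate withheld.
* Codon alignments come from a global protein alignment (BLOSUM62, gap
  open 10 / extend 0.5) back-threaded onto the CDS; gapped or ambiguous
  codon columns are dropped, internal stops are an error.

## Fitch parsimony mapping

Presence/absence of each miRNA family over a gene-family tree is scored
with Fitch small parsimony (unordered, reversible), because site
histories in duplicated families plausibly include both gains and
losses; Dollo (single gain) is available for comparison. Polytomies are
resolved arbitrarily with zero-length edges (logged); the parsimony
*score* is invariant to that resolution and to rerooting, and only
scores are asserted in tests. The deterministic reported labeling breaks
ties toward absence. Parsimony event counts are this package's explicit
formalisation of "multiple gains and losses"; the underlying biology is
not asserted to have exactly that many events.

## Synthetic-data generator

The generator emulates the shape of the real inputs: mature miRNAs
(21 nt default), transcripts of 300 nt at GC ≈ 0.42 (typical of
Brassicaceae coding sequence), an all-vs-all hit table (paralogs at
*E* = 1e-50, coverage 0.9; singletons with self-hits only), a
cross-species homolog table encoding true ages, and a 63-column
expression matrix — 63 matching the organ/developmental-stage panel the
expression analyses are built on. Planted sites are constructed by
reverse-complementing the miRNA and introducing the scheduled
wobbles/mismatches **outside** the weighted 2–13 region, so a planted
score ≤ 2.5 is predicted by all three default profiles; ablation
rewrites five Watson–Crick positions into mismatches (≥ 5 points),
exceeding every cutoff. Divergence mechanisms per group: site loss with
probability `p_site_loss` (default 0.3), else young-miRNA site gain with
probability `p_young_gain` (default 0.1), else unchanged; the expected
divergent fraction is p_loss + (1 − p_loss)·p_gain. Expression vectors
are equicorrelated normals (ρ = 0.8 for same, 0.2 for divergent pairs,
values shifted to a nonnegative scale), the minimal structure that makes
the group-contrast claim testable; miRNA repression is not modeled
mechanistically. All randomness flows from one `numpy` generator, so a
seed reproduces the bundle byte for byte.

**What passing tests show — and don't.** Recovery of planted truth shows
the scanner, catalogue, classifier and statistics are internally
consistent and correctly implement their definitions. It does not show
that the three profiles approximate the real tools' sensitivity, that
real binding-site divergence rates resemble the configured ones, or that
background (chance) binding sites are as rare in real transcripts as in
i.i.d. random sequence — random 21-mers almost never score ≤ 3 against a
random window (expected penalty ≈ 0.69/position), so false verdicts in
the synthetic cohorts are vanishingly rare, which is friendlier than
real genomes with conserved repeated families.

## Problem sizes and numerical choices

Test and acceptance runs use cohorts of 500 pairs (300 WGD + 200 tandem)
for recovery experiments, 200 random scanner-oracle pairs at transcript
lengths ≤ 500, 50 random 100-codon NG86 oracle comparisons (tolerance
1e-9), 100 random ≤ 8-leaf Fitch oracle trees, and 100 seeded runs of
the expression-power experiment (n = 200 per group) — sizes chosen so
every statistical check is well-powered while the whole suite stays
quick on a single CPU. Ties, orderings and JSON/TSV output are all
explicitly sorted, so identical inputs reproduce identical bytes.

## Known limitations

* No gapped/bulged duplexes, no target-mimicry, no translational- vs
  cleavage-mode distinction; all consensus hits are "interactions".
* Coordinate-level divergence (same family, different site) is only
  available behind the coordinate-aware flag and is not the default.
* NG86 lacks codon-frequency and transition/transversion bias
  corrections (yn00's models); absolute Ka/Ks values will differ from
  yn00, particularly at high divergence.
* The duplicate catalogue consumes precomputed similarity hits; running
  the search, syntenic-block detection and WGD dating are out of scope,
  as are tree inference and domain scanning for the phylogenetic stage.
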