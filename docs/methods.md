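# Methods

## Problem setting

Allohexaploid bread wheat (genome AABBDD) carries three homoeologous copies
of most loci, one per diploid-derived subgenome. For a gene family this has
two measurable consequences: the family is expected to be roughly three
times the size of its counterpart in a diploid relative, and most family
members should sit in 1:1:1 homoeolog *triads*. Two-line hybrid breeding
adds a second axis: for each cross the F1's expression of a gene can be
compared with its two parents and classified into dominance modes that are
candidate molecular correlates of heterosis. This package implements that
full analysis chain for homology-defined families such as the histone
methyltransferases, plus the promoter/lncRNA regulatory annotations that
usually accompany such studies.

## Family identification

Membership requires passing either of two homology screens, combined as a
union with per-gene evidence flags:

- **Domain screen**: profile-HMM hits kept at E-value strictly below 1e-10,
  optionally restricted to one Pfam accession (SET = PF00856, PRMT5 domain
  = PF05185; a DOT1L = PF08123 screen is the same call with a different
  accession).
- **BLASTP screen**: a hit is kept only if *all* of E < 1e-10,
  bit score > 100, percent identity > 50 and alignment length >
  0.5 × max(query length, subject length) hold. All four are strict
  inequalities, mirroring the "<"/">" wording of the criteria; the coverage
  denominator is the *longer* of the two sequences, the conservative
  reading of "50 % of the longer sequence".

Renaming sorts candidates by (chromosome rank 1A < 1B < 1D < 2A < … < 7D,
unplaced U last, then start coordinate, then gene id) and assigns
`prefix1..prefixN` gap-free; the map is a bijection and invariant to input
order. Protein MW, pI and instability index are computed with Biopython's
ProtParam module (average residue masses + one water; Henderson–Hasselbalch
bisection; Guruprasad dipeptide weights), pinning one widely used constant
set rather than re-deriving it; instability > 40 flags a protein unstable.

## Homoeolog groups and expansion

Group class is a pure function of per-subgenome member counts: (1,1,1) →
triad, two subgenomes with one member each → paired, a single member →
orphan, anything else → other. Multi-copy patterns such as 2:1:1 are *not*
forced into the three canonical rows — they land in "other" so that class
gene counts always conserve the family size. Any member on an unplaced (U)
scaffold also routes the group to "other", since its subgenome is unknown.
Displayed percentages are 100·n_genes/family_size rounded half-up to two
decimals; unrounded values are kept alongside.

Ortholog statistics follow the InParanoid bookkeeping: for each
(focal, partner) pair the group size is n_orthologs/n_groups on the focal
side; the focal species' average group size is the arithmetic mean over
partners and its average in-paralog count is that mean minus one.

The expansion test is a two-category χ² goodness-of-fit: observed
(focal, relative) totals against expected proportions k/(k+1) and 1/(k+1),
df = 1, no continuity correction, significance at p < 0.05. χ² is exactly 0
iff focal = k·relative and grows monotonically with the deviation at fixed
total. The construction (two categories over the summed counts) is the
simplest test consistent with a "deviation from 3:1" question and is stated
here explicitly because several χ² formulations exist.

## Heterosis expression

Relative qPCR expression is 2^−ΔΔCt with ΔCt = Ct_target − Ct_reference per
sample, calibrated against a designated sample. ChIP-qPCR enrichment is
percent-of-input: the input Ct is first shifted by log2(1/input fraction)
dilution cycles, then enrichment = 100·2^(adjusted input − IP Ct).

Expression is maternal-standardised per cross (every value divided by the
mother's replicate mean, so the mother is exactly 1), matching how relative
expression is usually displayed for parent/F1 panels.

**Dominance classification.** Two-sided Welch t-tests of F1 against each
parent at α = 0.05:

| significant vs | F1 mean position        | mode                 |
|----------------|-------------------------|----------------------|
| both parents   | above both              | over-dominant        |
| both parents   | below both              | under-dominant       |
| both parents   | between parents         | additive_or_none     |
| exactly one    | tracks higher parent    | high-parent dominant |
| exactly one    | tracks lower parent     | low-parent dominant  |
| neither        | —                       | additive_or_none     |

"Tracks" means the F1 is statistically indistinguishable from that parent
(the non-significant test); which of high/low it is follows from the parent
*means*' rank, never from mother/father identity — swapping the parents
maps every call to itself. Welch rather than pooled Student is the default
because three biological replicates give no power to check the
equal-variance assumption; the pooled test is available via `equal_var=True`.

The DEG screen applies the same Welch test plus a fold-change gate on
linear values: a gene is differentially expressed in a cross if |FC| > 2
(strictly) and p < 0.05 against at least one parent. This is a deliberate
simplification of count-based RNA-seq inference (negative-binomial
modelling is out of scope); on the package's replicate-mean expression
values it is the matching test. No multiple-testing correction is applied
by default, matching per-gene reporting conventions; results carry raw
p-values so a correction can be layered on.

Trait materials: HP if the F1 trait mean is significantly above both
parents, LP if significantly below both, MP otherwise (MP does not require
non-significance against both — failing the HP/LP criteria is enough).
Gene-set–trait association z-scores each member gene across samples,
averages the set and Pearson-correlates the profile with the trait; this is
a transparent stand-in for WGCNA eigengenes (first principal component),
which coincides with it when member genes are exchangeable. Network
construction itself is out of scope.

## Promoters and lncRNA targets

The promoter is the 2 kb (configurable) immediately 5' of the first CDS
base: genomic [cds_start−2000, cds_start−1] on +, the reverse complement of
[cds_start+1, cds_start+2000] on −, truncated (never padded) at chromosome
edges. Motif scanning is exact IUPAC matching on both strands with
overlapping occurrences reported at 0-based promoter offsets; a palindromic
motif is reported once. Scanning both strands mirrors PlantCARE behaviour;
single-strand mode is a flag.

lncRNA targets: *cis* links every protein-coding gene on the same
chromosome whose edge-to-edge gap to the lncRNA span is ≤ 100 kb
(inclusive; overlap = 0). *trans* links any non-cis pair with
|Pearson R| ≥ 0.90 and p < 0.05 across shared samples; pairs satisfying
both rules are reported once, as cis, so the two sets are disjoint. The
0.90 default is a deliberately strict, configurable cutoff chosen because
reported example links cluster around R ≈ 0.95 and no canonical threshold
exists; zero-variance vectors are skipped with a warning rather than
producing undefined correlations.

## Synthetic data generator

The generator emulates the *structure* of the real data, with planted truth:

- **Genome**: 21 chromosomes (7 per subgenome) of 300 kb plus a 100 kb
  unplaced scaffold, i.i.d. random nucleotides. Coding genes are placed
  sequentially with random gaps in the first 60 % of each chromosome (so
  loci never overlap); "distant" lncRNAs sit near the chromosome end,
  provably farther than the cis window from every coding gene, while
  cis-planted lncRNAs are dropped 5–50 kb downstream of anchor family
  genes. Chromosome length is the one scale parameter: the default
  comfortably holds the default family; larger planted families (e.g. the
  500-gene dominance benchmark) use a longer chromosome.
- **Family**: 47 triads + 3 paired + 5 orphans (152 genes) by default — the
  HKMT-like composition — plus 50 decoys. Hit tables straddle every filter
  threshold: planted members pass each criterion by a 10× margin, each
  decoy fails exactly one BLAST criterion (cycled, recorded in truth) and
  the HMM cut. At margin 0 all planted values sit exactly on the
  thresholds, so the strict inequalities must reject everything — a direct
  probe of boundary semantics.
- **Relatives**: five species with counts Poisson-distributed around
  focal/(k·inflation), k = 3; inflation > 1 plants a genuine expansion
  signal, and a zero-noise mode gives the exact ratio.
- **Expression**: 6 crosses × 3 roles × 3 replicates. Each family gene gets
  one planted dominance mode (cycled over the five), a lognormal base mean,
  and replicate noise of CV 0.1 (lognormal, mean-preserving); the planted
  effect is 4-fold. High/low-parent modes draw which parent is high at
  random. A seed-weight-like trait carries planted HP/MP/LP classes per
  cross; a tiller-like trait is generated per sample with a planted Pearson
  correlation (default −0.6) to the module genes' mean z-profile.
- **lncRNA expression**: each distant lncRNA shares a latent factor with
  one family gene at the configured correlation (0.95 by default) on the
  log scale; cis lncRNAs are independent noise.

One `numpy.random.default_rng(seed)` stream drives everything in a fixed
draw order; identical configs are byte-identical on disk, with no OS
entropy anywhere.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: hit scores are planted, not computed from
sequence, so the tests certify the *filters*, not hmmsearch/BLAST
themselves; expression replicates are exchangeable lognormals with no
count-based mean–variance relation, batch structure or tissue effects; and
genes sharing a planted dominance mode have correlated profiles across
samples, so trans-correlation recovery is checked as "planted pairs are
found", not "only planted pairs are found".

## Numerical and degenerate-input choices

- Displayed ratios/percents: decimal half-up rounding at 2 decimals
  (`round_half_up`); engines keep unrounded values.
- t-tests on two identical constant groups return p = 1 (no evidence)
  rather than NaN; all-zero-variance dominance input with equal means is
  additive_or_none, not an error.
- Pearson p-values come from the exact t-transform (scipy); n ≥ 3 enforced.
- Empty promoters (CDS at a chromosome edge) warn and return the empty
  string rather than failing a whole run.
- Parsers are strict and total on generator output: malformed lines raise
  with the line number; output order is documented (GFF3 models by
  (chromosome, start, id); hit tables keep input order).

## Benchmark problem sizes

The bundled checks run on deliberately desk-scale inputs chosen to keep the
suite fast while leaving comfortable statistical margins: 10,000 random
hits for filter/oracle equivalence, the 152-gene default family for
recovery and retention, 500 planted genes (single cross) for dominance
accuracy, 200 random count pairs for the χ² closed form, and a ~30-gene
genome for strand-symmetry and determinism checks.

## Known limitations

- Homoeolog groups are accepted as input (or planted); tree- or
  synteny-based inference of groups is out of scope, as are phylogeny
  construction and subfamily assignment.
- The DEG screen is not a count model; with real RNA-seq counts it will be
  anti-conservative for low-expression genes compared to EdgeR/DESeq2.
- The dominance decision table inherits the power of three-replicate
  t-tests: with small effects, high-/low-parent dominance degrades to
  additive_or_none before over/under-dominance does.
- The group–trait correlation is not an eigengene; for strongly
  heterogeneous modules the first principal component could differ.
- Motif scanning is exact-match IUPAC only — no position weight matrices,
  no mismatch tolerance.
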