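# Methods

This note documents the models and procedures kirfam implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions that matter when reading
its output.

## Receptor annotation

Transcripts are oriented cDNAs; only forward frames are translated
(standard genetic code). The coding region is the longest ATG-initiated ORF
of at least `min_orf_aa` residues (default 80); when no such ORF exists,
the longest stop-free forward stretch is used and flagged `no_start` —
this mirrors real cDNA sets in which a 5' end was not fully sequenced, and
the flag is never silently dropped.

ITIMs are matched with the immunoreceptor consensus `[ILVS]xYxx[LV]`,
which covers the hexamer variants observed in primate KIR tails (VTYAQL,
VKYTQL, SVYMEL); overlapping matches are all reported with 1-based
positions. The transmembrane helix is located by a Kyte–Doolittle sliding
mean (window 19): the maximal window above 1.6 seeds the span, which grows
while the shifted window mean stays above 1.0. When a transcript has been
mapped to an exon model, the TM exon segment is authoritative for
classification and the hydropathy scan is reported as corroborating
evidence only; a variant whose stem/TM exons are spliced out is therefore
soluble even if an extracellular stretch happens to look hydrophobic.

Receptor class follows standard KIR logic, applied in order:

1. no membrane anchor → **soluble**;
2. cytoplasmic tail ≥ 40 aa with ≥ 1 ITIM located after the TM →
   **inhibitory**;
3. tail < 40 aa with R/K at TM position 4 (numbered from the first TM
   residue) → **activating**;
4. tail < 40 aa, no TM charge, but proline at TM position 11 and threonine
   at position 13 (conserved anchors of adapter coupling in activating
   KIRs) → **putative activating**;
5. otherwise **ambiguous**.

The 40-aa long/short cutoff is a package choice: it cleanly separates
ITIM-bearing tails (≥ ~60 aa in the modelled architecture) from truncated
ones (≤ ~25 aa); no published cutoff exists.

## Splice-variant inference

Each transcript is globally aligned to the concatenated exons of its model
with BLAST-like affine-gap scores (match 2, mismatch −3, open −11, extend
−1); overall identity below 80% is treated as "wrong model". Alignment gap
placement inside repeated sequence is arbitrary, so score-equivalent
deletion gaps are slid to sit cleanly on exon boundaries before
interpretation, preferring (in order) whole-exon deletions, boundary
deletions with canonical dinucleotides (AG immediately 5' of an
alternative acceptor, GT at an alternative donor), then interior
deletions. Calling rules: whole-exon absence → `exon_skip`; 5'/3' partial
absence with the canonical dinucleotide → `alt_acceptor` / `alt_donor`;
an unaligned transcript segment of ≥ 20 nt matching a model intron at
≥ 95% identity → `intron_retention`; anything else → `complex`, never
dropped. A premature termination codon is the first in-frame stop upstream
of the final exon junction; a stop inside the last exon is a natural end.

Transcripts with only substitutions are *alleles*; any splice event makes
a transcript a *variant* of an allele — this split drives naming.

## Phylogenetics

Pairwise distances use the Kimura two-parameter correction
(d = −½ln(1−2P−Q) − ¼ln(1−2Q)) or Tamura–Nei (TN93) with observed base
frequencies; both support a gamma-rate adjustment that replaces each log
with the a((·)^(−1/a)−1) transform. Variances are delta-method. Saturated
pairs (log domain violated) are flagged infinite and rejected by the tree
builder with an explicit pair list. The TN93 implementation is verified
against an independent reference implementation on a frozen pair.

Trees come from Saitou–Nei neighbor joining. Taxa are processed in sorted
label order and Q-criterion ties break to the smallest index pair, so the
output is deterministic and invariant to input order; negative branch
lengths are clamped to zero and logged. On additive matrices NJ recovers
the generating topology and branch lengths exactly (tested against
enumerated additive matrices and cross-checked against scikit-bio).
Bootstrap supports resample alignment columns with replacement; support is
the percentage of replicate NJ trees containing each bipartition,
deterministic given the seed.

Likelihoods (Felsenstein pruning, reversible models JC69/K2P/HKY85/TN93/
GTR, discrete gamma with 4 equal-probability categories by category means,
optional invariant class) are used **only** for substitution-model
selection on the fixed NJ topology — topology search is out of scope by
design; this reproduces the analytical intent (model choice by BIC) at
desk scale. BIC = −2logL + k·ln(sites), with k counting substitution
parameters, 3 for empirical frequencies where applicable, +1 each for +G
and +I, and 1 shared branch-length scale. The candidate grid is the 5 base
models × {none, +G, +I, +G+I} = 20 combinations (reference GUI tools count
24 by enumerating +G+I sub-dialects separately; the extra dialects add no
information here). Non-converged candidates are flagged and excluded.

## Locus calling and nomenclature

Loci are maximal clades of the midpoint-rooted tree whose intra-clade
maximum pairwise distance is at most `locus_distance_threshold` (default
0.02 substitutions/site — between the observed within-locus polymorphism
ceiling of ~0.008 and the inter-paralog divergence floor of ~0.04) and
whose separating bipartition, when bootstrap supports are present, holds
at least `support_threshold` (default 70%, a conventional cutoff). Support
is looked up per *bipartition*, not per node, so near-zero internal edges
inside a tight allele cluster (which necessarily have low support) cannot
fragment the cluster. Labels are dense from 1 in traversal order, stable
under input reordering. With fewer than 3 sequences a single-linkage
fallback applies.

Names render as `<prefix>KIR<n>D<L|S><locus>*<allele>[v<k>]`. Two-digit
allele numbers change only with the encoded protein; synonymous-only
differences become sub-entries of the existing allele. Splice variants
number v1, v2, … in discovery order within their allele (historical
v-numbers are not derivable), and the configuration digit and tail letter
are recomputed from the variant's own annotation, since splicing can
change both. Variants attach to the nucleotide-closest allele at their
locus.

## Diversity, selection, recombination

θ_W = S/(a₁L) per site with the standard variance
θ/(a₁L) + a₂θ²/a₁²; π is the mean pairwise difference per site with the
Nei (1987) no-recombination variance. Complete deletion (drop any column
containing a gap or N) is the default gap policy for diversity tables,
matching common practice; the reported SDs follow the documented formulas
and are not guaranteed to match any particular desktop tool's dialect.
Loci observed once report `-` for all statistics.

dN/dS uses modified Nei–Gojobori counting: per-codon synonymous/
nonsynonymous site fractions weight transitions 2R against transversions 1
(R = 0.5 recovers the classic equal-weight scheme; by default R is
estimated from the data as the pooled transition/transversion count
ratio), with changes to stop codons excluded and positions renormalized.
Pairwise difference counts average over all minimal mutational pathways,
excluding pathways through stop codons unless all pass through one.
Proportions are Jukes–Cantor corrected; pairs at or beyond the 3/4
saturation bound are excluded and counted. Standard errors come from a
codon-column bootstrap (default 1,000 replicates, seeded). The codon
Z-test uses Z = (dS−dN)/√(se²+se²) one-tailed for the purifying
alternative. Sliding-window ω reports windows with dS = 0 as missing,
never 0.

Per-site selection uses SLAC-style counting: ancestral codons by Fitch
parsimony (the top-down pass keeps the parent state when possible and
otherwise minimizes nonsynonymous steps, ties lexicographic), observed
changes summed over branches with pathway averaging, expected
nonsynonymous fraction averaged over all node states at the site, and
one-tailed extended binomial tests in each direction (fractional counts
via the regularized incomplete beta). Calls use p ≤ 0.1 by default, with
no multiple-testing correction — per-site counting tests are conservative
and the threshold matches the study design. Counting tests need deep
sampling: meaningful power for ω ≈ 5 sites requires roughly ≥ 4
substitutions per codon of total tree length (see calibration below).

MaxChi scans every sequence pair: on gap-free, alignment-variable columns
(all columns for a pair, where "variable" is degenerate), a 2×2 chi-square
of matched/mismatched sites in adjacent half-windows (default: one fifth
of scanned sites, minimum 10) is slid across the alignment; the maximum is
the candidate breakpoint and significance comes from permuting site order
(default 1,000 permutations, seeded), Bonferroni-corrected across pairs by
default (configurable, since reference tools differ in their correction
dialect). Fragment boundaries are then refined by a fixed-rate Bernoulli
change-point estimate (rates taken from the fragment core and from the
flanks beyond the search zone) and extended outward by half a mean
informative gap — the change-point MLE stops at the outermost observed
mismatch while the true boundary lies, on average, half a gap beyond it.
Fewer than 4 mismatches is a no-scan result. The triplet scan restricts to
sites informative for a parent pair, locates switches of the closer
parent the same way, and attributes the minor parent; if the recombinant's
identity to the attributed parent inside the fragment falls below 95% the
attribution is reported as "unknown (closest relative X)". Overlapping
candidates per recombinant merge to the union span with the minimum p,
filtered at p ≤ 0.03.

## Synthetic families: what is emulated, what is not

The generator mirrors birth-and-death evolution of a KIR family:

- **Gene structure**: a 10-exon template — 2 signal-peptide exons, one exon
  per Ig domain (D0a, an optional duplicated D0b present in 4D loci,
  probability 0.2, D1, D2), stem, TM, and 2 cytoplasmic exons; all exon
  lengths are multiples of 3, so whole-exon skips are in-frame and
  frameshifts arise only from alternative acceptor/donor use. Anchor
  dinucleotides are implanted so the menu's alternative acceptor (36 nt
  into the D1 exon) and donor (4 nt before the TM exon end) are canonical.
  Full-length products are 416 aa (3D) or 512 aa (4D).
- **Features**: ITIM hexamers VTYAQL/SVYMEL in the cytoplasmic exons;
  hydrophobic TM codons; per-locus receptor archetypes (default 60%
  inhibitory, 20% activating with an arginine at TM position 4, first ITIM
  tyrosine replaced and a truncated tail, 20% putative-activating with
  P11/T13). Non-TM exons draw codons from a globular amino-acid
  composition with strongly hydrophobic residues downweighted, so
  extracellular domains do not mimic membrane helices.
- **Mutation**: K2P substitution (default κ = 4, a primate-scale
  transition bias) with 4-category discrete-gamma site rates (default
  α = 1) drawn once per family so rate variation is consistent across
  branches. Codon-level selection classes (default ω = 0.2 purifying, with
  configurable patches) act by acceptance sampling on proposals —
  nonsynonymous accepted with min(1, ω), synonymous with min(1, 1/ω) —
  and stop-creating or feature-disrupting proposals are rejected.
- **Family structure**: a random duplication history with deep splits
  (uniform on the upper 60% of tree depth), rescaled so the mean
  inter-locus proposal divergence matches the target (default 0.08
  substitutions/site); alleles diverge on a star genealogy with branch
  θ/2 (default θ = 0.004), so expected within-locus π equals θ. Because
  selection rejects proposals, all branch lengths are pre-inflated by a
  probe-based calibration factor (four probe lineage pairs evolved and
  re-measured); realized inter-locus K2P distance stays within 20% of the
  target across seeds. Allele counts per locus default to
  {1: 0.2, 2: 0.5, 3: 0.2, 4: 0.1}, matching a ~2-allele-per-locus family.
- **Splicing**: each allele emits a variant with probability 0.35, drawing
  from a menu of D2/D0a/stem skips, a combined stem+TM skip (soluble),
  the in-frame alternative acceptor, the frameshifting alternative donor,
  and a 45-nt intron retention. The truth class of each variant is derived
  from its realized structure (retained exons, frame, stop position), not
  from the annotation code, keeping the closed-loop tests meaningful.
- **Recombination**: fragments are copied between locus ancestors before
  allele divergence, producing the minor-parent signal the detectors look
  for; breakpoints are recorded in the truth table.

Not emulated: indel evolution outside the splice menu, full 61×61 codon
rate matrices, gene conversion tracts shorter than the scan resolution,
expression levels, and sequencing error. Passing the closed-loop tests
therefore demonstrates correctness of the inference machinery under the
modelled processes, not robustness to alignment error or artifacts of
real cDNA cloning.

## Calibration studies and problem sizes

The packaged calibration studies use deliberately desk-scale settings:
locus-recovery runs use 10-locus families (~30–35 transcripts of
1.25–1.54 kb) over 20 seeds with 100 bootstrap replicates; per-site
selection power uses 48-taxon balanced coding trees (300 codons, branch
length 0.08 — a deeply sampled family giving the counting test the ≥ 4
substitutions/codon it needs, with 10 sites at ω = 5 against a ω = 0.1
background) over 50 seeds; MaxChi calibration uses 1-kb pairs carrying a
copied 300-nt fragment from an 8%-divergent donor, 500 permutations, 50
seeds, with recombination-free 8-sequence families as family-wise
false-positive controls. Production defaults (1,000 bootstrap replicates,
1,000 permutations) are set in `PipelineConfig`.

## Degenerate inputs and edge rules

- Site-coverage filtering is boundary-inclusive (a column at exactly 95%
  coverage is kept).
- Distance matrices with a saturated pair fail tree building explicitly
  rather than silently truncating.
- `nj_tree` requires ≥ 3 taxa; the pipeline falls back to single-linkage
  clustering below that.
- An input with no duplicate sequences is treated as already
  clone-collapsed: the evidence filter (default: keep sequences seen ≥ 2
  times or in ≥ 2 individuals) engages only when the input looks like
  clone-level reads (≥ 1.5 reads per unique sequence), so a coincidental
  duplicate pair cannot erase a unique-transcript data set.
- Within the pipeline, the family alignment is built by projecting each
  transcript onto the shared exon-template coordinate system via its
  splice mapping (model-anchored alignment); tree distances use pairwise
  deletion there, because splice variants would otherwise delete whole
  domains from every sequence under complete deletion.
- ω is reported as missing (never 0 or ∞) wherever dS = 0.

## Known limitations

- The likelihood machinery fits models on a fixed topology only; it is not
  a tree-search engine.
- SLAC-style counting has low power on shallow families; with ~30
  sequences at KIR-scale divergence, expect few significant per-site
  calls.
- The MaxChi pair scan reports the scanned pair, not a directionality of
  recombination; minor-parent attribution requires the triplet scan.
- Variance estimates for θ_W and π follow the standard no-recombination
  formulas; desktop tools differ in dialect, so parenthesized SDs are not
  comparable across tools at the third decimal.
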