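# Methods

octoscope analyses subgenome dominance in an allopolyploid formed from four
diploid progenitor species. Its running example is an octoploid with
progenitor-named subgenomes (*vesca*, *iinumae*, *viridis*, *nipponica*,
with *vesca* dominant), but every species label is configuration. This note
documents the models, the defaults and why, the numerical choices, and what
the bundled simulator does and does not emulate.

## Subgenome assignment from gene trees

Each focal (polyploid) homoeolog is assigned by walking from its leaf toward
the root of a bootstrap-labelled gene tree. The first ancestor whose clade
has support ≥ the threshold (default 80) *and* contains at least one leaf of
a non-ignored diploid progenitor is the qualifying clade:

* exactly one diploid species in the clade → **assigned** to that species;
* two or more → **ambiguous**, and the search stops — climbing higher can
  only add species, so continuing could never sharpen the call and stopping
  preserves monotonicity of assignment counts in the threshold;
* no qualifying ancestor → **no-call**.

Leaves with roles *focal*, *outgroup* or *ignore* are transparent: they
never block the walk, so a sister paralog from the polyploid itself cannot
prevent an assignment. Missing supports are treated as below any positive
threshold (absent evidence is not support); at threshold 0 they pass. For a
multifurcating node each child is one clade and the node qualifies on its
own support. Because the ancestors of a leaf are totally ordered, "smallest
qualifying clade" needs no tie-break; a brute-force enumeration over all
clades containing the focal leaf is kept as a test oracle. Nested nodes
below the qualifying clade are not required to meet the threshold — only the
clade that decides the call must be supported.

Rooting prefers a configurable outgroup list (first species present wins,
rooted on the edge subtending the smallest clade holding all its leaves);
with no outgroup present the tree is midpoint-rooted on unit branch lengths
and flagged, and flagged trees are excluded from headline summaries.

## Chromosome assignment and homoeologous exchanges

Per-gene calls are mapped onto gene order (ordinals, not bp; bp spans attach
only when a GFF3 is supplied). A chromosome's progenitor is chosen by
parsimony: among called species, the one whose adoption as consensus leaves
the fewest maximal discordant runs, with ties broken by call count and
unresolvable ties left unassigned. A plain majority vote fails exactly in
the interesting case — a chromosome mostly replaced by one very large
exchange — whereas the run-count criterion prefers "one big foreign block on
an *iinumae* chromosome" over "many native fragments on a *vesca*
chromosome". The reported consensus fraction is count(assigned)/total
called, which equals the majority fraction except in that pathological case.

HE blocks are maximal runs of genes called to a single non-consensus donor,
bridging up to `max_gap` (default 1) interleaved uncalled or consensus
genes; a call to a *different* donor always closes a run, so heavy miscall
noise fragments rather than merges blocks. Runs with fewer than `min_run`
(default 3) donor-called genes are dropped from headline lists; single-gene
events are reported separately with a flag, since single-gene replacements
are indistinguishable from gene conversion at this resolution. Donor bias is
summarized as a donor × recipient matrix with ratio(d, r) =
count(d→r)/count(r→d), reported in gene units by default and block units on
request; an empty denominator reports `inf`/`nan` rather than guessing.

## Homoeolog expression bias (HEB)

For a pair (A, B) with per-tissue counts x_At, x_Bt, the model is
x_At ~ Binomial(n_t = x_At + x_Bt, p_t). Conditioning on pair totals makes
sequencing depth cancel within a pair, and gene length enters only through
the null proportion q = L_A/(L_A + L_B) — together these realize
"normalization for length and depth" with no tuning parameters, which is why
the binomial was chosen as the likelihood family. The nested hypotheses:

* H0: p_t = q (0 free parameters) — equal expression;
* H1: p_t = p, MLE p̂ = Σx_At/Σn_t (1 parameter) — one consistent scaling
  factor ŝ = odds(p̂)/odds(q);
* H2: p̂_t = x_At/n_t (T parameters) — tissue-inconsistent bias.

Log-likelihood kernels drop binomial coefficients (they cancel in every
ratio) and use 0·ln 0 ≡ 0. D01 = 2(ℓ1−ℓ0) is referred to χ²(1) and
D12 = 2(ℓ2−ℓ1) to χ²(T−1); ℓ0 ≤ ℓ1 ≤ ℓ2 and 2(ℓ2−ℓ0) = D01 + D12 hold to
1e−9 and are asserted in tests. First-test p-values get Benjamini–Hochberg
correction (per analysis run, not per chromosome); the second test is
deliberately uncorrected because its question is a *failure* to reject.
Both tests default to α = 0.01. A pair is *consistent-bias* iff q01 ≤ α and
p12 > α, with direction from ŝ; *inconsistent* iff both reject; otherwise
*unbiased*. Testable pairs require call support strictly above 80 and at
least one read (A+B) in every tissue. Pairs with total count < 20 are
flagged low-power but kept — there is no exclusion rule to inherit. χ²
asymptotics are used throughout; a beta-binomial option exists in the
simulator to measure robustness to overdispersion, but the analysis model
itself is binomial, and an overdispersed likelihood is left as future work.
Summaries histogram log2 ŝ (the model estimate, not an FPKM ratio; the FPKM
route is available separately) per dominant-vs-other pairing with counts of
significantly biased pairs on each side. Missing lengths fall back to
q = 0.5 with a warning.

## Fractionation and tandem arrays

Retention is a binary presence vector per subgenome over the ancestral gene
order, smoothed with 100-gene sliding windows. The window step is not
dictated by anything in the data, so the default is step 1 — maximally
smooth, matching a continuous retention curve — and configurable. Windows
never span chromosome boundaries because vectors are per chromosome.
Content differences are percent-more(d, s) = 100·(count_d − count_s)/count_s.
Tandem arrays are maximal same-family runs with successive members at most
10 genes apart in rank order ("distance" is gene-rank, not bp); singletons
are not arrays. A transitive-closure brute force serves as the test oracle.

## TE density and comparative statistics

TE density of a gene is the fraction of bp covered by the merged union of TE
intervals within the gene body ± flank. The flank default is 2,000 bp — a
promoter-scale neighborhood; "near genes" has no canonical width, so it is
exposed as configuration. Merging first makes density invariant to how the
annotation fragments a repeat. All internal coordinates are 0-based
half-open; GFF3's 1-based closed convention is converted only at the I/O
boundary, with round-trip tests.

Density–expression association uses Spearman rank correlation (undefined on
constant vectors — an explicit error). Subgenome density distributions are
compared with pairwise two-sample KS tests; the "lowest-density" subgenome
is the smallest-mean sample, reported with a flag saying whether every
pairwise KS test against it rejects at α. Category bias across the four
subgenomes uses a χ² goodness-of-fit with df = 3; expected weights default
to uniform at the function level, while the pipeline passes subgenome
gene-content proportions so the test asks for bias *beyond* gene-number
differences (a uniform-weights run reproduces the naive test).

## The simulator

`simdata` generates, under one seed and with byte-identical reruns: a
four-subgenome gene order (ancestral order thinned by per-subgenome
retention, adjacent tandem duplications, donor-biased HE blocks that
overwrite recipient origins and are kept non-adjacent so truth blocks are
unambiguous), TE intervals (one per gene window, Beta-distributed target
density by origin), gene trees (fixed 6-leaf topology per gene; the focal
leaf is sister to its true origin's relative with probability
`tree_signal`, supports drawn from concordant/discordant ranges), and
homoeolog pair counts (Poisson pair totals log-linear in TE density with a
negative coefficient, binomial splits under an H0/H1/H2 mixture; each gene
appears in at most one pair so the count matrix is consistent with per-pair
truth).

Defaults are chosen once as the study conditions: retention 0.95 / 0.83 /
0.80 / 0.79 (dominant ≈ 14–20% more genes than the others), HE donor
weights 9:1:1:1, 30 HE events of 5–25 genes, tree signal 0.9 with
concordant supports 85–100 and discordant 40–90, T = 3 tissues at ~500
reads per pair, mixture 0.7/0.2/0.1 with 70% of biased pairs favoring the
dominant subgenome, TE density Beta(2, 8) for the dominant vs Beta(4, 6)
for the others, TE effect −2 on log abundance. The default scale — 4
subgenomes × 2 chromosomes × 500 ancestral genes (≈3,500 genes after
fractionation) — runs the full pipeline in well under a minute on one CPU;
larger scales are plain configuration.

What the simulator does **not** emulate: sequences (trees are
topology-first with parametric supports, not built from simulated
alignments), realistic gene-tree shapes (one fixed 6-leaf topology rather
than variable taxon sampling), read-level artifacts (mapping bias, multi-
mapping, positional coverage), linked retention (losses are independent per
gene, not fragment-wise), bp-accurate HE breakpoints, and overdispersion
beyond the optional beta-binomial. Passing tests therefore demonstrate that
the algorithms recover the structures they model under their own
assumptions — not that real octoploid data meet those assumptions.

## Numerical and degenerate-input choices

* Supports are integers 0–100; non-numeric or out-of-range labels are parse
  errors, absent labels stay absent.
* ŝ is 0 or inf when p̂ hits 0 or 1; log2 histograms drop non-finite values
  but keep the pairs in counts.
* Chromosomes with no calls, or tied by both run count and call count, are
  unassigned (fraction 0).
* χ² with any zero expected weight is an error; expected counts below 5
  warn.
* BH on an empty p-value vector returns empty arrays.
* Retention windows require window ≤ vector length; presence vectors must
  be strictly 0/1.

## Known limitations

* The ambiguity rule stops at the first qualifying clade; an original
  implementation that climbs past ambiguous clades would assign strictly
  more (but less conservative) calls.
* Gene-ordinal HE coordinates mean block sizes are in genes; bp sizes
  depend on the supplied annotation.
* The binomial HEB model understates variance if biological replicates are
  collapsed; the flagged low-count pairs and the beta-binomial simulator
  switch are the tools for judging that risk.
* KS p-values are asymptotic; with very few genes per subgenome the
  "lowest density" flag should be read qualitatively.
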