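# Methods

## Putative-AMP scanning

Each residue carries an "antimicrobial index"; because the index is modelled
on IC50-like potency data, **low values mean antimicrobial**. A sliding
window of `window_length` residues (default 7) computes the mean index at
every position; maximal runs of consecutive windows with mean strictly below
`threshold` (default 0.225) are merged into one stretch covering all their
residues, and stretches shorter than `min_stretch` (default 12) are
discarded. Coordinates are 0-based, half-open throughout.

The shipped per-residue index is a stand-in, not a reproduction of any
published predictor's table: cationic (K, R) and bulky hydrophobic
(W, F, I, L, V, Y) residues score 0.05–0.14, the remaining residues
0.60–0.95. The deliberately wide gap puts random background sequence far
above the threshold (background mean ≈ 0.50, s.d. of a 12-residue mean
≈ 0.10, so a spurious stretch needs a ≈ 3 σ excursion sustained over
several overlapping windows) while motifs built from the low subset sit far
below it. Any other index can be supplied as a TSV; precomputed peptide
tables from an external predictor bypass the scanner entirely. The ambiguous
residue X scores the mean of the 20 standard values. Only curated entries
(UniProt `sp|` headers, or everything under `--assume-curated`) are scanned.

## Peptide clustering

Greedy, longest-first: each peptide joins the first cluster whose
representative is ≥ 80 % identical, else founds a new cluster; the
representative is therefore always the longest member and the result is
deterministic. Identity is the maximum number of matched residues over all
global alignments (match 1, mismatch 0, no gap penalty — equivalently the
longest common subsequence) divided by the shorter sequence's length. This
convention is symmetric and reproducible; it is slightly more permissive
than a gap-penalized aligner, which only matters near the threshold. The
"> 80 %" cutoff is implemented as ≥ 0.8 (the common `-c 0.8` semantics);
`strict=True` and a longer-sequence denominator are available. Duplicate
peptides within one taxon are kept: cluster-level edge counting deduplicates
them anyway. Greedy clusters are always refinements of single-linkage
components at the same threshold (tested); they are not claimed to match any
external tool's exact boundaries.

## Networks

**Shared-AMP network.** Edge weight between two taxa = number of distinct
clusters containing at least one peptide from each (`count_mode="pairs"`
counts cross-taxon member pairs instead, for sensitivity analysis). Taxa
with no shared clusters stay in the graph as isolated nodes, which matters:
isolation maximizes the Die score. Genus-level networks aggregate species
profiles (peptides concatenated, protein counts summed) before clustering
and counting, using a supplied species→genus map or the binomial's first
word.

**Co-occurrence network.** Counts are converted to per-sample proportions;
pairs whose correlation satisfies the sign, |ρ| ≥ `rho_cut` (default 0.4)
and p ≤ `p_cut` (default 0.05, raw) gain an edge weighted |ρ|. Spearman is
the default (rank-based, robust on compositional proportions); Pearson with
a two-sided t-approximation is selectable, as is Benjamini–Hochberg
correction (off by default, matching the raw-p convention of the cutoff
pair). Constant taxa are excluded with a warning. Negative-sign networks can
be built but are not part of the default validation path. The bi-directed
transform gives every undirected edge (i, j) the two arcs i→j and j→i
weighted by the source node's relative abundance — mean per-sample
proportion over the group, rescaled by the maximum into (0, 1] so that
out-strengths stay commensurate with max-normalized shared-AMP weights and
one Die implementation serves both networks. Zero-abundance sources would
produce zero-weight arcs and are dropped.

## Die score

`D_i = (N_i − S_i)/N_p` with `N_p = (n²−n)/2`, `N_i = N_p − deg_i`; for
bi-directed input, degree and strength use out-edges only. With raw
cluster-count weights S_i can exceed N_p and push D_i below −1; dividing all
weights by the maximum restores the advertised [−1, 1] range, so
`normalize_weights=True` is the default and the raw mode is kept, flagged,
for sensitivity analysis. z-normalization (mean 0, sample SD 1) happens per
network over its full node set, before intersecting with the partner
network. If every raw score coincides (e.g., an edge-less network) the
z column is NaN with a warning rather than an error.

## Validation statistics

Ranking is ascending with average ties (lowest Die = rank 1);
`Dist = |rank_BW − rank_MB|`. Skewness is the type-2 sample statistic
`G1 = g1·sqrt(n(n−1))/(n−2)`; the positive-skew verdict is `G1 > 0.4` OR
median strictly closer to Q1 than to Q3, with linear-interpolation
quartiles — the histogram criterion is visual only and is emitted as a plot,
not scored. Extreme-value Pearson selects the k highest and k lowest taxa by
the BW z-score (ties broken lexicographically by taxon id); with 2k = m it
reduces to the plain Pearson correlation, and with k = 1 the two-point
correlation is returned as its analytic sign (±1) rather than through the
floating-point formula. The Wilcoxon signed-rank test runs on the paired
rank lists, two-sided, zeros dropped; the exact null distribution is used up
to 25 informative pairs when tie-free, otherwise the normal approximation
with continuity correction (rank differences tie often, so the approximation
is the usual branch). Note the signed-rank test is a location test: a fully
reversed ranking has symmetric differences and is *not* flagged — that case
is caught by the extreme-value correlation and the skew verdict instead.

## Synthetic benchmark

The generator emulates the hypothesis' statistical structure, not real
biology: taxa are partitioned into compatibility blocks (default sizes
6/3/2/1 over 12 taxa — deliberately unequal, so the Die score has a
gradient to rank); every taxon carries its block's 3 motifs (20-mers from
the low-index residue subset, each copy independently mutated at rate 0.02,
keeping expected identity ≈ 0.98) planted into distinct background proteins
(10 per taxon, 120 residues, uniform over the 20 amino acids), plus 2
private motifs. Abundances over 40 samples share a lognormal(σ = 1) latent
factor per block with negative-binomial (size 5) counts around
baseline × factor; `discordant` mode reverses the taxa order against the
same block-size profile, so members of large AMP blocks become
co-occurrence loners and vice versa — a naive independent reshuffle would
itself produce positively skewed Dist (the absolute difference of two
independent rankings is right-triangular) and would be a broken negative
control. `null` mode makes every taxon independent.

Defaults were fixed with `scripts/calibrate_synth.py` over 20 seeded
replicates: concordant recovery (positive skew, k = 1 extreme r = 1,
Wilcoxon p > 0.05) in 19/20, discordant skew-verdict failure in 11/20 —
the verdict's lenient OR-design lets chance quartile asymmetry rescue some
discordant replicates, which is a property of the verdict, not of the
generator — and within-block Spearman ρ > 0.4 for 97 % of block pairs.
These problem sizes (12 taxa, ~60 peptides, 40 samples) keep a full
pipeline replicate well under a second while exercising every stage.

What the benchmark does *not* emulate: phylogenetic sequence correlation,
realistic proteome composition, compositional artefacts of deep 16S data,
or sparse/zero-inflated abundance structure. Passing it shows the pipeline
recovers planted concordance, not that the biological hypothesis holds.

## Worked reference table

The packaged `nash_die_scores.tsv` is the published ten-genus excerpt of a
NASH gut-microbiome case study: z-normalized Die scores from both networks,
the genus ranks within that study's full intersection (hence ranks up to
32 among ten rows), and the Dist values. Tests reproduce every Dist value
from the printed ranks and check that re-ranking the printed scores is
order-consistent with the printed ranks; the absolute printed ranks
themselves are not re-derivable from the excerpt alone.

## Degenerate inputs and numerical choices

Empty FASTA → empty record list; all-uncurated proteome → warning and an
empty profile; sequence shorter than the window → no hits, not an error;
zero-SD score vectors → error in `normalize_scores`, NaN-with-warning inside
`die_scores`; empty taxon intersection → error; all-zero rank differences →
degenerate Wilcoxon p = 1 with warning. Ties are broken deterministically
everywhere (lexicographic taxon ids; longest-then-lexicographic peptides),
so every pipeline output is reproducible byte-for-byte for a fixed seed.
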