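# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open on the plus strand of a
scaffold; GFF3 (1-based closed) is converted on read, BED is native.  The
TSS of a gene is `tx_start` on the plus strand and `tx_end − 1` on the minus
strand.  TSSs are deduplicated on the full `(scaffold, position, strand)`
key: downstream analyses are strand-directional, so two genes starting at
the same base on opposite strands are distinct initiation events.  Ambiguity
codes in input sequence become `N`; soft-masked (lowercase) bases are
uppercased and retained, since none of the statistics here depend on repeat
masking.

## Gene density

Scaffolds at least as long as the window (default 50 kb) are tiled with
full-length non-overlapping windows from coordinate 0; the trailing
remainder is dropped so every window measures the same amount of sequence —
a per-window count is then directly "genes per 50 kb".  A TSS at position
*p* is counted in the unique window with `start ≤ p < end`.  A window with
zero TSSs is a gene desert; the desert percentage is reported over tiled
windows.  Mitochondrial scaffolds are removed by a configurable id regex
(default `MT|mito|chrM`).  %AT is computed over unambiguous bases.  Intron
counts per gene are `n_exons − 1` (genes without exon structure contribute
zero) and intron sizes are the gaps between consecutive exons; with no
introns at all the mean size is reported as 0 with a warning rather than
NaN, so summary tables stay numeric.

## Core promoters and filters

The promoter window spans `upstream` bases before and `downstream` bases
after the TSS (defaults 150/50), reported 5′→3′ on the gene's sense strand
with the TSS at sense offset 0 (sequence index = `upstream`).  On the minus
strand the genomic interval is `[tss − downstream + 1, tss + upstream + 1)`
and the extracted sequence is reverse-complemented.

Only genes with an annotated 5′ UTR (CDS start strictly downstream of the
TSS in the sense direction) have a trustworthy TSS; others are rejected up
front.  Remaining filters, in precedence order: window off the scaffold;
overlap with any run of `N` (any single `N` by default — the strictest
reading of "gap"); scaffold length ≤ 10 kb (strict); scaffold carrying a
CpG island ≥ 10 kb; overlap with any other extracted promoter, in which
case *both* members of the pair are dropped.  Each promoter is either
retained or carries exactly one rejection reason.

CpG islands are called with the classic sliding-window criteria: 200 bp
windows with GC fraction ≥ 0.50 and observed/expected CpG
`(#CG·L)/(#C·#G) ≥ 0.60`, merged into maximal intervals.  All thresholds
are configurable; only the ≥10 kb length gate is specific to the
contamination use here, where a long island on a scaffold of an AT-rich
assembly is taken as a sign of bacterial sequence.  The filter is applied
per scaffold (contamination is a property of the assembly unit, not of one
promoter).  Note that *uniform-composition* random DNA satisfies these
criteria nearly everywhere — the island definition is only meaningful
against an AT-rich background, which is also why the synthetic default is
64.2% AT.

## Orientation and directionality

Adjacent gene pairs (consecutive after sorting by `tx_start`, ties by
`tx_end`) are head-to-head when the left gene is on the minus strand and
the right on plus (divergent), tail-to-tail for the converse (convergent),
and head-to-tail otherwise.  The summary table counts overlapping pairs
(`left.tx_end > right.tx_start`), non-overlapping pairs, and non-overlapping
pairs with intergenic gap < 1 kb; category percentages are taken over all
regions and over overlapping + near regions, rounded half-up to one
decimal (the convention of published genome-statistics tables).

A head-to-head pair with TSS-to-TSS distance ≤ 1 kb (inclusive; overlapping
pairs included) is a bidirectional-promoter candidate.  If both genes carry
a retained promoter, both are `bidirectional`; if exactly one does, it is
`putative_bidirectional` (divergent partner present but without a usable
promoter annotation); retained promoters in no such pair are
`unidirectional`.  The classes partition the retained set by construction.

## Motif models and scanning

A 4×w count PFM becomes a log-odds PWM via
`score(b, j) = log2(((pfm[b,j] + pc·bg[b]) / (N_j + pc)) / bg[b])` with
pseudocount `pc = 0.25` and background `bg` (uniform unless a genome
composition is supplied).  A window is a hit when its score is at least
`score_threshold × max_score` (default 0.8 — common practice, configurable
per motif; a small epsilon keeps the exact consensus included at threshold
1.0).  IUPAC consensus scanning (with `U ≡ T`) matches degenerate classes
exactly via overlapping regex lookahead.  In both modes windows containing
`N` can never match (the PWM gives `N` a −∞ row).  All overlapping and tied
hits are reported; there is no greedy masking.  Hit coordinates are the
5′-most base of the site on the scanned strand, for antisense hits too.

Positional profiles count hits per 10 bp bin across −400..+100 around each
TSS (bins half-open, the TSS in the bin starting at 0), divided by the
number of anchors profiled; anchors with truncated or gap-containing
windows are excluded.  Composition profiles report per-offset base and
dinucleotide frequencies over the same windows; "CpG" is C immediately
followed by G on the sense strand.

## Co-occurrence

Enrichment is promoter-level presence/absence (≥1 hit of each motif).  With
`n` promoters tested, `n_a`/`n_b` carrying each motif, and `n_both`
carrying both, the expected overlap under independence is `n_a·n_b/n` and
the ratio is observed/expected.  Significance is the exact hypergeometric
upper tail; a seeded label-permutation mode is provided as a cross-check.
Because the exact p-value is discrete (hence conservative), calibration
tests use the standard randomized p-value `P(X > k) + U·P(X = k)`, which is
exactly Uniform(0,1) under the null; reported analysis p-values remain the
exact ones.

## U1–PAS cumulative profiles

For each anchor the 500 bp flank is read 5′→3′ *away* from the anchor,
starting at distance 1 (the anchor base itself is excluded):
`sense_downstream` on the coding strand, `antisense_upstream` on the
non-coding strand — the template of any divergent transcript.  Hits are
binned by distance in 10 bp bins, normalised per anchor, and accumulated by
prefix sum; monotonicity of the cumulative vector is asserted on every run.
All hits are counted (not at most one per bin), which keeps the profile
mass equal to the total hit count.  Anchors with truncated flanks are
dropped and counted.  Profiles can be anchored on TSSs or on the 5′ ends of
motif hits found around TSSs (e.g. GC-box positions), via the same code
path.

## Synthetic genomes

Background sequence is i.i.d. mononucleotide with configurable AT fraction;
the default 0.642 matches the AT-rich genome this analysis style was
developed for, as do the default gene-structure parameters (4.2 introns per
gene, ~280 bp median intron, ~587 bp median intergenic distance, and a
22.3/21.0/56.7% head-to-head/tail-to-tail/head-to-tail orientation
mixture).  Genes are placed as two-gene cassettes whose internal pair is
drawn from the orientation mixture; head-to-head cassettes get a lognormal
TSS-to-TSS spacing.  Cassettes are separated by larger gaps, and only
within-cassette pairs carry configured orientation labels — an i.i.d. draw
over *all* consecutive pairs is impossible, because a head-to-head pair
forces its left gene onto the minus strand, so a stationary strand process
would force equal head-to-head and tail-to-tail rates.

Motif planting overwrites promoter bases with a realised consensus
(degenerate positions sampled uniformly within class) at a normal-
distributed sense offset clipped to the window; PAS/5′SS planting draws
Poisson site counts per flank and direction at per-kb rates and writes each
site on the strand the corresponding cumulative scan reads.  Planted sites
never overlap one another (collisions are redrawn a bounded number of
times, then raised).  Everything is deterministic under a fixed seed, and
every planted feature is recorded with exact genomic coordinates.

What the generator does **not** emulate: dinucleotide structure (beyond an
optional AT-rich background), repeats and transposons, transcription-unit
overlap on opposite strands, UTR introns, and expression evidence.  Passing
planted-truth tests therefore demonstrates correctness of the measurement
chain, not performance on real assemblies.

## Test and simulation sizes

The planted-motif recovery runs on a 2 Mb genome (4 × 500 kb) with 2,000
genes; fitting 2,000 genes into 2 Mb requires a compact gene structure
(1 intron/gene, ~120 bp exons, ~300 bp intergenic), chosen to mirror
gene-dense unicellular-like genomes.  The PAS-asymmetry recovery instead
uses a sparser layout (4 × 1.2 Mb, ~800 bp intergenic, 1.5 kb cassette
separation) so that anchor flanks are disjoint: with densely packed
same-strand neighbours the 500 bp windows overlap and planted sites are
counted from two anchors, inflating both strands' totals and biasing the
measured rate ratio toward 1.  That simulation also uses a GC-rich
background (AT 0.30): on a 64.2% AT background, chance `AWTAAA` matches
occur at ~2.2/kb (analytically) and would dominate plantable signal,
whereas at AT 0.30 the chance rate is ~0.02/kb.  The co-occurrence null
calibration uses 1,000 sets of 100 promoters with independent planting at
rate 0.5.

## Known limitations

- GFF3 reading targets well-formed `mRNA`/`transcript` features with `exon`
  and `CDS` children and common biotype attributes; exotic attribute
  dialects may need pre-normalisation.
- The CpG-island caller is single-threaded and allocates O(scaffold) arrays;
  chromosome-scale scaffolds (>100 Mb) work but are memory-hungry.
- PWM scanning reports all windows above threshold; for highly degenerate
  matrices at low thresholds the hit list can be large.
- The bidirectional classification is annotation-based; it cannot see
  divergent non-coding transcription that only expression data would reveal.
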