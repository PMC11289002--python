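# Methods

## Region model

A reference topology places T transmembrane (TM) intervals on the ungapped
coordinates of one named reference sequence, together with the membrane side
of its N-terminus. The lipid-water-interface (LWI) is operationalised as a
residue rule: the `flank_width` (default 5) reference positions immediately
N-terminal and C-terminal of each TM. The physical interface is a layer of
roughly 6–10 Å along the membrane normal; five residues of an interfacial
segment is the conventional sequence-space approximation and the only
definition used here.

Windows are clipped at the sequence termini and never enter a TM interval;
either event sets a truncation flag. When the loop between helices *i* and
*i*+1 is shorter than twice the flank width, the facing flanks share
residues. Those residues count for **both** flanks in per-flank statistics
(so each flank still describes its own helix end), while pooled selectors
(`LWI_total`, `LWI_inner`, `LWI_outer`) deduplicate columns — otherwise
short loops would be double-weighted in aggregate frequencies. The analytic
number of shared residues for a loop of length L is max(0, 2w − L), clamped
to L when the loop is shorter than one flank (a loop cannot share more
residues than it has).

Membrane sidedness alternates at every TM crossing starting from the
N-terminus side; with an inner N-terminus the inner flanks of a 6-TM subunit
are N-TM1, C-TM2, N-TM3, C-TM4, N-TM5, C-TM6. All regions are defined on
the reference and transferred to every species through alignment columns:
insertions relative to the reference are invisible to region statistics,
which matches how regions are selected from an alignment in practice.

## Composition statistics

Frequencies pool every non-gap, non-X residue at the selected columns over
the sequences of a stratum (a phylum group, or `all`); each residue is one
observation. A per-sequence-then-average mode is provided because frequency
plots in the literature are ambiguous between the two conventions; the
pooled mode is the default and the one the tests pin down.

Group totals use the published seven-member hydrophobic set (Y, I, L, M, F,
C, W) and thirteen-member hydrophilic set, kept verbatim even where
unconventional (Val listed hydrophilic, Cys hydrophobic); His belongs to
both the hydrophilic and the positive set, as listed. `AminoAcidScales.
conventional()` substitutes textbook sets. The hydrophilic total is defined
as the exact complement of the hydrophobic total so the two always sum to 1
in floating point. Charge ratios return `inf` for a zero denominator and
`nan` for 0/0. Mean hydropathy is the frequency-weighted Kyte–Doolittle
index; the Wimley–White interface ΔG values are shipped only as a plot
ordering, never entering a statistic. Snorkeling capability (default
{K, R, W, Y}) is an annotation layer, not a statistic, since no formula
for a "snorkeling score" is established.

Enrichment calls compare observed frequency with a background
("natural abundance") table: `enriched`/`depleted` by sign, `absent` when
the letter never occurs (log₂ ratio −inf). The packaged default background
is the UniProtKB/Swiss-Prot proteome-average composition, normalised to sum
to 1; it is an explicit, swappable input because no single canonical source
exists for such baselines. Loading renormalises totals within 1e-3 of 1 and
rejects anything further off.

## Conservation

The score is the pairwise p-distance: mismatches over compared sites,
restricted to the region's columns, uniform rates, no model correction —
0 is identical, 1 fully diverged. Per analysed region (not globally), a
sequence with more than 50% gaps/X in the region is dropped and logged (the
"improper sequence" rule; threshold configurable), then *complete deletion*
removes every column still holding a gap or X in any retained sequence. A
pairwise-deletion mode exists for full-length comparisons across strata
with non-overlapping tails.

Variances come from a column bootstrap: B resamples of the retained columns
with replacement (default B = 1000), recording the per-pair variance of
replicate distances; replicate draws are independent and governed by a
single integer seed, making results bit-reproducible. The bootstrap uses a
float32 matrix product over the pair × column mismatch indicators, which
keeps a 1225-pair, ~900-column, 1000-replicate run in the low seconds.

## KL logos

Column distributions use background-weighted pseudocounts,
p_a = (c_a + w·q_a)/(n + w) with default w = 1, so no observed letter ever
hits log 0; w = 0 is allowed and gives raw frequencies with unobserved
letters contributing zero height by the p log p limit. Letter heights are
the signed per-letter KL contributions p_a log₂(p_a/q_a); their sum is the
position's divergence D(p‖q) ≥ 0. The TSV height table is the canonical
output; the SVG rendering (letters stacked by |height|, largest at the
axis) is best-effort presentation.

## Chi-square reports

Pearson's statistic without continuity correction, dof = (r−1)(c−1),
p-values from the χ² distribution; degenerate tables (all-zero margins)
are errors, and all-zero letter rows are dropped at assembly. The default
table is letters × flanks within a stratum; letters × strata over a shared
region is also emitted. No multiple-testing correction is applied by
default (raw statistics are reported); a Bonferroni option exists.

One calibration caveat is inherent to star-phylogeny data: residues of the
same alignment column share an ancestor, and this clustering — identical
across strata — makes stratum letter counts underdispersed relative to a
multinomial at moderate substitution rates, so raw chi-square p-values are
conservative there. The null-calibration test therefore runs at a
near-saturating rate, where residues are effectively independent draws from
the stationary composition and the χ² null applies; on real families the
statistic should be read as descriptive, not as an exact test.

## Synthetic families

The generator emulates the statistical structure of a vertebrate channel
family without simulating an aligner or indel evolution in the core:

- **Star phylogeny.** All species descend independently from one ancestor.
  This keeps the expected pairwise distance closed-form,
  E[d] = (2r − r²)(1 − Σ_a p_a²) for branch substitution probability r and
  stationary composition p, which the tests verify by Monte-Carlo.
- **Substitution to stationarity.** A substituted site redraws from its
  region class's stationary distribution, so planted compositions are exact
  stationary targets while distances grow with the rate.
- **Quota ancestors.** Ancestor residues are laid down by a largest-
  remainder quota over the stationary distribution, then shuffled. On a
  star tree the shared ancestor dominates the sampling variance of pooled
  region frequencies (a 30-site region has only 30 independent ancestor
  draws); the quota removes that term so planted compositions are
  recoverable at the advertised binomial precision. The cost is integer
  granularity: a letter with sites × p below 1 may get no ancestor site, so
  composition-recovery checks need regions with enough sites per letter.
- **Phylum-specific tails.** Terminal tails get their own ancestor, length
  and composition per phylum (distant clades' tails are not homologous),
  with per-species length jitter; tails are gap-padded into the alignment,
  N-tails anchored at TM1. The gapless core spans one flank width before
  TM1 through one flank width after the last TM.

The `catsper_like` fixture fixes the study conditions: 5 phyla × 10
species; substitution rates TM 0.05, LWI 0.20, loop 0.30 per site; tail
rate 0.15, chosen so that full-length conservation sits between TM and LWI
as observed for this kind of subunit; inner-LWI composition with Phe at
exactly 0.20 and strong Trp/Tyr enrichment; Cys weight zero at both LWI
classes; mammalian N-tails of 350 residues with His at 0.17 versus 120 for
fishes. `null_uniform` (uniform compositions, equal near-saturation rates)
gives every statistic nothing to find; `high_divergence` runs the
channel-like compositions at saturation. Fixtures are generated
deterministically from fixed seeds at call time.

What passing on these families does and does not show: the generator has
no indels in the core, no rate variation within a region class, no
covariation between sites, and a star topology instead of a real tree —
so the tests demonstrate correctness of the statistics and recovery of
planted signal, not robustness to alignment error or phylogenetic
non-independence. On real data, pairwise distances are correlated through
shared internal branches and the chi-square caveat above applies.

## Numerical choices

- Coordinates are 1-based inclusive at every user-facing boundary.
- `X` is permitted, never counted as any amino acid, excluded from
  composition denominators and treated as missing by deletion rules.
- Degenerate cases flag rather than raise where a value can be carried:
  empty residue pools give degenerate profiles, incomparable pairs give
  NaN distances; fewer than two usable sequences is an error.
- Distances are computed from integer mismatch counts in float64; only the
  bootstrap matrix product runs in float32.
- All TSVs are written with `%.10g` floats and fixed column order;
  the manifest contains no timestamps — identical inputs and seed produce
  byte-identical outputs.
- Chi-square, KS and distribution quantiles come from scipy; FASTA IO from
  Biopython; the KL logo construction and the p-distance/bootstrap engine
  are implemented here and cross-checked against independent oracles in
  the test suite.

## Problem sizes

Default test and acceptance runs use the bundled fixture scale — 50
sequences, ~680 alignment columns, bootstrap B in the hundreds for
determinism checks and 1000 where variances are reported; the calibration
study uses 200 replicate families of 45 sequences. These sizes make the
full suite run in seconds while leaving every statistical check
well-powered at its stated tolerance.

## Known limitations

- Flank insertions present in non-reference species are invisible (regions
  are reference-anchored by design).
- The 50% gap-fraction drop rule is a declared stand-in for the various
  "gaps/missing data" treatments of desktop phylogenetics software; the
  threshold is configurable and logged.
- Only p-distance is offered (no JTT/WAG corrections, no trees), and only
  frequency-versus-background "selection" language is supported — no
  dN/dS or site-model tests.
- The logo rendering is presentation-only; the height TSV is the tested
  artifact.
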