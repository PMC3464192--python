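# Methods

## The disorder model

`disomut` scores intrinsic disorder with a windowed propensity predictor.
Each residue type `a` carries a TOP-IDP disorder propensity `s(a)` (shipped
in `src/disomut/data/top_idp.tsv`; higher = more disorder-promoting, from
W = −0.884 to P = +0.987). For a sequence `x₁…x_L`:

1. `w̄(i)` = mean of `s(x_j)` over a centred window of length `w` (default
   21), mirror-padded at the termini;
2. `ps(i) = 1 / (1 + exp(−k · (w̄(i) − m)))` with gain `k` (default 8 per
   propensity unit) and midpoint `m` = the mean of the 20 scale values.

A residue is called **disordered** iff `ps ≥ 0.5`, **ordered** otherwise;
the boundary belongs to disorder by convention and every call site uses the
same rule.

Design intent: the predictor is a *transparent stand-in* for neural-network
disorder predictors. It reproduces the structural features the downstream
analysis depends on — region-level smoothing, strict monotonicity in
residue propensity, determinism, sensitivity of borderline sites to single
substitutions — and deliberately claims no numerical equivalence with any
published tool. Consequences worth knowing:

- *Window 21* smooths to region-level signal, comparable in scope to
  long-disorder predictors; a single substitution can move `ps` at a site
  by at most `k/4 · (s_max − s_min)/w ≈ 0.18`, so only sites within that
  margin of the threshold can flip. Real predictors are sharper (their Δps
  dynamic ranges differ per tool); no attempt is made to match them.
- *Steepness 8* spreads scores over (0, 1) such that poly-P scores
  confidently disordered and poly-W confidently ordered (the calibration
  property asserted in the tests).
- *Mirror padding* keeps the profile length equal to the sequence length
  and makes homopolymer profiles exactly constant; profiles of reversed
  sequences are exactly reversed.
- Sequences too short to mirror the window (`L ≤ w/2`) are scored at the
  full-sequence mean everywhere.
- Masked residues (`X` under the "mask" input policy) score at the scale
  midpoint, i.e. neutrally.

External predictors are supported as dense per-residue score tracks
(wild-type, and per-mutation mutant tracks); missing positions are an
error, never imputed, because a silent gap would shift every downstream
coordinate.

## Transition classification

Mutants are rescored on the **full** mutated sequence; only the mutated
residue's score enters the class decision (D→O iff `ps_wt ≥ 0.5 > ps_mut`,
etc.), with `Δps = ps_wt − ps_mut`. Score changes at neighbouring residues
are real (any windowed or context-sensitive predictor produces them) but
never affect the class; full mutant profiles are still produced because the
MoRF analysis needs them. Δps dispersion is summarized by tail fractions
(default cutoff |Δps| ≥ 0.2) and unbiased sample excess kurtosis (hence the
n ≥ 4 requirement).

Secondary-structure transition tables consume external H/E/L state tracks
with 0–9 reliability indices; a pair is counted only when both the before
and after assignment have reliability ≥ 4 (configurable), and the
reliability is taken at the mutated residue only — whether a window-based
reliability rule would be more faithful to the upstream predictor is left
open, so the residue-only convention is the documented one. Filtered pairs
are counted, not dropped.

Substitution matrices are 20×20 wild-type (rows) × mutant (columns) counts
per stratum (dataset × transition class), zero diagonal by construction,
with rows/columns ordered along the Vihinen flexibility scale
(rigid → flexible) by default, or alphabetically.

## α-MoRF detection and impact

Stage 1 scans the order/disorder call track for maximal ordered runs of
length 5–25 flanked on both sides by ≥ 10 consecutive disordered calls
(all three bounds config-exposed; runs touching a terminus lack a flank and
are rejected). These defaults encode the "short binding-competent ordered
element inside long disorder" notion from the α-MoRF literature; they are
deliberately tunable because the reference predictor's exact thresholds are
not public, and for the same reason published MoRF gain/loss fold values
are not reproduction targets.

Stage 2 is a two-class quadratic discriminant over six candidate features
(mean `ps` in the stretch, mean flank `ps`, stretch length, both flank
lengths, mean propensity of the stretch residues): Gaussian class densities
with class-specific covariances, score = log posterior odds, accepted iff
score > 0. Singular covariances are ridge-regularized with
`10⁻⁶ · trace/dim` on the diagonal (escalating ×10 until the Cholesky
factorization succeeds) and a warning. The model ships untrained; training
sets come from the synthetic generator's planted MoRF dips, and fitted
models persist as plain-text JSON.

Impact of a mutation compares accepted MoRFs overlapping the mutated
position (within the ordered stretch; flanks do not count) in wild type vs
mutant: **lost**, **gained**, **present_no_change**, or **absent** — the
absent category is excluded from enrichment denominators. Mutations are
placed into IDR/OR strata by the wild-type score.

## Curation controls

- **Alignment**: global Needleman–Wunsch with affine gaps; BLOSUM85 with
  gap open −11 / extend −1 (the matrix choice follows the original NES
  protocol; the gap penalties are the conventional BLAST-family defaults,
  config-exposed). A gap of length `L` costs `open + (L−1)·extend`; end
  gaps are penalized like internal ones. BLOSUM85 is loaded at run time
  from biotite's matrix database (Biopython does not bundle it). Identity
  = matches / alignment columns, excluding double-gap columns (relevant for
  pairs projected out of a multiple alignment); a shorter-sequence
  denominator is available by option. Ties between co-optimal alignments
  resolve to the aligner's first traceback, which is deterministic for
  fixed inputs — score and identity are tie-invariant.
- **Redundancy clustering**: proteins sharing ≥ 40% pairwise identity are
  merged by single linkage (connected components of the ≥-threshold graph,
  so identity is transitive across a cluster); one representative per
  cluster is drawn uniformly from the id-sorted member list with the run
  seed. The partition never depends on the seed or input order — only the
  representative draw uses randomness. Mutations on non-representatives
  are discarded and counted.
- **Outlier removal**: proteins with extreme mutation counts are flagged
  either as the top-k by count (deterministic tie-break by id) or by a
  count threshold; the removed mutation fraction is reported so runs can be
  compared against the reference figure (the original curation removed four
  proteins carrying 12.4% of disease mutations).
- **NES extraction**: for each ortholog pair at ≥ 95% identity, every
  aligned column with two differing canonical residues and no gap yields a
  pseudo-mutation human→ortholog at the human coordinate; columns gapped in
  the human sequence have no coordinate and are skipped. Substitutions
  identical to an annotated disease mutation are removed. The same
  substitution observed in several orthologs collapses to one record by
  default — the per-ortholog counting convention (`keep_multiplicity=True`)
  is also implemented because reference dataset sizes suggest it may have
  been used; neither is asserted as the original's.

## Enrichment statistics

- **Fisher exact test** (two-sided, point-probability convention): sums
  hypergeometric probabilities of all same-margin tables whose point
  probability is ≤ the observed one, with a 10⁻⁷ relative slack guarding
  floating-point ties; computed in log space so P-values near 10⁻³⁰⁰ stay
  exact, and validated exhaustively against integer-exact enumeration for
  all tables with total ≤ 40. A total probability within 10⁻⁹ of 1 snaps
  to exactly 1.
- **Bonferroni**: multiply by the family size, cap at 1; the family is all
  features/categories tested within one analysis.
- **Fold difference**: ratio of the two group proportions; SE by the delta
  method on the log ratio (a bootstrap SE is available as a cross-check —
  the "standard error of fold difference" has no canonical definition, so
  the estimator is documented rather than assumed). Folds with a zero
  proportion are flagged undefined, not fabricated. Where references report
  one standard deviation instead of one SE, both estimators exist; which
  convention a given figure used is noted, not guessed.
- **Composition profiling**: per-residue fractional difference
  `(f_sample − f_background)/f_background` with SEs from seeded multinomial
  bootstrap resampling (default 10 000 replicates; bit-reproducible for a
  fixed seed).
- **Feature normalization** (UniProt-FT-style): evidence-qualified features
  ("Potential", "Probable", "By similarity") dropped; level 1 = keyword,
  level 2 = keyword + description with boilerplate prefixes ("Required
  for", "Involved in", "Mediates", …) stripped case-insensitively,
  longest-prefix-first; disease-named keywords removed (they would be
  trivially enriched in a disease dataset); labels hit by < 5 disease
  mutations removed.

## The synthetic generator

`simulate.SimConfig` defines the study conditions. Proteins are built from
alternating ordered/disordered blocks with geometric lengths (means 40/30
residues — typical domain/linker scales), uniform lengths 300–800, and
residues drawn per block with probability ∝ `exp(±β·z)` (`z` =
standardized propensity, sign by block type, default β = 1 — enough to
give blocks clearly distinct compositions without making every disordered
site unflippable). Mutation datasets (default three arms of 5 000, the
order of magnitude of curated disease/polymorphism collections) plant
D→O transitions at per-site probabilities matching the observed shares of
the disease (20%), polymorphism (11.5%) and neutral (7.3%) datasets, by
substituting, at a disordered-called site, a more order-promoting residue
drawn uniformly among those that flip the call (the window mean is
monotone in the substituted propensity, so if the most extreme residue
fails no residue can — unflippable sites are resampled from the class pool
and counted). Unplanted mutations get uniform random substitutions and may
flip calls *accidentally*; that baseline is measured on a zero-planting
run and subtracted during parameter recovery, never suppressed.
Annotations tile true blocks (10-residue tiles that never straddle a block
boundary) with coverage odds `annotation_odds` (default 3) higher in
disordered blocks, so the residue-level coverage odds ratio equals the
planted odds in expectation.

What the generator does **not** emulate: genetic-code adjacency of
substitutions (real missense spectra are constrained to single-nucleotide
changes; planted substitutions are not), codon-level mutability such as
CpG hotspots, ortholog phylogenetic structure, realistic UniProt feature
vocabularies, and length/composition differences *between* datasets.
Passing recovery tests therefore demonstrates that the pipeline measures
what was planted under its own model of the data — not that the built-in
predictor agrees with any published predictor on real proteomes.

## Numerical conventions and degenerate inputs

- Coordinates are 1-based inclusive in every file, 0-based half-open
  internally; conversion lives in the I/O layer only.
- The order/disorder boundary `ps = 0.5` is disordered everywhere.
- Rejected mutation rows (wild-type mismatch) are counted and reported;
  out-of-range positions, unknown proteins and identity substitutions are
  hard errors.
- Zero mutations in a region is a zero rate, not an error; an empty MoRF
  candidate list is valid output.
- All randomness flows from explicit integer seeds (`numpy` Generator);
  cluster representatives, bootstrap draws and the generator are
  bit-reproducible for a fixed seed.

## Problem sizes

The test suite and the acceptance script run the synthetic study at 60
proteins (~33 k residues) with three arms of 5 000 mutations (tests) or
4 000 (acceptance script's sanity run), sizes at which the planted fold of
2.0 carries a ~3-SE band of roughly ±0.7 and each full run completes in a
few seconds. Statistics on published count tables are exact and
instantaneous at any size.

## Known limitations

- The built-in predictor's absolute disorder content is calibration-
  dependent; only threshold-relative behaviour (calls, flips, shares) is
  meaningful.
- Stage-2 MoRF classification is only as good as its training set; with
  the synthetic trainer it separates planted dip types, nothing more.
- Fisher's exact test is conservative for large sparse families; no FDR
  alternative is provided because the analysis convention is Bonferroni.
- NES extraction assumes the supplied alignments are orthologous and
  reliable; no ortholog detection or alignment-quality filtering is done.
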