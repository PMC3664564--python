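# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices and the limitations of `mirpair`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Screening model

The pipeline assumes two normalized expression matrices (mRNA and miRNA;
features × samples, positive linear relative-expression values) over the
same samples, split into a case and a control group. No distributional
assumptions are made about expression: all screening statistics are
rank-based, chosen for robustness at clinical sample sizes (the reference
design is 7 vs 7).

**Present call.** A feature is *present* when its log2 expression exceeds a
floor (default 4.0) in at least a fraction `min_frac` (default 0.5) of the
samples of at least one group. Both knobs are exposed because array
present-call conventions vary; only present features are tested.

**Rank-sum difference and distinctness.** Midranks are assigned over the
pooled case+control values; `D = R_case − R_control`. Under the null `D`
centers at `(n1 − n2)(n1 + n2 + 1)/2`; its directional extremes are
`n1(n1 + 2 n2 + 1)/2 − n2(n2 + 1)/2` (case on top) and the mirror image.
A feature is *distinctly expressed* iff `D` equals the extreme of its own
direction, which is equivalent to the group value ranges not overlapping.
With unequal group sizes the two extremes are **not** symmetric around
zero — `max_rank_sum_diff` therefore reports the extreme of the observed
direction, taken relative to the null center (for 7 vs 7 both extremes are
±49 and the familiar `|D| = 49` reading applies). Any cross-group tie
(shared value in both groups) makes overlap-freedom impossible and thus
forbids distinctness. The equivalence of the rank-based and overlap-based
definitions is property-tested over random instances including ties.

**Mann–Whitney p.** Two-sided. `exact` enumerates the permutation
distribution of U (valid only without cross-group ties; requesting it with
ties is an error that points to `normal`), `normal` is the tie-corrected
normal approximation with continuity correction, `auto` (default) uses
exact when `n1 + n2 ≤ 16` and the input is free of cross-group ties. The
exact route is scipy's enumeration; an independent brute-force
enumeration over all `C(n1+n2, n1)` rank assignments serves as the test
oracle, swept exhaustively for all `n1, n2 ≤ 8`.

*Discreteness caveat.* At 7 vs 7 the exact two-sided p is supported on a
grid; the largest attainable rejection rate not exceeding 0.05 is
`130/3432 ≈ 0.0379` (rejection region `U ≤ 8` or `U ≥ 41`). Null
simulations must therefore be compared against 0.0379, not 0.05; the
continuity-corrected normal approximation shares the same rejection region
at this sample size. This is a property of the test, not of the
implementation.

**Regulated / fold change.** Regulated ⇔ present and `p ≤ alpha`
(inclusive boundary, default 0.05, raw p by default; Benjamini–Hochberg
behind `adjust="bh"`). Signed fold change is computed from the ratio `r`
of group arithmetic means of linear values (`+r` if `r ≥ 1`, else
`−1/r`); the median is available via `agg="median"` since the aggregation
convention is not universal. Distinct features are flagged among the
regulated ones.

## Target prediction

Canonical seed matching on the 3′UTR sense strand, strict Watson–Crick
(no G:U wobble), coordinates 0-based half-open. Site types: 6mer
(reverse complement of miRNA positions 2–7), 7mer-m8 (2–8), 7mer-A1
(6mer + target adenosine opposite position 1), 8mer (both). Overlapping
classifications of one seed occurrence collapse to the strongest type.
Score = site-type rank (8mer 4 … 6mer 1) plus a +1 3′-supplementary bonus
when the reverse complement of miRNA positions 13–16 occurs within the 10
bases immediately 5′ of the site; the 10-base window is this package's
choice and is fixed so the score stays deterministic and oracle-checkable.
This scanner is a deliberately transparent stand-in for structure-aware
thermodynamic scoring (secondary/tertiary-structure accessibility models),
which is out of scope; every consumer of a prediction table accepts an
externally computed table instead, so a thermodynamic predictor's output
can be substituted without touching the pairing logic.

## Pair assembly, genomic map, enrichment, structure

**Pairs.** A candidate pair is a regulated miRNA and a regulated predicted
target with opposite fold-change signs, unique at the (miRNA, transcript)
level (multiple sites collapse into the best-scoring row). Direction comes
from the signed fold change, not from the rank statistic.
`restrict_to_distinct` optionally narrows the mRNA side to distinctly
expressed transcripts, because published pair lists of this design have
been read both ways. Output order is canonical (`mrna_id`, `mirna_id`), so
the result is invariant to input row order.

**Genomic map / hotspots.** Regulated features with coordinates are
plotted as −log10(p) by position; the hotspot scan counts regulated vs
present features per fixed window (default 10 Mb) per chromosome and
attaches a binomial upper-tail p against the genome-wide regulated
fraction. The scan is reported as a table and never thresholded into a
headline call, because window-based enrichment at this scale is a
screening aid, not a test with controlled error.

**GO.** Flat annotations (no is-a propagation — a known limitation);
term occurrence counts per selection, optional omission of shallow terms
(`min_level`); enrichment/depletion as exact hypergeometric tails
(`P(X ≥ k)` / `P(X ≤ k)`, which share the observed point mass) of term
*membership* against the present-feature background — tissue-specific
background rather than the whole annotation universe, configurable. A
label-resampling permutation alternative exists for cross-checking.
Categories sum term counts with an "other" fallback, conserving totals.

**Structure.** UPGMA (unweighted average linkage) over samples on
dissimilarity 1 − Pearson r, computed on log2 expression of a feature
subset; samples are sorted by id before linkage so output is
order-invariant. PCA operates on row-wise z-scores using the population
(ddof = 0) standard deviation — deterministic and exactly reconstructible;
components are oriented so each loading vector's largest-magnitude entry
is positive. The separation score is the minimal number of misassigned
samples over both labelings of a 2-cluster cut, or over all thresholds and
polarities of a 1-D score (exhaustive search).

## Validation and concordance

Standard-curve qPCR quantification: least-squares `Ct = a + b·log10(q)`
(slope b < 0 required; efficiency `10^(−1/b) − 1`), technical triplicates
averaged (optionally dropping the replicate farthest from the median when
the range exceeds 1 Ct), target quantity normalized to a reference assay.
Concordance = Spearman rho of matched per-feature fold changes (signed
log2 scale), with an empirical probability from `k` uniform random
permutations of the validation-to-screening pairing:
`p = (#{|rho_perm| ≥ |rho_obs|} + 1)/(k + 1)` — two-sided on |rho| with
the +1 small-sample correction, floor `1/(k+1)`; the signed one-sided
tail is reported alongside since the convention is not universal. The
full single-step maxT machinery of Westfall–Young-style resampling is
unnecessary for a single statistic and intentionally not implemented.
The rho is computed over matched per-feature fold changes (one value per
validated feature), the reading that makes screening and validation
directly comparable across platforms.

## Synthetic-data model

The generator emulates the target study design so every stage is testable
without downloads; all randomness flows from one seed through named
per-stage generators (`[seed, stage]`), making every artifact
byte-reproducible.

- Baseline log2 expression ~ Normal(7, 2) floored at 0 — a plausible
  array scale; the source material states no distribution.
- Absent features (`frac_absent`, default 0.2) get baselines uniform in
  [0.5, 2.5], below the 4.0 present floor in essentially all samples.
- DE features receive signed log2 shifts with |shift| ~ |Normal(2.0,
  0.5)| (floored at 0.25) in the case group; planted DE baselines are
  kept ≥ floor + 2 so detectability is a matter of noise, not of the
  present call. Within-group noise is Normal(0, 0.5) per sample.
- Distinct features (a subset of DE) get post-hoc gap enforcement: the
  case group is shifted until the groups are separated by at least
  max(0.5, noise_sd).
- True pairs cycle the DE miRNAs (≤ `max_targets` targets each); each
  paired target's direction is forced opposite to its miRNA's. Each pair
  gets one exact seed-match site (8mer by default) spliced into the
  target's UTR at a recorded, non-overlapping position; incidental seed
  matches of pair miRNAs elsewhere are scanned for and recorded as chance
  sites.
- The qPCR table writes triplicate Ct values on a configurable standard
  curve (default slope −1/log10 2, i.e. efficiency 1.0) from the linear
  expression values, plus a constant-quantity reference assay; at noise 0
  the validation fold changes equal the screening fold changes exactly.
- GO annotations: 30 terms with names/levels/categories, Poisson(2)
  random terms per gene, plus one term preferentially attached to DE
  transcripts (probability 0.5 vs 0.05 background) as a planted
  enrichment signal.

Defaults (2000 mRNAs / 300 miRNAs, 100/20 DE, 10 distinct, 10 pairs)
mirror the emulated design's *proportions* — a minority of present
features regulated, a small distinct subset — at a reduced feature count
chosen as the package's own desk-scale working size; effect size and
noise defaults are calibration choices, not values taken from any
dataset. What passing tests on these data do **not** show: robustness to
probe-level artifacts, batch effects, correlated features, heteroscedastic
noise or annotation bias — none of which the generator models.

## Numerical and interface choices

- Expression is stored on the linear scale; every log2 transform is
  explicit at its computation site (avoids double-log bugs).
- Text outputs are TSV with header, UTF-8, LF endings, repr-based
  shortest round-trip floats; coordinates 0-based half-open everywhere.
- All cross-group tie handling uses midranks; exact-mode requests with
  cross-group ties fail loudly rather than silently degrading.
- `run_all` stages communicate only through files; the manifest records
  the seed, config and SHA-256 digest of every output, and contains no
  timestamps, so same-seed reruns are byte-identical.
- Single-threaded by contract; the CLI rejects `--threads ≠ 1`.

## Known limitations

- No thermodynamic/conservation-aware target scoring; seed matching only.
- Flat GO annotations without ontology-graph closure.
- No normalization or probe-level processing: the pipeline consumes
  normalized matrices.
- Exact-test discreteness at small n (see above) means nominal and
  attained significance levels differ; report attained sizes when
  calibrating.
- The permutation concordance p has floor 1/(k+1) and, for very few
  validated signals (n ≲ 8), random permutations can tie |rho| = 1,
  lifting the minimal p above the floor.
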