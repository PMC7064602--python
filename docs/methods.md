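# Methods

## Model

A peptide-spectrum match (PSM) is either correct (H=1) or wrong (H=0).
Within a charge stratum Z, the three engine scores **x** = (XCorr, deltaCn,
spScore) are treated as a draw from the mixture

    p(x|Z) = π₀ p(x|Z, H=0) + π₁ p(x|Z, H=1),

and the quantity of interest is the local FDR, the posterior probability
that a PSM in a given region of score space is wrong:

    lFDR(x, Z) = (1 + (π₁/π₀) γ(x, Z))⁻¹,  γ(x, Z) = p(x|Z,H=1)/p(x|Z,H=0).

Two assumptions make everything estimable from a target/decoy search:

* **Target/decoy symmetry.** Decoy matches are distributed like wrong
  target matches, in both score and count. Per histogram cell, the decoy
  count n₀ estimates the wrong-hit count and the target excess
  n₁ = targets − n₀ the true-hit count; group-wise, the prior odds are
  estimated as π₁/π₀ = max(T − D, 0)/max(D, 1) from the group's target (T)
  and decoy (D) totals.
* **Shared score distributions across groups.** The non-canonical group is
  far too small for its own 3D histogram, so γ is estimated from *all*
  PSMs, and only the prior odds π₁/π₀ are group-specific. A non-canonical
  group with, say, 0.9 true PSMs per wrong one receives systematically
  higher lFDRs than a proteome group with 18:1 odds over the identical
  score cells — this is the entire protective mechanism.

The acceptance threshold converts local to global FDR: target PSMs are
sorted by lFDR and the threshold is the largest value whose running mean
(the estimated global FDR of the accepted list) stays at or below the
requested level α. Thresholds are selected per group in two-group mode and
pooled in one-group mode; charge strata share one threshold within a
group. A decoy-counting global-FDR estimate (#decoys passing / #targets
passing) is reported alongside as a cross-check. Ties are resolved on
whole distinct lFDR values, so the accepted set is exactly
{lfdr ≤ threshold} and never splits a cell.

## Histogram estimation choices

* **Binning.** 40 equal-width bins per dimension (configurable), spanning
  the observed [min, max] per stratum; values on the top edge fall into
  the last bin. A dimension with zero spread raises an error pointing at
  the 1D mode. The 1D comparison mode runs the identical machinery on an
  XCorr-only histogram.
* **Smoothing.** Counts are averaged over the cell's 3×3×3 neighbourhood
  box, clipped at the grid borders (border cells average over their
  existing neighbours only). The *signed* target excess is smoothed first
  and floored at zero afterwards: flooring the raw per-cell difference
  before averaging would inflate n₁ in pure-noise regions (the positive
  part of mean-zero Skellam noise) and bias the lFDR downward exactly
  where it must be high.
* **Pseudocounts.** γ is computed as ((n₁+ε₁)/Σn₁)/((n₀+ε₀)/Σn₀) with
  ε₀ = ε₁ = 0.05 counts (divided by the window volume when smoothing, since
  box-mean output lives on a counts/27 scale). The pseudocount exists only
  to keep γ finite in decoy-free cells; it must stay well below one count,
  because a larger value caps γ at ~n₁/ε₀ in the clean high-score region
  where decoys are absent, which inflates every small lFDR, stops the
  running-mean threshold far too early, and drives the realized error rate
  of the accepted list well below nominal (most visibly for the
  non-canonical group, whose acceptances all live in that region). With
  ε = 0.05 an empty neighbourhood still yields γ = Σn₀/Σn₁ < 1, i.e. a
  high lFDR, so stray wrong matches in quiet cells are not invited in.
* **Degenerate inputs.** Groups without PSMs raise an error recommending
  one-group mode; a group without decoys gets a capped prior (10⁶) and a
  warning; strata below 100,000 PSMs warn that the histogram is unstable
  (the synthetic test datasets run far below this on purpose).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.03 | target global FDR per group; 0.01 available but only costs peptides |
| `bins` | 40 | histogram intervals per score dimension |
| `window` | 3 | neighbourhood box width for smoothing |
| `eps0`, `eps1` | 0.05 | pseudocounts (raw-count units) in the density ratio |
| `score_dims` | 3 | 3 = (XCorr, deltaCn, spScore); 1 = XCorr-only comparison mode |
| `grouping` | two_group | group-specific vs pooled priors and thresholds |
| `decoy_prefix` | `DECOY_` | accession prefix marking decoy matches |
| `min_len` | 8 aa | minimum ORF length emitted by the database builder |
| `cutoff` | 0.0 | expression filter (strict >) for transcripts entering the database |

## Synthetic data: what it emulates, what it does not

The generator emulates a search against a concatenated target/decoy
database with competition. Per spectrum: a correct match with the
group-specific true fraction (defaults 0.9 proteome, 0.3 non-canonical,
10% of spectra non-canonical); otherwise a wrong match that lands on the
decoy section with odds `decoy_ratio` (default 1.0, so decoy counts
estimate wrong-target counts and (T−D)/D estimates the true/wrong ratio).
Scores come from two 3-variate normals chosen to resemble Comet score
distributions of HLA class-I data — overlapping components
(true XCorr 2.6 ± 0.8 vs wrong 1.5 ± 0.5, etc.), positive XCorr/deltaCn
correlation for true matches, near-independence for wrong ones — because
with well-separated components no finite-α threshold binds and calibration
claims would be vacuous. deltaCn is clipped to [0, 1] and spScore to ≥ 0.
The second engine reproduces a correct match with probability 0.9 and the
*same* wrong match with probability 0.1 (otherwise a different wrong match
or nothing), which is what makes the intersection informative.

Charge strata are split 10/60/30% (Z1/Z2/Z≥3). Default runs use 200,000
PSMs per dataset and 10–20 seeds in the heavier checks; these sizes make
each stratum dense enough for a 40³ histogram while keeping a full
calibration sweep around a minute.

Not emulated: spectrum-level structure (peaks, mass errors), retention
times tied to sequences, engine score recomputation, shared peptides
between the proteome and ORF databases. Passing calibration here shows the
estimator is honest *under target/decoy symmetry and shared score
distributions*; it cannot show robustness to violations of those
assumptions in real data (e.g. decoy sets that are easier to match than
true negatives).

## Sequence handling

Stop-to-stop translation emits, per forward frame, every segment between
stop codons — including the open-ended segments at the transcript ends
(`include_terminal=True`), since unannotated transcripts routinely lack a
stop before the clone boundary. Codons containing N translate to X and
segments are split at X, so no fabricated residue becomes searchable. No
maximum length is imposed. Proteome classification collapses I to L on
both sides (isobaric under MS) and uses exact substring search via a k-mer
seed index; a peptide matching only whitelisted transposable-element
accessions remains non-canonical with a `te_exception` flag. The relative
peptide position statistic reports the C-terminal coordinate
(start + length)/protein length of the first occurrence, the N-terminal
variant being a flag away.

## Grouping and QC

Protein grouping is plain cardinality-greedy set cover (ties to the
lexicographically smallest accession, for byte-reproducible output);
proteins sharing a peptide with a selected lead join its group, and a
selected protein already absorbed into an earlier group heads no group of
its own. Greedy cover is not guaranteed minimum-cardinality — small
counterexamples exist with as few as three proteins — and no exhaustive
repair is attempted; determinism and the conservation property (adjusted
counts per group sum to the group's distinct peptides, with a shared
peptide credited to its first group by lead order) are the contracts.
Adjusted counts subtract peptides already credited to higher-ranked
members; HLA sampling divides them by protein length; the
expression–sampling relation is summarised by a degree-3 polynomial fit on
log10(expression + 1) with the Pearson r between fit and data.

QC consumes external predictions (HLA-binder p-values, hydrophobicity
indices) rather than reimplementing the predictors: binder fraction with
an inclusive p ≤ 0.05 threshold, ordinary least squares of retention time
on hydrophobicity (residual standard error √(SSR/(n−2))), and a one-sided
F-test of residual variances with the putatively noisier list first, by
default each list around its own regression line.

## Known limitations

* The lFDR is a cell-level quantity; PSMs inside one cell are
  indistinguishable, and results depend on bin count for small datasets.
* π₁/π₀ estimation degrades for groups with very few decoys (capped, with
  a warning) — the one-group mode exists for exactly that case.
* The intersection's FDR cannot be estimated from decoys alone once both
  engines' thresholds have been applied; on synthetic data it is measured
  against ground truth instead.
* File formats are deliberately minimal TSV/FASTA dialects; engine-native
  formats (pep.xml, msms.txt, mzIdentML) are out of scope.
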