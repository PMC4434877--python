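# Methods

## Model and procedure

`dcreg` compares the co-expression structure of a gene × sample expression
matrix between two conditions. The statistical object is a *network pair*:
one set of gene-pair links with two Pearson correlation coefficients per link,
one per condition. The pair-retention rule — keep a link iff
`max(|r1|, |r2|)` passes the cutoff — deliberately admits links strong in
*either* condition, because a link that is strong in one condition and absent
in the other is exactly the differential signal of interest. Pearson on
log2-scale values is the default (Spearman is available); correlations need
at least three samples per condition and the error names the offending
condition.

Two complementary gene-level calls are made and intersected:

* **DCp** scores each gene by the root-mean-square change of its neighbor
  correlations, `dC = sqrt(Σ (x_j − y_j)² / n)`, bounded in [0, 2] with 2
  attained only when every incident correlation flips between the extremes.
* **DCe** first flags differential links (DCLs) with a limit-fold-change
  model and then scores each gene by the upper-tail binomial probability of
  its incident DCL count `k_i` out of degree `n_i` at the network-wide rate
  `K/N` (computed via the binomial survival function; exactly 1 at k = 0).

Intersecting the two calls ("true DCGs") is conservative by design: DCp is
sensitive to diffuse neighborhood change, DCe to concentrated link-level
change, and requiring both sharply reduces false positives from either route.
Links flagged by DCe that touch a true DCG ("true DCLs") and the TF→target
overlay (DRGs/DRLs) follow set logic documented in the API; a DRL's
`p_dcg` is the DCp p-value of its starred (DCG) endpoint, the smaller of the
two when both endpoints qualify, and a link matching the library in both
orientations emits two records.

## Permutation null — why the network is rebuilt per round

Significance of dC comes from shuffling the condition labels of the pooled
samples (preserving group sizes) rather than shuffling genes: gene shuffling
would destroy the neighbor structure the statistic is defined on. A subtle
but decisive choice is what happens to the link set under permutation.
Holding the observed link set fixed and only recomputing its correlations
makes the test wildly anti-conservative: links enter the network *because*
the observed labeling made one of their correlations extreme, so the observed
dC is conditioned on its own selection while pseudo dCs are not. Measured on
no-structure data (300 genes, 8+8 samples, 200 rounds, 20 datasets), the
fixed-link scheme calls 97% of genes significant at p ≤ 0.05. The default
scheme (`relabel-reselect`) therefore re-applies the same cutoff to every
permuted dataset and, for each gene, counts only the rounds in which the gene
carries at least one link — the conditional add-one estimator
`p = (1 + #{pseudo ≥ observed}) / (1 + #rounds with links)`. Under the null
this restores exchangeability between the observed and permuted statistics;
the same measurement gives a 5.2% call rate and a pooled Kolmogorov–Smirnov
distance from U(0, 1) of ≈ 0.01 (6,000 p-values). The fixed-link variant is
retained as `scheme="relabel-fixed-links"` for methodological comparison
only. Permutations operate on samples in sorted-id order, so results are
invariant to the column order of the input matrix and bit-reproducible given
the seed. FDR is Benjamini–Hochberg across genes.

## Limit-fold-change selection — binning and reversals

The LFC idea is a magnitude-dependent fold-change threshold: among same-sign
links, the fold change `max(|r1|,|r2|) / (min(|r1|,|r2|) + ε)` is ranked
within equal-count bins of the signal magnitude `max(|r1|,|r2|)` and the top
δ fraction of each bin is flagged (δ = 0.25, up to 20 bins, ε = 1e−8 by
default; per-bin counts are δ × bin size rounded half up, and bins never
shrink below 10 links so small networks degrade to fewer bins rather than
singleton bins). Links with no differential signal (|r1| = |r2|) are never
flagged, so identical networks yield zero DCLs at any δ < 1.

Sign-reversing links (r1·r2 < 0, reversal type 1; a zero product is typed 0
because no sign change is demonstrable) are handled as their own group,
ranked globally by |r1 − r2| with the same δ, *without* magnitude binning.
Two reasons: the fold-change ratio is not a meaningful score across a sign
change, and genuine reversals share nearly identical magnitudes, so binning
them by magnitude concentrates them into a few bins where a per-bin cap would
arbitrarily discard true reversals in small networks.

## Study design

A study arm runs three comparisons — pre-vs-control, post-vs-control,
pre-vs-post — and attributes to the disease only what the treated comparison
does *not* reproduce: `disease = pre − (pre ∩ post)`, applied to DRG sets by
gene identity and to DRL sets by ordered (TF, target) identity (correlations
necessarily differ between comparisons and play no role in the identity).
Key regulators are then the DRLs whose TF is itself a disease DRG, plus those
TFs. An empty pre-vs-post report means "no detected treatment effect" and is
a valid outcome, never an error; likewise a cutoff retaining no links yields
an empty comparison report with a logged warning. Per-comparison permutation
seeds are spawned deterministically from the run seed.

The bundled worked-example tables (`dcreg.datasets`) transcribe the published
downstream record of a two-subtype depression study; the module docstring
documents three transcription ambiguities (one partly illegible row, the
unmarked discarded rows of the MDD table — recoverable from the published
key-regulator list, though the source's own count of 48 retained rows is then
internally inconsistent with the reconstructed 47 — and one unidentifiable
discarded SSD row that does not affect the key overlap). Upstream
dataset-scale quantities (the original 20,283-gene matrix and its DRG/DRL
counts) depend on data and an unpublished cutoff outside this package's
scope; the set-logic stages downstream of the printed tables are what the
package reproduces exactly.

## Synthetic data

The generator plants regulator hubs in a factor model: each hub's targets
load on the hub's latent variable with loading equal to the desired
hub–target correlation (+0.9 by default), which makes every per-condition
correlation matrix positive semi-definite by construction (the matrix is
still validated, with a logged nearest-PSD repair as a safety net, and the
generation aborts if a repair would move entries by more than 0.1).
Between the baseline and the altered condition a configurable fraction of
each hub's links flips sign (default 1.0 — the planted condition is a fully
sign-reversing regulator, the strongest biologically interpretable form of
differential regulation) and a further fraction collapses to the background
correlation ("shift"). Remaining genes form an equicorrelated background
(default correlation 0). Samples are multivariate normal on a log2-like
scale (mean 8, sd 1), with default group sizes of 8 — the small-cohort regime
the method targets. The library contains every planted hub→target relation
plus two decoy background targets per hub.

What the generator does *not* emulate: probe-level microarray artifacts,
normalization residue, batch effects, heavy-tailed or heteroscedastic noise,
and realistic background co-expression blocks. Passing recovery tests
therefore shows the statistics behave correctly under the declared model, not
that results on real arrays are free of artifacts from those sources.

Desk-scale defaults are 120 genes with 3 hubs × 10 targets for recovery runs
and 300 structure-free genes for null calibration; at these sizes a 500-round
permutation comparison takes about a second, and the full acceptance sweep
(20 replicates of each study) well under a minute. The method scales as
genes² per permutation round, which is practical to a few thousand genes;
genome-scale matrices should be pre-filtered to the variable subset first.

## Numerical choices and degenerate inputs

* Zero-variance genes cannot carry correlations; their pairs are marked
  undefined, logged, and excluded from the pair universe.
* Genes without network neighbors are reported in a skipped list, never
  silently dropped; their dC is undefined (NaN marker at the statistic
  level).
* Correlations are clipped to [−1, 1] against floating-point overshoot;
  canonical link order is lexicographic on gene symbols (unique by
  invariant), and all outputs are deterministically sorted.
* The binomial tail uses `scipy.stats.binom.sf` (log-space stable); exact
  summation via `math.comb` serves as the independent oracle in tests.
* Tie-breaks in LFC ranking are stable sorts on the canonical link order, so
  equal scores resolve deterministically.

## Known limitations

* The permutation test's re-selection scheme assumes the two groups are
  exchangeable under the null; confounded designs (batch = condition) will
  produce calibrated-looking but biologically misleading p-values.
* With 5–8 samples per group, single-link evidence is weak by construction;
  the DCe binomial test only flags genes with several concordant links, so
  regulators with one or two targets are essentially undetectable at these
  sizes.
* The δ parameter caps the DCL fraction per group; in very small networks
  where genuine reversals dominate the opposite-sign pool, some true
  reversals necessarily fall below the cap (seen in simulations under ~80
  genes).
* DRL orientation comes entirely from the library; the method cannot infer
  regulatory direction from expression.
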