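# Methods

`intronsens` quantifies how individual introns respond to small-molecule
splicing inhibitors that bind the branch-point-adenosine pocket of
SF3B1/Hsh155 (pladienolide-B, thailanstatin-A, herboxidiene), in a budding
yeast whose Hsh155 has been humanised at the drug-binding pocket. It
implements three layers of analysis plus a synthetic-data generator with
known ground truth that stands in for deposited sequencing data.

## 1. Junction-based splicing efficiency

For one retained-intron event, reads informative about splicing fall into
two classes:

* **N_EE** — reads whose alignment gap coincides exactly with the intron
  boundaries (exon–exon junction reads: the intron has been excised);
* **N_IE** — reads whose contiguous aligned block crosses the 5'SS or the
  3'SS with at least `overhang` nt on each side (unprocessed boundary
  reads: the intron is still present).

Splicing efficiency is

    SE = 100 · N_EE / (N_EE + N_IE)   [percent]

and is undefined (missing) when both counts are zero. Retained-intron
events are extracted from transcript models as the gaps between
consecutive exons; coordinates are 0-based half-open genomic intervals
internally, with GTF (1-based inclusive) converted at the reader
boundary. Events from multi-intron genes are quantified but excluded
from dose-response analysis. Event/condition groups whose replicate-mean
total count `mean(N_EE + N_IE)` is below 100 are removed (the decision
per group is recorded in a filter log); the filter is idempotent.
Replicates are collapsed by computing SE per replicate and averaging; a
pooled-counts estimator (sum counts first) is offered as an option
because it weights replicates by depth. A utility converts summed
exonic coverage to estimated read counts by dividing by the positions
one aligned paired-end read covers (default 240).

Parameters: `overhang` (default 4 nt per side — the junction counter's
value is not published, so it is exposed); `threshold` (default 100
replicate-mean reads).

## 2. Dose-response normalisation, ranking, clustering

Raw SE at each dose is normalised to the same intron's no-drug (DMSO)
control: `relSE(d) = 100 · SE(d) / SE(0)`. Values above 100 (splicing
improved under drug) are retained and flagged, not clamped. Events with
`SE(0) = 0` cannot be normalised and are excluded with a log entry.
`dSE_05 = SE(0) − SE(0.5 µM)` measures the low-dose drop (small = resistant).

Within each non-zero dose, introns are ranked by relSE (rank 1 = most
resistant; ties get the mean rank), and the per-dose ranks are averaged
into the **average rank**, the primary resistance ordering. Intrinsic
SE (dose 0) is split into equal-frequency quintiles; ties are broken by
input order (ordinal ranks), a documented arbitrary choice.

Profiles `(relSE_0.5, relSE_5)` are clustered agglomeratively. The
default distance is **uncentered Pearson** (cosine without
mean-centering) with **average linkage** — the characteristic defaults
of the classic gene-expression clustering tools this analysis style
comes from; Euclidean and other SciPy metrics/linkages are options. The
tree is cut into `k = 3` groups (the cut height derives from k) and
groups are named by their mean relative SE: `most_resistant`,
`intermediate`, `most_sensitive`. Note a genuine limitation of the
uncentered metric: it measures profile *direction* only, so two groups
of profiles that are parallel but offset in magnitude are
indistinguishable to it; planted-magnitude recovery checks therefore use
the Euclidean option. The dendrogram is serialised as Newick.

The variant-branch-point summary counts introns whose BP 7-mer deviates
from the consensus UACUAAC among the bottom third of the resistance
ranking (boundary `rank > ceil(2n/3)`) and attaches a hypergeometric
tail probability; the test is an addition beyond the raw count and is
labelled as such in the output. Drug-versus-drug differences are
per-intron `relSE_A − relSE_B` (antisymmetric under swap). Covariate
correlations report squared Pearson r or Spearman rho with two-sided p;
missing pairs are dropped and counted, zero-variance inputs are flagged.

## 3. SMIT co-transcriptional splicing curves

A SMIT read gives, for one nascent transcript, the Pol II position
(3'-end, nt relative to the 3'SS, negative = upstream) and its splice
status. Spliced reads upstream of the 3'SS are physically impossible
and are counted and excluded. Binning by position (default 10 nt) gives
the **raw fraction spliced** per bin, `spliced / (spliced + unspliced)`.

### Capture-bias correction

The library captures a molecule with probability depending on its insert
length. At position x the unspliced product has length
`L_u = primer_offset + x` and the spliced product `L_s = L_u −
intron_length`. With capture weights `w_u = P(L_u)`, `w_s = P(L_s)`
(insert-law mass summed over the bin's integer positions), the observed
fraction is the true fraction with its odds multiplied by `w_s / w_u`;
the correction inverts that:

    f = f_raw · w_u / (f_raw · w_u + (1 − f_raw) · w_s)

This is the minimal model using exactly the quantities available
(position, insert length, product lengths, insert-length probability
function); it is isolated behind one function so an alternative kernel
can be swapped in. Raw fractions of exactly 0 or 1 are fixed points.

A corrected value is only **computed** where it is identifiable: both
weights at least `weight_floor` (10⁻³ of the law's peak), within
`max_weight_ratio` = 10-fold of each other, and `L_s > 0`. Elsewhere
the bin is NaN. A computed bin is flagged **reliable** when its
delta-method standard error — binomial noise in the raw fraction
amplified by the inversion derivative `w_u w_s / denom²`, assessed at
the Jeffreys midpoint so observed 0/1 fractions are not treated as
noiseless — is at most `max_se` = 0.02. "Reliable" therefore means the
point estimate itself can be trusted to roughly ±2.5 standard errors
(±0.05); at moderate depths only well-balanced, well-populated bins
qualify, which is the honest statement of what the assay pins down.

The insert-length law can be supplied (e.g. the generator's known law)
or estimated from the pooled reads as a pseudocount-smoothed histogram.
The estimated law is the *observed* length distribution, which is the
capture law tilted by the availability of molecules at each length; the
tilt biases pointwise corrected fractions somewhat but cancels almost
entirely in the AUC ratios below (null calibration stays at 100%).

### Onset, windowed AUC, resistance

The **onset of splicing** is the smallest bin centre ≥ 0 whose corrected
fraction exceeds θ = 0.05 for w = 2 consecutive bins, detected on the
control (denominator) curve only so both members of a comparison share
one window. The **AUC** is the trapezoidal integral of the corrected
curve over `[onset, onset + 200 nt]`, evaluated on the exact window
(curve values at the bounds interpolated); missing bins inside the
window are linearly interpolated when they are at most 50% of the
window, otherwise the gene is flagged and the AUC withheld. Then

    ΔAUC = 1 − AUC_treated / AUC_control
    CTX resistance = (1 − ΔAUC) · 100%   [percent]

with values above 100% permitted and flagged. Significance per gene
uses the two-sided Wilcoxon signed-rank test over paired per-bin
corrected fractions in the window (exact null for n ≤ 25, normal
approximation with continuity correction beyond; zero differences
dropped and counted; withheld below 5 usable pairs). When a treated
sample has several uninhibited references (same strain + carrier,
control strain + carrier, control strain + drug), the best estimate is
the arithmetic mean of the per-comparison resistances, flagged partial
if fewer than three are available.

## 4. Synthetic-data generator

The generator emulates the two experiment designs at desk scale with
known ground truth persisted alongside every table.

**Junction counts** — per intron i, dose d, replicate r: total count ~
negative binomial with mean `expression_depth_i` (dispersion α = 0.05
by default, mild replicate-level overdispersion; var = µ + αµ²), split
`N_EE ~ Binomial(total, SE_i(d)/100)` with
`SE_i(d) = intrinsic_SE_i · (1 − sensitivity_i(d))`. Inhibition is a
free per-dose multiplicative factor rather than a mechanistic EC50
model: with only two non-zero doses, two free parameters per intron is
the faithful minimal description. Defaults: 2 replicates, doses
{0, 0.5, 5} µM, depth 1000, intrinsic SE ~ Uniform(30, 95)%, inhibition
drawn non-decreasing in dose.

**SMIT reads** — per molecule: Pol II position x ~ Uniform(−100, 500)
(covering pre-3'SS territory and the analysis window with margin); true
spliced state ~ Bernoulli of the gene's logistic splicing curve
`f(x) = f_max / (1 + exp(−(x − midpoint)/slope))` for x ≥ 0, 0 upstream,
scaled by a per-condition inhibition factor; molecule length
`primer_offset + x`, minus the intron length if spliced; retained with
probability proportional to the insert-law density at that length. The
default insert law is a discretised normal (mean 250 nt, sd 60 nt,
support 100–600 nt) — unimodal and interacting with typical yeast
intron lengths; it is a stand-in, not an estimate of any real library.

`designed_smit_panel()` provides a fixed three-gene panel whose geometry
mirrors how real SMIT primer panels are built — short introns
(90–110 nt), primer 120 nt from the 3'SS, onset midpoints 90–130 nt —
so that both product lengths stay capturable across the 200-nt window.
With randomly drawn gene geometry under the narrow default insert law,
much of the window is often unidentifiable and the AUC is withheld;
that reflects assay physics, not an implementation limit, and is why
the demo pipeline and the calibration checks use the designed panel.

**What the generator does not emulate:** alignment artefacts, rRNA
contamination, duplicate reads, gene-specific transcription and decay
rates, nuclear decay of nascent transcripts, or multi-intron isoform
complexity. Passing recovery tests on this generator shows the
estimators invert the stated sampling models correctly at realistic
depths; it does not certify behaviour under real-data artefacts the
models exclude.

## 5. Numerical and design choices

* Coordinates: 0-based half-open everywhere internally.
* Ties in resistance ranks: mean rank. Ties at quintile boundaries:
  input order.
* Missing values in TSV output: sentinel `NA`; all tables carry
  provenance headers (version, config hash, seed); identical config +
  seed reproduces every output byte-for-byte.
* All randomness flows from the single configured seed
  (`numpy.random.default_rng`).
* Problem sizes used in the shipped end-to-end checks: 100–200 introns
  at depths 500–1000 for recovery/ranking, 60 profiles for cluster
  recovery, 3 genes × 5000 retained reads/gene for SMIT (50 replicate
  seeds for null calibration) — sizes at which the binomial/NB sampling
  envelopes make the stated tolerances meaningful.

## Known limitations

* The capture-bias inversion is pointwise and nonparametric; at bins
  with strongly imbalanced weights its variance is amplified, which the
  reliability flag makes explicit rather than hiding.
* Estimating the insert law from captured reads conflates capture
  probability with availability; supply an external law where the
  distinction matters.
* The hypergeometric tail on the variant-BP count assumes
  exchangeability across introns (no covariate adjustment).
* Only retained-intron events are modelled; other alternative-splicing
  event classes are out of scope.
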