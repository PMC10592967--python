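# intronsens

Intron-specific sensitivity to SF3B1-pocket splicing inhibitors:
junction-based splicing efficiency, dose-response resistance ranking and
clustering, and co-transcriptional splicing (SMIT) resistance metrics,
with a synthetic-data generator carrying known ground truth.

## The problem

Bacterial natural products such as pladienolide-B (Plad-B),
thailanstatin-A and herboxidiene inhibit pre-mRNA splicing by occupying
the branch-point-adenosine pocket of SF3B1 (yeast Hsh155). In a yeast
strain whose Hsh155 pocket has been humanised to bind these drugs,
different introns lose splicing at strikingly different rates as drug
concentration rises. Quantifying that intron-by-intron response takes
three measurements this package implements for anyone analysing such
experiments (or prototyping the analysis on simulated data):

1. **Splicing efficiency (SE)** from junction reads. For one
   retained-intron event, with `N_EE` reads spanning the exon–exon
   junction and `N_IE` reads crossing an unprocessed intron–exon
   boundary,

   `SE = 100 · N_EE / (N_EE + N_IE)`  (percent).

   Events with replicate-mean total coverage below 100 reads are
   removed; replicate SEs are averaged.

2. **Dose-response resistance.** Per intron, SE at each dose is
   normalised to its DMSO control (`relSE = 100 · SE(d)/SE(0)`); introns
   are ranked by relSE within each dose (rank 1 = most resistant), the
   per-dose ranks averaged into an *average rank*, and the
   `(relSE_0.5, relSE_5)` profiles hierarchically clustered (uncentered
   Pearson distance, average linkage, k = 3) into most-resistant /
   intermediate / most-sensitive groups. Summaries locate
   variant-branch-point introns within the ranking and correlate
   resistance with covariates (Pearson r², Spearman rho).

3. **Co-transcriptional resistance (SMIT).** Single-molecule intron
   tracking reads give Pol II position and splice status per nascent
   transcript. After inverting the library's insert-length capture bias,
   the fraction-spliced-versus-position curve is integrated over a
   200-nt window anchored at the gene-specific onset of splicing:

   `ΔAUC = 1 − AUC_treated / AUC_control`, and co-transcriptional
   resistance `CTX = (1 − ΔAUC) · 100 %`, with paired Wilcoxon p-values
   per gene.

The generator (`intronsens.synthio`) simulates both read types from
known truth — negative-binomial totals split binomially for junction
counts; logistic position-dependent splicing with insert-length capture
bias for SMIT — so every estimator can be validated by parameter
recovery. See `docs/methods.md` for the full model descriptions.

## Worked example

Library use, statsmodels-style (build a model, `fit()`, read the
results):

```python
from intronsens import DoseResponseModel
from intronsens.cli_io import RunConfig, run_pipeline, read_table

cfg = RunConfig(outdir="demo_out", seed=1, sim={"n_introns": 60})
run_pipeline(cfg)                      # simulate -> se -> doseresp -> smit
res = DoseResponseModel(read_table("demo_out/se.tsv")).fit(k=3)
print(res.summary())
```

which prints (same numbers as `demo_out/doseresp_summary.txt`):

```
Dose-response resistance summary
======================================
events analysed:        60
doses (uM):             [0.0, 0.5, 5.0]
cluster groups (k=3):
  most_resistant   n=35    mean relSE=  40.5%
  intermediate     n=18    mean relSE=  37.7%
  most_sensitive   n=7     mean relSE=  24.4%
most resistant introns (by average rank):
  intron0006       avg rank    5.0  relSE_05=  74.0  relSE_5=  57.7
  intron0036       avg rank    5.0  relSE_05=  78.4  relSE_5=  54.7
  intron0051       avg rank    5.0  relSE_05=  85.7  relSE_5=  53.5
  intron0010       avg rank    8.0  relSE_05=  75.3  relSE_5=  50.1
  intron0023       avg rank    8.0  relSE_05=  71.5  relSE_5=  57.2
```

Sixty simulated introns pass the coverage filter; each intron's relative
SE at 0.5 and 5 µM drives its rank (intron0006 retains 74% of its
splicing at 0.5 µM — a resistant intron) and its cluster group. The
SMIT stage of the same run compares a treated condition whose true
splicing curves were halved against control, and recovers that:

```
SMIT co-transcriptional splicing summary
============================================
genes with comparisons:   3
comparisons computed:     3
genes excluded:           0
AUC window length (nt):   200
median CTX resistance:    46.1%
per-gene comparisons:
  gene000    control->treated    onset= 105.0  dAUC=+0.539  CTX=  46.1%  p=3.05e-05
  gene001    control->treated    onset= 115.0  dAUC=+0.551  CTX=  44.9%  p=6.1e-05
  gene002    control->treated    onset=  85.0  dAUC=+0.485  CTX=  51.5%  p=3.81e-06
```

CTX near 50% for every gene matches the simulated 50% inhibition.

The same pipeline is scriptable from a shell:

```sh
intronsens demo --out demo_out --seed 1
intronsens se --counts counts.tsv --out run1 --min-count 100
intronsens doseresp --se run1/se.tsv --k 3 --out run1
intronsens smit --reads smit_reads.tsv --bin 10 --window 200 --out run1
```

Every output file carries a provenance header (package version, config
hash, seed); rerunning with the same config and seed reproduces every
file byte-for-byte.

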