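# termscan

Genome-wide detection of transcription-**termination readthrough** from
strand-specific tiling-array signal, with change-point segmentation of the
tracks and comparison of mutant **expression signatures**.

In budding yeast, short non-coding transcripts (snoRNAs, CUTs, some SUTs)
are terminated by the NNS (Nrd1–Nab3–Sen1) pathway, while mRNAs use the
CPF/CF pathway; mutations in CTD kinases and termination factors cause RNA
polymerase II to read through past annotated 3′ ends. `termscan` is for
people who want to quantify that defect genome wide: it takes an annotation
of transcription units, strand-specific per-probe log2-intensity tracks for
wildtype and mutant, and (optionally) a gene × sample expression matrix, and
answers *which features show readthrough, how strong the average 3′
extension is, where the signal segments change, and which mutants share an
expression signature*.

## The core rule and models

**Readthrough calling.** For each feature, probe intensities are replicate-
averaged and binned into w = 25 bp windows anchored at the 3′ end (offset 0
is the first bin past the end, strand-aware). With bin difference
d_b = x̄_mut(b) − x̄_wt(b) over the first 150 bp (6 bins), a feature is
scored positive when

    #{ b : d_b > 0.6 } ≥ 4   (of 6 bins),

and features whose 3′ end lies < 150 bp from the next same-strand transcript
are excluded (trailing signal there is not attributable). All constants live
in `ReadthroughParams`.

**Segmentation.** Per-region probe series are fit by a piecewise-constant
Gaussian model: exact least-squares dynamic programming places k−1
breakpoints, and k is selected by BIC(k) = −2 log L_k + 2k·log n (pooled MLE
variance, ties to smaller k).

**Signatures.** Per mutant, M_g = mean(mutant replicates) − mean(wildtype
pool) in log2; genes pass the filter when p < 0.05 and |M| > log2 1.7.
Signatures are clustered on 1 − cosine similarity (average linkage) and
gene-set overlaps are scored with the upper-tail hypergeometric test.

A synthetic-data module generates annotation, probe tracks and expression
matrices with planted ground truth (readthrough sites, close neighbors,
overlapping gene modules), so the whole pipeline is testable end to end.

## Worked example

```python
from termscan import SimulationConfig, call_all, generate_annotation, generate_tracks
from termscan.readthrough import summarize_by_class, summaries_to_frame
from termscan.tiling import normalize_tracks

cfg = SimulationConfig()          # 108 features, probes every 8 bp, 2 replicates
ann, truth = generate_annotation(cfg, seed=1)
tracks = normalize_tracks(generate_tracks(ann, truth, cfg, seed=2))
calls = call_all(ann, tracks, ["mut_1", "mut_2"], ["wt_1", "wt_2"])
print(summaries_to_frame(summarize_by_class(calls)).to_string(index=False))
```

prints

```
feature_class  n_total_annotated  n_excluded  n_tested  n_positive  fraction_positive
          CUT                 12           1        11           4           0.363636
          ORF                 60           6        54           2           0.037037
          SUT                 12           1        11           4           0.363636
       snoRNA                 24           2        22           8           0.363636
```

Each row counts features of one class: `n_excluded` had a same-strand
neighbor within 150 bp (or missing bins), `n_positive` passed the 4-of-6
rule among the `n_tested` remaining. The planted contrast — readthrough at a
large fraction of snoRNAs but only a few percent of ORFs — is recovered
(here 18 of 20 planted sites called, no false positives). The
`examples/` directory has one script per capability: calling, metagene
profiles, segmentation, and signature clustering/enrichment. The same
functionality is exposed on the command line (`termscan simulate`,
`termscan readthrough call`, `termscan run --config run.yaml`, ...).

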