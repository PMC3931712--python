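# epimotif

Prediction of transcription-factor binding regions by fusing sequence
motif scanning with the spatial organization of modified nucleosomes.

## The problem

Position weight matrices (PWMs) are the standard representation of a
transcription factor's sequence preference, but scanning a mammalian genome
with a PWM alone drowns the handful of functional sites in false positives:
short, degenerate motifs match everywhere.  Chromatin offers an orthogonal
signal.  Nucleosomes carrying particular histone modifications (H3K4me3,
H2A.Z and other "active" marks) are enriched in two peaks flanking bound
sites, with a nucleosome-free region at the site itself, while repressive
marks show no such structure.  `epimotif` turns that observation into two
simple interval features and a probabilistic classifier:

* **MNN** (modified-nucleosome neighboring): distance in bp from a region's
  center to the nearest nucleosome center carrying a given mark;
* **MNO** (modified-nucleosome occupancy): the number of marked nucleosome
  centers within ±1 kb of the region's center.

A logistic regression classifier (LRC) maps these features to a binding
probability `h_θ(x) = 1 / (1 + exp(−θᵀx))`, fitted by minimizing the binary
cross-entropy `J(θ) = −(1/m) Σᵢ [yᵢ ln h_θ(xᵢ) + (1−yᵢ) ln(1−h_θ(xᵢ))]`
with a quasi-Newton method.  Sequence and chromatin are fused per 1-kb genome
bin as

```
score(bin) = h_θ(features(bin)) × pwm_rel(bin)
```

where `pwm_rel` is the best double-strand PWM score in the bin mapped onto
the relative unit scale `(raw − s_min)/(s_max − s_min)`, with `s_min`/`s_max`
the sums of per-column minimum/maximum log-odds: the per-column worst
sequence scores 0 and the consensus scores 1.  Rankings are evaluated with
ROC curves and AUC.

Because the workflow's real inputs (genome-wide binding-site annotations and
nucleosome-center calls from ChIP-seq) are large external datasets, the
package ships a first-class synthetic-data generator that emulates them —
random genome with planted motif instances, assembly-gap runs, and per-mark
nucleosome tracks with the bimodal-plus-depletion geometry described above —
so the entire method is testable end to end on a laptop.

## Worked example

```bash
epimotif run --out results --seed 5
```

generates the default synthetic study (3 chromosomes × 2 Mb, 500 planted
sites each), trains the MNN classifier on chr1, scores every 1-kb bin of
chr2–chr3 and prints the pooled test-set AUCs:

```
{"pwm": 0.9028, "lrc": 0.9928, "combined": 0.9943}
```

Reading: matrix scanning alone ranks bins at AUC 0.90; the chromatin
classifier alone reaches 0.99; the fused score is the best of the three —
the chromatin signal removes sequence false positives.  `results/` holds the
per-bin score table (`scores.tsv`), the fitted model and matrix
(`model.json`, `pwm.json`), ROC curves and a reproducibility log.  Repeating
the command with the same seed reproduces every file byte for byte.

The individual stages are also exposed: `simulate`, `build-pwm`, `scan`,
`features`, `profile`, `train`, `predict`, `evaluate` — see
`epimotif <cmd> --help`.  As a library:

```python
from epimotif import SyntheticDatasetSpec, generate, position_profile

ds = generate(SyntheticDatasetSpec(seed=0))
prof = position_profile(ds.tracks["H3K4me3"], ds.sites)
# prof.offsets spans -1015..+1015; prof.ratio peaks near ±150 bp
```

## Layout

```
src/epimotif/
  genome_model.py   coordinate types, binning, interval arithmetic
  pwm.py            PWM construction, double-strand scanning, relative scale
  features.py       MNN / MNO features, positional occupancy profiles
  classifier.py     logistic regression (cost, gradient, BFGS fit)
  pipeline.py       training/test assembly, fused scoring, factor transfer
  evaluation.py     ROC / AUC, pooled and per-chromosome
  synthetic.py      synthetic genome + binding sites + nucleosome tracks
  io.py             FASTA / GFF / track / score tables, run configuration
  workflow.py       end-to-end orchestration
  cli.py            command-line interface
docs/methods.md     model assumptions, parameter choices, limitations
```
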