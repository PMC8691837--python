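# ghostcyto

An in-silico ghost cytometer: a desk-scale, end-to-end simulation of
compressive motion-imaging flow cytometry and of the machine-learning
pipeline that predicts a cell's fluorescence label — and sorts it — from
stain-free waveforms alone.

## The problem

Image-based cell classification is information-rich but slow: forming and
processing microscopy images caps the throughput far below the ~10,000
cells/s of conventional flow sorters.  Ghost motion imaging (GMI) removes
the image from the loop.  A cell crossing a static structured-illumination
mask `H` produces, on a single-pixel detector, a 1D waveform

G[t] = Σ_{i,j} I[i,j] · H[t−(h−1)+i, j],

the column-summed cross-correlation of the mask with the cell's contrast
map `I` translated one pixel per sample along the flow axis.  The waveform
(>100 samples) is a compressive, image-equivalent measurement: a classifier
trained on waveforms paired with fluorescence-threshold labels can predict
the label *in silico*, at waveform rate, and drive a sorter.  The package
simulates the whole chain — cell phantoms, optics, trigger electronics,
gating and labeling, SVM and CNN classifiers, sorting — and certifies the
forward model by exact image reconstruction from multi-pattern waveforms.

It is intended for people designing or studying compressive cytometry
pipelines who need a controllable, fully seeded stand-in for instrument
data: every benchmark here is synthetic, and the phantom generator is the
ground truth.

## Worked example

```python
import numpy as np
from ghostcyto import benchmarks
from ghostcyto.gating import threshold_label
from ghostcyto.svm import repeated_eval

# two size-matched cell lines differing only in internal texture;
# one carries a fluorescent stain used for supervision
spec = benchmarks.two_class_spec(n_per_class=1000, seed=1)
events, _ = benchmarks.simulate_benchmark(spec, benchmarks.two_class_optics(), seed=1)
labels = threshold_label(events, benchmarks.two_class_label_rule())

res_w = repeated_eval(events, labels, benchmarks.waveform_svm_config(seed=1))
res_s = repeated_eval(events, labels, benchmarks.scalar_svm_config(seed=1))
print(f"waveform AUC {res_w.mean_auc:.3f} +/- {res_w.std_auc:.3f}")
print(f"scalar   AUC {res_s.mean_auc:.3f}")
```

prints

```
waveform AUC 0.966 +/- 0.004
scalar   AUC 0.489
```

The two populations have the same size distribution, so the conventional
FSC/SSC scalars are at chance (AUC ≈ 0.5), while the 128-sample dGMI
waveform, which samples the cell's interior texture through the mask,
separates them at AUC ≈ 0.97 — the in-silico analog of classifying two
morphologically similar cell lines label-free.  `repeated_eval` reports
the mean ± sd over 10 balanced train/test samplings and, separately, the
AUC of the vertically averaged ROC.

The command line exposes the same pipeline:

```bash
ghostcyto throughput --acquisition-time 100us   # -> 10,000 cells/s
ghostcyto simulate --config run.yml --out events.h5
ghostcyto evaluate --events events.h5 --modalities dGMI --out report.json
ghostcyto export-fcs --events events.h5 --out events.fcs
```

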