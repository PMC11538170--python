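# atrspect

MRI-free spatial normalization and striatal quantification for
dopamine-transporter (¹²³I-ioflupane) SPECT, built around **adaptive
template registration (ATR)**.

DAT-SPECT shows intense uptake in the caudate and putamen and very
little anywhere else, so warping a subject into template space — the
step that lets fixed atlas VOIs quantify everyone identically — is
fragile exactly in the patients that matter, whose striatal signal has
collapsed.  ATR sidesteps the problem: it models each subject as a
weighted mixture of two templates, a normal-uptake pattern **N** and a
disease ("egg-shape", posterior putamen lost) pattern **E**,

    T(w) = w·N + (1 − w)·E,     w ∈ {0.001, 0.002, …, 0.999},

scores every mixture against the linearly pre-aligned subject with
zero-mean normalized cross-correlation (ZNCC), and uses the best-scoring
mixture as that subject's normalization target.  **Split-ATR** optimizes
`w` independently per hemisphere and composes an asymmetric target,
preserving the left/right asymmetry typical of Parkinson disease.

After normalization, atlas-derived VOIs (indicator set to 100, smoothed
with an 8 mm FWHM Gaussian, thresholded strictly above 50) yield, for
striatum, caudate and putamen:

* uptake ratio `R = mean(region) / mean(occipital)` per side, and the
  per-region high/low-side values;
* asymmetry index `AI = |L − R| / (L + R) × 200 %`;
* binding ratio `R − 1` (the specific-binding scale of the Southampton
  method, for comparability).

Method agreement is evaluated with OLS regression (slope, intercept,
Pearson r, p) and the one-way random-effects intraclass correlation
ICC(1,1) with exact-F confidence bounds.

A deterministic digital-phantom module generates DAT-SPECT-like
subjects (configurable striatal ratios, posterior putamen loss,
geometric deformation, scanner blur, noise) together with a matching
atlas and exact ground truth, so the whole pipeline is testable without
any data download.  See `docs/methods.md` for the model, assumptions
and numerical choices.

## Worked example

```python
import numpy as np
from atrspect.phantom import make_template_pair, PhantomSpec, generate_phantom
from atrspect.atr import run_atr
from atrspect.quant import quantify

# templates averaged from 8 normal-type and 8 egg-shape-type phantoms
pair, atlas, vois = make_template_pair((64, 64, 64), 3.44, seed=0)

# an asymmetric subject: near-normal left, egg-like right hemisphere
spec = PhantomSpec(shape=(64, 64, 64), spacing=(3.44,) * 3,
                   caudate_ratio_left=3.5, putamen_ratio_left=3.2,
                   caudate_ratio_right=1.8, putamen_ratio_right=1.5,
                   putamen_posterior_fraction_right=0.45,
                   deformation_amplitude_mm=3.0,
                   noise_model="gaussian", noise_sigma_pct=3.0)
subject, _, truth = generate_phantom(spec, seed=33)

for mode in ("atr", "split_atr"):
    normalized, sel, _ = run_atr(subject, pair, mode=mode)
    rr = quantify(normalized, vois)
    print(mode, sel.weights(),
          "striatum L/R = %.2f / %.2f" % (rr.striatum.ratio_left,
                                          rr.striatum.ratio_right))
print("truth        striatum L/R = %.2f / %.2f"
      % (truth.ratios_at_resolution["striatum"]["left"],
         truth.ratios_at_resolution["striatum"]["right"]))
```

prints

```
atr {'w': 0.185} striatum L/R = 2.45 / 1.31
split_atr {'w_left': 0.623, 'w_right': 0.001} striatum L/R = 2.54 / 1.24
truth        striatum L/R = 2.59 / 1.21
```

The global weight (0.185) is a compromise between the two hemispheres —
the symmetric target template compresses the apparent asymmetry — while
the split weights land on each hemisphere's own pattern (0.623
near-normal left, 0.001 egg-like right) and the measured ratios track
the ground truth.  (`w` is the normal-template fraction; `truth` is the
ideal measurement of the same phantom at scanner resolution with no
deformation or noise.)

A command-line interface mirrors the library:

```sh
atr phantom --seed 7 --out subj/            # synthetic subject + atlas + truth
atr run --mode atr --subject subj/phantom.nii.gz \
    --template-normal N.nii.gz --template-egg E.nii.gz \
    --atlas subj/atlas.nii.gz --labels subj/labels.json --out run/
atr evaluate --reference truth.csv --candidate run/ratios.csv --out table.csv
```

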