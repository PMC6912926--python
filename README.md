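# finsex

Automated phenotypic sexing of sexually dichromatic fish (zebrafish-style)
from lateral RGB images, with the downstream statistics needed to interpret
the classifiers ecologically.

Zebrafish males carry a more intensely yellow caudal fin than females, but
the difference is subtle enough that human scoring is subjective and
labor-intensive, and gonadal inspection is terminal. `finsex` implements
two image-based classifiers and the statistical machinery around them:

* **Fin-color SVM** — each fish's caudal-fin crop is converted to CIE
  L\*a\*b\* (sRGB primaries, D65, 2°); per-channel histograms over fixed bin
  edges form the feature vector; a soft-margin SVM with Gaussian kernel
  k(x, y) = exp(−γ‖x−y‖²) separates the sexes. The signed decision value
  f(x) = Σᵢ wᵢ k(Xᵢ, x) + b doubles as a per-fish coloration score.
* **Whole-body residual CNN** — a small convolutional network (3×3 stem,
  residual stages widening toward the head, global mean pooling, 2-unit
  softmax) classifies sex from the whole image, so it can exploit body
  shape as well as color. Implemented directly in NumPy; a reduced 64×64
  geometry trains in minutes on one CPU.
* **Agreement and sex ratios** — classifier-vs-gonadal-truth 2×2 tables
  summarized by the phi coefficient φ = (n₁₁n₂₂ − n₁₂n₂₁)/√(r₁r₂c₁c₂);
  per-group male proportions modeled by a Bernoulli GLM with logit link,
  logit(πᵢ) = μ + αᵢ, with back-transformed least-squares means and
  Tukey–Kramer-adjusted contrasts.
* **Pigmentation intensity and body size** — the z-transform of the SVM
  decision values is a cohort-level pigmentation-intensity score; an
  ANCOVA with treatment, sex, their interaction and polynomial body-size
  covariates (degree ≤ 3, with factor-by-covariate interactions), backward
  elimination by F-tests, externally-studentized-residual outlier
  filtering (|r| > 3), and Tukey–Kramer LS-means quantifies how fin
  coloration relates to body weight and length in each sex.
* **Synthetic cohorts** — since no photographs ship with the package, a
  generator renders fish-like images (ellipse body + triangular fin on a
  light background) whose statistical structure matches a
  temperature-treatment dichromatism study: males yellower than females,
  treated males attenuated, fin color coupled to body weight in males
  only, females rounder-bodied, and realistic weight/length cell means.

## Worked example

```python
import numpy as np
from finsex.simulate import SimConfig, simulate_cohort
from finsex.features import extract_fin_features
from finsex import svm as fsvm
from finsex.agreement import confusion, phi

cohort = simulate_cohort(SimConfig(n_per_cell=50, seed=1))   # 200 fish
ids, X, y = extract_fin_features(cohort.samples)             # 192-dim histograms
model = fsvm.train(X, y)
scores = fsvm.intensity_scores(fsvm.score_cohort(model, X, ids))
pred = np.array([s.predicted_sex for s in scores])
groups = np.array([s.group for s in cohort.samples])
for g in ("control", "treatment"):
    m = groups == g
    t = confusion(y[m], pred[m])
    print(f"{g}: phi = {phi(t):.3f}  predicted male = {100*(t.n11+t.n21)/t.total:.1f}%")
```

prints

```
control: phi = 0.980  predicted male = 51.0%
treatment: phi = 0.393  predicted male = 30.0%
```

The control group is sexed almost perfectly from fin color alone, while in
the treated group many males — whose fin yellowness the generator
attenuates, emulating temperature-induced masculinization of genotypic
females — are scored female, depressing both the agreement φ and the
apparent male proportion. The intensity z-scores make the mechanism
explicit: on the same run, mean z is +1.40 for control males, +0.05 for
treated males and −0.72 for females. A whole-body CNN trained on the same
cohort is robust to the color attenuation because the body-shape cue
survives.

The same pipeline is scriptable end to end:

```bash
finsex run --config config.yaml --out results/
```

with stages `simulate → features → train-svm → predict → agreement →
intensity → ancova`, a per-run provenance manifest, and JSON/CSV artifacts
throughout. Individual subcommands (`finsex simulate`, `finsex ancova`,
…) expose every stage separately.

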