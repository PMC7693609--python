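# thermomics

Deep-learning-driven analysis of infrared breast-thermography sequences.

Breast tumors recruit blood flow (vasodilation, driven e.g. by nitric
oxide) and run a hotter metabolism than normal tissue, which leaves
spatially heterogeneous, time-varying patterns in the skin temperature
field. This package implements a screening pipeline that turns a short
thermal image sequence per subject into a compact quantitative descriptor
("thermomics", by analogy with radiomics) and classifies subjects as
healthy vs symptomatic:

1. **Heat matrix.** The ROI of each frame is vectorized and stacked into a
   p × n matrix X (p pixels, n frames, p > n), each pixel's time course
   mean-centered.
2. **Low-rank decomposition.** Principal component thermography (PCT) is
   the SVD X = UΓVᵀ; sparse PCT replaces each direction with the penalized
   variance maximizer max ‖u‖₂=1 uᵀXXᵀu under an ℓ1 penalty / cardinality
   cap (elastic-net sparse PCA), solved by soft-thresholding power
   iteration with projection deflation.
3. **Avatar.** The first three spatial bases β₁, β₂, β₃, min-max
   normalized, become the three channels of a 224 × 224 image.
4. **Deep features.** A ResNet-50 backbone (declarative layer table;
   25,583,592 trainable + 53,120 non-trainable parameters with its
   1000-class head) maps the avatar to the 2048-d global-average-pool
   activation vector. Inference runs in NumPy; weights are seeded-random
   by default (a local pretrained `.npz` can be supplied).
5. **Latent thermomics.** An 8-layer sparse autoencoder
   (2048–1024–256–64–16, mirrored decoder, ReLU/sigmoid, BCE loss + ℓ1 on
   the first hidden code, Adam) compresses features 128× to 16 values.
6. **Screening.** A random forest with leave-one-out cross-validation
   classifies subjects from the 16 latent codes and/or clinical covariates
   (age, family history), reporting accuracy with a percentile-bootstrap
   interval and the pooled out-of-fold ROC.

Because real screening cohorts are not redistributable, the package ships
a **Pennes bioheat phantom simulator**: explicit finite differences on
ρc ∂T/∂t = ∇·(k∇T) + ω_b c_b (T_a − T) + q_m over a 2-D skin-plane grid,
with tumor discs of elevated metabolic heat (q_m ~ U[1e5, 1.2e6] W/m³ vs
2e4 W/m³ normal) and perfusion, 23 frames per subject, and 0.04 °C camera
noise. Everything is testable offline on synthetic cohorts.

## Worked example

```python
import numpy as np
import thermomics as tm

seqs, recs = tm.generate_cohort(30, 30, seed=1)          # 60 phantom subjects
backbone = tm.Backbone(weights="seeded_random", seed=0)

feats = []
for seq in seqs:
    hm = tm.build_heat_matrix(seq)                        # 3364 x 23, centered
    bs = tm.sparse_pct(hm, k=3, lambda1=0.05)             # sparse spatial bases
    feats.append(tm.extract_features(tm.make_avatar(bs), backbone).values)

scaled, scaler = tm.scale_features(np.asarray(feats))
model, latent = tm.train_autoencoder(scaled, tm.AutoencoderSpec(seed=0),
                                     tm.TrainConfig())    # 16-d codes
dm = tm.build_design_matrix(latent.codes, recs,
                            subject_ids=[s.subject_id for s in seqs],
                            feature_set="latent_only")
report = tm.loocv_random_forest(dm, n_trees=1000, seed=0)
print(f"accuracy {report.accuracy:.2f}% "
      f"({report.accuracy_interval[0]:.2f}-{report.accuracy_interval[1]:.2f}), "
      f"AUC {report.roc_auc:.3f}")
```

On this strong-effect synthetic cohort the pipeline prints

```
accuracy 95.00% (88.33-100.00), AUC 0.991
```

i.e. 57/60 phantoms are classified correctly out-of-fold, the percentile
bootstrap over the correctness vector spans 88–100%, and the pooled ROC
area is near 1 — the latent codes retain the thermal-heterogeneity signal
planted by the tumor heat source. A label-permuted control on the same
codes scores 45%, i.e. chance.

The same run is available as a shell tool:

```bash
thermomics run --config run.yaml --seed 1 --out results/
thermomics simulate --out cohort/ --seed 1 --n-healthy 30 --n-symptomatic 30
```

`thermomics run` writes per-stage intermediates (TIFF sequences,
feature/code CSVs, report JSONs, ROC PNGs, a comparison table and a
manifest) into the output directory; stages are cached by a content hash
of their configuration.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch at the default 60-subject
cohort for both decompositions (sparse PCT and PCT) and all three feature
sets (latent, clinical, latent+clinical), prints the accuracy/ROC summary
table, and writes the target JSON to `--out`. Runtime is roughly 8
minutes on one CPU.
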