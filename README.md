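# gcirnet

Gaussian functional-connectivity EEG imaging and variational-autoencoder
decoding for motor-imagery brain–computer interfaces.

Motor-imagery (MI) EEG decoding suffers from volume conduction (poor
spatial specificity) and strong inter-subject variability — a sizable
fraction of users never reach usable accuracy with conventional
pipelines ("BCI illiteracy"). `gcirnet` implements a connectivity-first
alternative: instead of classifying raw channel × time matrices, each
trial is converted into compact images of *functional coupling* and
decoded generatively.

The pipeline, per trial `X ∈ R^{C×τ}`:

1. **Preprocess** — common-average reference, zero-phase Butterworth
   band-pass (4–40 Hz), resampling to 128 Hz, and the spherical-spline
   surface Laplacian (current-source density) to undo volume-conduction
   smearing; then the MI window is cut.
2. **Gaussian functional connectivity** — for each rhythm
   Ω ∈ {μ 8–12, βl 12–15, βm 15–20, βh 18–40 Hz}, channels are reduced
   to band-limited reconstructions x_c(Ω) and compared pairwise with a
   Gaussian kernel, `K[c,c′] = exp(−‖x_c−x_c′‖²/2σ²)`, σ set by the
   median heuristic per trial and band. The matrix is compressed to a
   flow vector `g_c = (1/C) Σ_{c′≠c} K[c,c′]` and min-max normalized
   channel-wise over the training set.
3. **Topographic imaging** — flows are rendered to 40×40 scalp maps via
   azimuthal-equidistant projection, Delaunay triangulation and linear
   barycentric interpolation; the four band maps stack into a 40×40×4
   image.
4. **VAE decoding** — a LeNet-style encoder (3×3 convs with 6/16/120
   filters, average pooling, 12 000-unit flatten, 128-D Gaussian
   latent), a mirrored decoder, and an MLP classifier on the latent
   mean, trained with Adam under the normalized three-term loss

   L = w_rec·NMSE + w_cla·NBCE + w_reg·NKL,  (w on the simplex)

   where each term equals 1 for a non-informative predictor, making the
   weights comparable and searchable.
5. **Evaluation & interpretability** — stratified 5×80/20 shuffle
   splits refit per split; Friedman / Holm-corrected paired tests /
   average-rank model comparison; Grad-CAM++ relevance maps per conv
   layer mapped back to electrodes; connectivity-edge percentile graphs
   and latent extraction.

The network and its backpropagation are implemented directly in NumPy
(float64, gradient-checked against finite differences), so the package
has no deep-learning-framework dependency.

## Worked example

Generate a synthetic binary MI session (8 sensorimotor channels,
lateralized μ/low-β sources), run the full pipeline, and evaluate:

```python
import gcirnet as g
from gcirnet.model import LossWeights, TrainConfig

montage = g.default_montage8()
trials, truth = g.simulate_trials(
    g.SynthConfig.binary_lateralized(n_per_class=100, seed=11), montage)

prep  = g.preprocess_trialset(trials, montage)   # surface Laplacian
flows = g.compute_flows(prep)                    # n x 4 bands x 8 channels

splits = g.make_splits(trials.labels, n_splits=5, seed=0)
factory = lambda: g.FlowImageClassifier(
    xy=montage.xy, weights=LossWeights(0.2, 0.6, 0.2),
    train_cfg=TrainConfig(epochs=60, batch_size=64, patience=10), seed=0)
result = g.evaluate_subject(factory, flows, trials.labels, splits)
print(f"accuracy: {result['mean']:.2f} +/- {result['sd']:.2f} %")
```

Output:

```
accuracy: 100.00 +/- 0.00 %
```

100 ± 0 % over the five held-out test sets: the planted lateralized
coupling is strong, and the pipeline recovers it completely. The same
evaluation with the label assignment permuted stays at chance
(52.5 % with seed 1), confirming the accuracy comes from the planted
class structure and not from leakage.

The same stages are scriptable from the shell:

```
gcirnet simulate --n-per-class 100 --seed 11 --out trials.h5 --montage-out m.tsv
gcirnet preprocess --in trials.h5 --montage m.tsv --out prep.h5
gcirnet features --in prep.h5 --out flows.h5
gcirnet evaluate --flows flows.h5 --montage m.tsv --epochs 60 --seed 0
```

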