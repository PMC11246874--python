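# sarcoseg

Segmentation of soft-tissue sarcoma in multi-modal thigh MRI.

Soft-tissue sarcomas arise in muscle, fat and fibrous tissue and are
imaged clinically with several MRI pulse sequences at once: the tumor is
hypointense relative to muscle on T1-weighted images and hyperintense on
T2-weighted and STIR images, so the sequences carry complementary
information.  `sarcoseg` implements a complete pipeline for segmenting
the tumor from three co-registered sequences (T1WI, T2WI, STIR):

1. **Preprocessing** — resample every volume to a standard grid
   (1 mm, 512×512 planes by default), normalize each scan plane with a
   trimmed max–min rule
   `S' = clip((S − S₅) / (S₉₅ − S₅), 0, 1)` where S₅/S₉₅ are the 5th/95th
   intensity percentiles of the plane, convert the clinicians' rectangular
   tumor marker boxes to filled-rectangle ground-truth masks, crop a
   256×256 window around each box, and keep the 64 central planes of each
   sequence, aligned across modalities.
2. **Architecture** — a UNet with one encoder path per modality.  At every
   skip level the per-modality feature maps are concatenated into
   F ∈ R^{H×W×C} and fused by an attention-weighted block:

   - channel gate: `F_c[:,:,k] = σ(W₂ δ(W₁ Z))ₖ · F[:,:,k]` with
     `Zₖ = mean_{i,j} F[i,j,k]`, W₁ ∈ R^{C/2×C}, W₂ ∈ R^{C×C/2},
     δ = ReLU, σ = sigmoid;
   - spatial gate: `F_s[i,j,:] = σ(p_{ij} + q_{ij}) · F[i,j,:]` with
     `p = max over channels` and `q = 1×1 convolution (W_s ∈ R^{1×1×C×1})`;
   - fused map: `F_f = F_c + F_s`.

   Two baselines share the same convolution schedule (channels doubling
   64→512 over 4 levels): **SUNet** (one encoder on the stacked
   modalities) and **MUNet** (multi-encoder with plain concatenation).
3. **Self-supervised pretraining** — each modality encoder is pretrained
   with a masking pretext task: a 30×30 patch at the tumor boundary is
   blanked, the clean and corrupted slices pass through weight-sharing
   encoders producing features F⃗ and G⃗, and the encoder minimizes
   `L = (1 − cos(F⃗, G⃗)) + L_Dice`, where
   `L_Dice = −2Σ(y_p·y_t)/(Σy_p + Σy_t)` is the soft Dice loss on the
   clean branch's segmentation.  The pretrained encoders are transferred
   into the multi-encoder model before supervised training.
4. **Training & evaluation** — Adam (lr 1e-5), up to 100 epochs with
   patience-10 early stopping, 80/20 patient-level split; evaluation by
   pixel accuracy, Dice = 2TP/(2TP+FN+FP), sensitivity TP/(TP+FN),
   specificity TN/(TN+FP), and the 95th-percentile Hausdorff distance in
   mm.

Because clinical MRI of this kind cannot be redistributed, the package
ships a seeded synthetic **phantom** generator: cylindrical thigh + bone
phantoms with a single ellipsoidal tumor obeying the modality contrast
rules, with exact analytic masks and boxes.  Every stage of the pipeline
is developed and tested against these phantoms.

The neural-network stack (convolutions, transposed convolutions,
pooling, batch norm, attention gates, Adam) runs on a compact numpy
reverse-mode autodiff core (`sarcoseg.autodiff`); there is no GPU or
deep-learning-framework dependency.

## Worked example

```python
import numpy as np
from sarcoseg import (PhantomParams, generate_cohort, load_cohort,
                      DatasetParams, build_dataset, patient_split,
                      ModelConfig, build_model, TrainConfig, train, evaluate)
from sarcoseg.train_eval import SliceArrayDataset

# 6 synthetic subjects at reduced geometry (96x96 planes, 2 mm in-plane)
params = PhantomParams(n_subjects=6, volume_shape=(12, 96, 96),
                       spacing=(6.0, 2.0, 2.0), tumor_radius_range=(10, 18), seed=7)
generate_cohort(params, "scratch/cohort")
ds_params = DatasetParams(target_spacing=(1, 2, 2), plane_size=(96, 96),
                          crop=96, n_slices=64)
manifest = build_dataset(load_cohort("scratch/cohort"), "scratch/dataset", ds_params)
print(len(manifest), "slice records")          # 384  (6 patients x 64 planes)

train_m, test_m = patient_split(manifest, 0.8, seed=1)
rows = train_m[train_m.x_min >= 0].groupby("patient").head(4)
dataset = SliceArrayDataset.from_manifest("scratch/dataset", rows)
model = build_model(ModelConfig(variant="ours", base_channels=8), seed=0)
cfg = TrainConfig(learning_rate=1e-3, max_epochs=5, early_stop_patience=4, seed=0)
_, history = train(model, dataset, cfg)
print(history.round(3).to_string(index=False))
```

prints (exact numbers are seed-reproducible):

```
384 slice records
 epoch  train_loss  val_loss
     0      -0.018    -0.000
     1      -0.025    -0.001
     2      -0.031    -0.001
     3      -0.040    -0.001
     4      -0.051    -0.001
```

The loss is the soft Dice loss (−1 is a perfect overlap): over five
epochs the fused model has begun fitting the training patients' tumor
rectangles, while the held-out validation patient is still near zero at
this tiny budget — longer runs (see `scripts/acceptance.py`, which
trains for 6 epochs on 36 patients and reaches test Dice ≈ 0.8–0.94
across the three variants) bring the validation side along.  `evaluate` reports the comparison table
(Model / Acc / Dice / Sensitivity / Specificity / Hausdorff95) on the
held-out patients.

The same pipeline is scriptable from the shell:

```bash
sarcoseg synth --subjects 45 --seed 7 --out cohort/
sarcoseg preprocess --cohort cohort/ --out dataset/
sarcoseg pretrain --dataset dataset/ --modality T1WI --out t1.npz --steps 200
sarcoseg train --dataset dataset/ --variant ours --pretrained t1.npz ... --out ours.npz
sarcoseg evaluate --dataset dataset/ --checkpoint Ours=ours.npz --out report.csv
```

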