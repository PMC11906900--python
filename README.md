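# dbahnet

Automated segmentation of the **cortical** and **trabecular** compartments in
3D high-resolution µCT scans of mouse tibiae, built around **DBAHNet** — a
dual-branch attention-based hybrid network that combines 3D shifted-window
(Swin) transformer blocks with attention-gated convolution branches — plus
the full surrounding pipeline: preprocessing, live augmentation, training,
sliding-window inference, morphological postprocessing and DSC/HD95
evaluation.

Separating the dense cortical shell from the spongy trabecular lattice is the
prerequisite for bone morphometry in preclinical studies (drug treatments,
mechanical loading, ovariectomy models). Manual and dual-threshold
segmentation struggle exactly where it matters most — the metaphysis near the
growth plate, where the two compartments intermingle. This package targets
researchers who want a reproducible, scriptable version of that workflow that
runs and is fully testable on a laptop CPU: the network and its training loop
are implemented on a compact NumPy reverse-mode autodiff core (`dbahnet.nn`),
so there is no GPU or deep-learning-framework dependency.

## The model

The network embeds a one-channel volume into `C` channels by strided
convolutions with per-axis reduction `E` (default `C=96`, `E=[4,4,2]`), then
runs three hierarchy levels, each with two parallel branches:

* **transformer branch** — a pair of 3D Swin blocks (regular then shifted
  volume partitioning) followed by a stride-2 convolution,

      x̂ˡ  = MHSA(LN(xˡ⁻¹)) + xˡ⁻¹        xˡ   = MLP(LN(x̂ˡ)) + x̂ˡ
      x̂ˡ⁺¹ = SMHSA(LN(xˡ)) + xˡ          xˡ⁺¹ = MLP(LN(x̂ˡ⁺¹)) + x̂ˡ⁺¹

  with `Attention(Q,K,V) = Softmax(QKᵀ/√d_k)V` inside local windows;
* **convolution branch** — a channel-wise attention module (CACM) in the
  encoder / spatial-wise attention module (SACM) in the decoder.

Branches are fused per level by a transformer–convolution feature fusion
module (TCFFM); a bottleneck of four global transformer blocks operates on
the `8C` map; decoder skips are filtered by cross-attention gates plus
residual skip connections; transposed convolutions restore full resolution.

Training uses the combined loss `L = α·Dice + β·CE` with `α = β = 0.5`, SGD
with momentum 0.99 and a cosine-annealed learning rate starting at `1e-4`.
Evaluation reports the Sørensen–Dice coefficient `DSC = 2|X∩Y|/(|X|+|Y|)`
per compartment and the 95th-percentile Hausdorff distance (HD95) in mm.

Because real µCT datasets of this kind are not public, the package ships a
phantom generator (`dbahnet.phantom`) producing µCT-like tibia volumes — a
tapered cortical shell, an anchored trabecular lattice, a fibula
cross-section, holder/resin background, Gaussian noise — with exact
ground-truth labels, so the entire pipeline is testable end to end.

## Worked example

```python
import numpy as np
from dbahnet import (PhantomParams, generate_phantom, preprocess_pipeline,
                     PreprocessConfig, PostprocessConfig, postprocess_pipeline,
                     evaluate_pair)
from dbahnet.sanity import overfit_training_crop
from dbahnet.train import predict_labels
from dbahnet.volumes import LabelMap

# train a tiny network on one phantom crop (published optimizer protocol)
best, model, image, labels = overfit_training_crop(seed=0)
print(f"foreground mean DSC after training: {best:.3f}")

pred = predict_labels(model, image)
refined = postprocess_pipeline(pred, PostprocessConfig())
rec = evaluate_pair(refined, LabelMap(labels), spacing=(5.0, 5.0, 5.0))
print(f"cortical DSC {rec.dsc_cortical:.3f}  trabecular DSC "
      f"{rec.dsc_trabecular:.3f}  avg HD95 {rec.avg_hd95:.4f} mm")
```

Typical output (seed 0, a couple of minutes on one CPU core):

```
foreground mean DSC after training: 0.954
cortical DSC 0.990  trabecular DSC 0.913  avg HD95 0.0309 mm
```

i.e. the small network overfits its training crop to a mean foreground Dice
above 0.9, the cortical shell being easier (sharper intensity contrast) than
the thin trabecular struts, and the boundary error stays in the tens of
micrometres at 5 µm voxels.

A command-line interface wires the stages together
(`dbahnet phantom | preprocess | train | predict | postprocess | evaluate |
pipeline`); run `dbahnet --help`.

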