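# cryocdae

Progressive denoising of single-particle cryo-EM image stacks with a
cascade of convolutional denoising autoencoders, plus the SNR-calibrated
projection simulator, pseudo-supervised fine-tuning, and clustering
evaluation needed to study it end to end — no downloads, one CPU.

## Who this is for

Cryo-EM images sit near SNR 0.1: the noise carries ten times the pixel
variance of the signal. Clustering particles by projection direction — the
step that feeds 2D class averages into 3D reconstruction — suffers badly at
that level. This package is for method developers and students who want a
complete, reproducible, pure-Python implementation of cascade denoising
with pseudo-supervised adaptation, exercised on simulated particles with
known ground truth.

## The method

Each block is a convolutional autoencoder `y = DC(EC(x))`: an encoder of
three (conv 3x3 + conv 3x3 + 2x2 max-pool) modules with 32 channels and
ReLU, a decoder of three stride-2 transposed convolutions and a final
channel-collapsing convolution, dropout 0.5 in both halves. Blocks are
shape-preserving; training minimizes

    (1/n) Σᵢ L(yᵢ, DC_φ(EC_θ(xᵢ)))      (L = mean squared error, RMSProp)

**Phase 1 — pre-training on simulated tiers.** Projections of a phantom
volume are replicated and corrupted at SNR 0.1 / 0.4 / 0.6 plus a clean
tier, index-aligned. Block 1 learns low→mid, block 2 mid→high, block 3
high→clean: each block removes only part of the noise.

**Phase 2 — pseudo-supervised fine-tuning on the target stack.** Without
clean references, each image's surrogate target is the pixel mean of its
k = 30 nearest neighbors (Euclidean) among the block's own outputs —
similar orientations share signal, independent noise averages away
(variance ≈ σ²/k). Blocks are fine-tuned sequentially, each feeding the
next. The final stack can be histogram-equalized for display.

Evaluation: PSNR (`10·log₁₀(peak²/MSE)`, peak 1.0) against clean
references, and Precision/Recall/F1 of seeded k-means or Ward clustering
after optimal cluster-to-class matching.

## Worked example

```python
from cryocdae import (CascadeDenoiser, ConvDenoisingAutoencoder,
                      SimulationPlan, build_datasets, make_phantom, psnr)
from cryocdae.simulate import default_orientations

plan = SimulationPlan(
    phantom=make_phantom(side=64, n_components=4, seed=7),
    orientations=default_orientations(),
    n_per_class=50,          # 200 images per tier at desk scale
    seed=7,
)
tiers, test = build_datasets(plan)          # 4 aligned tiers + labeled test stack

model = CascadeDenoiser(
    block=ConvDenoisingAutoencoder(epochs=20),
    k_neighbors=30,
    random_state=7,
)
model.fit([t.pixels for t in tiers])        # phase 1: pre-train 3 blocks
record = model.fine_tune(test.pixels)       # phase 2: adapt to the test stack

clean = test.clean_ref.pixels
print(f"raw      {psnr(clean, test.pixels).mean_db:6.2f} dB")
print(f"denoised {psnr(clean, record.stages[-1]).mean_db:6.2f} dB")
```

Output of this exact script (deterministic for the seeds shown):

```
raw        4.96 dB
denoised  14.56 dB
```

meaning the cascade recovers about 10 dB of peak signal-to-noise over the
raw SNR-0.1 images, measured against the clean projections of a phantom
the blocks were never pre-trained on.

The same workflow is available from the shell:

```bash
cdae simulate --config run.yaml --out data/
cdae pretrain --config run.yaml --data data/ --out model/
cdae finetune --config run.yaml --model model/ --stack data/test.npz --out run/
cdae denoise  --config run.yaml --model run/ --stack data/test.npz --out out.mrc
cdae evaluate --config run.yaml --stack run/denoised.npz --out metrics/
```

Stacks are written as MRC (mode-2 float) plus a lossless NPZ container
carrying labels, SNR tags and clean references; metrics come out as CSV;
every stage logs to stderr and derives its own seed from the single
`seed:` in the YAML config.

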