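# deastrain

Machine-learning strain-field customization for a bioreactor built on a
9 × 9 array of independently controllable dielectric elastomer actuators
(DEAs), implemented end to end on a closed-form **surrogate device model**
that stands in for finite-element simulation.

The pipeline:

1. **Virtual device** (`deastrain.device`) — a dual-Gaussian single-pixel
   voltage → strain calibration (strictly monotone on the 0–7.1 kV operating
   range), engineering/true strain conversion, and a deterministic surrogate
   simulator mapping an 81-D voltage array to X- and Y-direction strain
   fields (60 × 60 low resolution, 480 × 480 high resolution).  Each strain
   axis renders smoothly along its own direction but near-plateau across it,
   reproducing the device's directional limitation, with a clamped tapered
   boundary frame.
2. **Sampling & datasets** (`deastrain.sampling`) — uniform-voltage baseline
   and uniform-strain (inverse-CDF through the calibration curve) sampling,
   histogram uniformity metrics (std of bin probabilities, Shannon entropy),
   dual-Gaussian curve fitting, and 10,000-train / 100-test dataset
   construction.
3. **Inverse control** (`deastrain.inverse`) — a 3600 → 180 (tanh) → 81
   perceptron per strain axis, trained with seeded SGD (lr 0.001) to predict
   the voltage array reproducing a target strain image.
4. **Forward control** (`deastrain.forward`, `deastrain.srgan`) — stage 1:
   one 81 → 7200 perceptron predicting the concatenated X/Y low-resolution
   pair; stage 2: an adversarial super-resolution generator (residual blocks
   + three ×2 upsampling blocks over a bicubic skip) with a convolutional
   discriminator, BCE adversarial loss plus MSE content loss, Adam
   (generator lr 0.00025, discriminator lr 0.0001, batch 8).  All networks
   are plain NumPy with hand-written backprop — no deep-learning framework
   is required.
5. **Evaluation** (`deastrain.evaluation`) — SSIM with a Gaussian window of
   size 11 computed as local maps over valid windows (both the three-term
   luminance × contrast × structure form with C3 = C2/2 and the reduced
   two-term form), and 9 × 9 per-pixel voltage error grids.
6. **Demo targets** (`deastrain.targets`) — concentric annuli, linear
   gradients, and seeded tumor–stroma-like interface blobs
   (Fourier-perturbed ellipses), plus the reproduce-and-score loop
   (target → inverse model → simulate → SSIM).

## CLI

```bash
deastrain generate --n-train 10000 --n-test 100 --scheme uniform_strain --seed 0 --out data/
deastrain simulate --voltages data/voltages.csv --out sim/ --resolution lr
deastrain train-inverse --axis x --data data/ --out inv_x.npz
deastrain evaluate --model inv_x.npz --data data/
deastrain train-forward --stage lr --data data/ --out fwd.npz
deastrain predict --voltages data/voltages.csv --model fwd.npz --out pred.png
deastrain reproduce --target target.png --axis x --inverse-model inv_x.npz --out repro/
deastrain evaluate-ssim --a a.png --b b.png --out ssim.json
```

Strain-field images are exchanged as 8/16-bit grayscale PNGs with JSON
sidecars recording the axis and the linear display range (default strain
0–70 ↦ intensity 0–1); voltage arrays as CSV (81 columns `v00..v88`,
row-major, kV).

## Scope notes

A finite-element electromechanical model of the device (custom user
element, coupled temperature–displacement step, neo-Hookean C10 = 0.207,
D1 = 0.05) is out of scope and replaced by the closed-form surrogate; physical device fabrication, viscoelastic/dynamic behavior, and
full-scale 480 × 480 / 50-epoch adversarial training (the scaled-down
preset is the tested path) are likewise out of scope.
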