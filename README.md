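# ucpwi — post-processing for contrast-agent plane-wave ultrasound

Plane-wave imaging (PWI) insonifies the whole field with a single unfocused
transmission: frame rates are high and the mechanical index is low, which is
exactly what fragile contrast microbubbles need — but the lack of transmit
focus makes the images poor, and strong tissue scatterers drown out the
bubble signal. `ucpwi` implements a three-stage post-processing chain that
separates microbubble echoes from tissue directly in the channel
radio-frequency (RF) domain, before beamforming:

1. **RF segment classification.** A 1-D U-net (607,112 parameters; CNN and
   RNN baselines included) scores sliding length-60 RF windows as
   *microbubble* vs *tissue*; overlapping scores are averaged into a
   per-sample bubble mask.
2. **Bubble-approximated wavelet transform (BAWT) + eigenvalue threshold.**
   The scattered pressure of a shelled microbubble — obtained by solving the
   Doinikov shell model — serves as a matched mother wavelet. Bubble-classified
   samples are replaced by their wavelet coefficient at the scale that places
   the wavelet passband on the second harmonic; tissue-classified samples are
   zeroed. Pixels whose largest subarray-covariance eigenvalue λ₁ falls below
   `c = 0.15` of their scan line's maximum are rejected as residual tissue.
3. **Eigenspace-based minimum-variance (ESBMV) beamforming.** Per pixel, the
   Capon weight `w = R̃⁻¹d / (dᴴR̃⁻¹d)` (steering vector `d = 1` on delayed
   data, subarray length `L = 32`, diagonal loading `ε = δ·tr R`) is projected
   onto the signal subspace spanned by eigenvectors with `λᵢ ≥ α·λ₁`
   (`α = 0.4`) before the subarray-summed output.

Image quality is reported as contrast-to-tissue and contrast-to-noise ratios
on the linear envelope,

    CTR = 20 log10(I_UCA / I_tissue)
    CNR = 20 log10(|I_UCA − I_tissue| / √(σ²_UCA + σ²_tissue)),

with improvement quoted as |CTR_method − CTR_DAS|.

Because no public channel-RF recordings exist for this acquisition, the
package ships a physics-based simulator (`ucpwi.rf_sim`): tissue scatterers
return linear replicas of the transmit pulse, microbubbles return the
nonlinear Doinikov scattered pressure with second-harmonic content, and every
sample carries a ground-truth bubble/tissue label. The neural networks run on
a small NumPy engine (`ucpwi.nn`) with hand-written backward passes that are
verified against finite differences in the test suite.

## Worked example

```python
import numpy as np
from ucpwi import (
    DrivePulse, ProbeGeometry, PipelineConfig, RegionSpec, TrainConfig,
    build_mother_wavelet, build_unet, compare_methods, make_training_corpus,
    optimal_scale, simulate_plane_wave_rx, train,
)
from ucpwi.rf_sim import bubble_tube_phantom

# 1. train the segment classifier on a seeded synthetic corpus
corpus = make_training_corpus(n_frames=12, seed=1, n_segments=20_000)
model, history = train(build_unet(seed=0), corpus, TrainConfig.fast(seed=0))
print(f"accuracy {history['final_test_acc']:.4f}  AUROC {history['final_auroc']:.4f}")

# 2. bubble-matched mother wavelet from the shell model
wavelet = build_mother_wavelet()
print(f"{len(wavelet.psi)} samples, peak {wavelet.f_center/1e6:.2f} MHz, "
      f"optimal scale {optimal_scale(wavelet, 4e6):.3f}")

# 3. run the chain on a contrast-filled tube under a strong tissue layer
geom = ProbeGeometry(n_elements=64)
frame = simulate_plane_wave_rx(bubble_tube_phantom(11, geom), geom,
                               DrivePulse(), seed=11, n_samples=1100)
cfg = PipelineConfig(model=model, wavelet=wavelet, depth_decimation=4)
zidx = lambda z: int(round((z * 2 * 25e6 / 1540 - 1) / 4))
regions = RegionSpec(uca_region=(10, 54, zidx(0.018), zidx(0.020)),
                     tissue_region=(10, 54, zidx(0.009), zidx(0.011)))
for name, row in compare_methods(frame, cfg, regions).items():
    print(f"{name:<12s} CTR {row['ctr_db']:7.2f} dB   ΔCTR {row['d_ctr_db']:6.2f} dB")
```

Output:

```
accuracy 0.9902  AUROC 1.0000
17 samples, peak 3.88 MHz, optimal scale 0.484
DAS          CTR    2.58 dB   ΔCTR   0.00 dB
MV           CTR    5.76 dB   ΔCTR   3.18 dB
ESBMV        CTR    9.11 dB   ΔCTR   6.53 dB
U-net+ESBMV  CTR    8.63 dB   ΔCTR   6.05 dB
proposed     CTR   29.54 dB   ΔCTR  26.96 dB
```

The classifier separates bubble from tissue segments almost perfectly on the
held-out split; the dilated wavelet peaks at 2 × 4 MHz = 8 MHz as intended
(3.88 MHz / 0.484); and the full chain raises the tube-versus-tissue contrast
by ~27 dB over plain delay-and-sum, with the adaptive beamformers ordered
DAS < MV < ESBMV on the raw data.

A CLI mirrors the library: `ucpwi wavelet`, `ucpwi simulate`, `ucpwi train`,
`ucpwi classify`, `ucpwi bawt`, `ucpwi beamform`, and `ucpwi run` (the full
chain, with ablation flags `--no-classifier` / `--no-bawt`). Frames, masks
and images travel as HDF5; wavelets as NPZ; configs as YAML.

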