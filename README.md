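# srslipid

Quantitative 3D analysis of lipid droplets in two-channel stimulated Raman
scattering (SRS) image stacks.

## The problem

Lipid droplets (LDs) are the neutral-lipid storage organelles of oocytes and
early embryos, and both their geometry (number, volume, aggregation) and
their composition (the degree of fatty-acid unsaturation) change through
development. Label-free SRS microscopy can image both at once: the
2900 cm⁻¹ channel (total C–H stretch) shows every droplet as a bright
compact object against dimmer cytoplasm, while the 3010 cm⁻¹ channel
(=C–H stretch) reports carbon–carbon double bonds. The per-voxel ratio

&nbsp;&nbsp;&nbsp;&nbsp;R = I₃₀₁₀ / I₂₉₀₀

scales linearly with the number of C=C bonds per lipid and — because depth
attenuation and illumination inhomogeneity multiply both channels
identically — is insensitive to the depth-dependent signal loss that makes
raw intensities unusable for volumetric quantification.

`srslipid` turns a pair of co-registered 3D TIFF stacks (one per channel,
with caller-supplied voxel geometry) into per-droplet tables and statistics:

1. **Preprocessing** — per-plane baseline subtraction (Gaussian-debiased
   percentile anchor, refined from the acellular region once the cell body
   is known) and anisotropic Gaussian smoothing.
2. **Droplet segmentation** — per-plane Bradley adaptive thresholding
   (integral image, local mean restricted to the cell body), 3D
   connected-component labeling (6- or 26-connectivity), and per-droplet
   half-maximum boundary refinement for unbiased volumes.
3. **Unsaturation** — a per-voxel ratio map plus per-droplet summaries; the
   default per-droplet estimator subtracts the local cytoplasm pedestal
   from both channel sums and weights voxels by the droplet's own profile,
   which cancels partial-volume mixing exactly. Volume-weighted summaries
   U_w = Σᵢ uᵢVᵢ / ΣᵢVᵢ are provided alongside plain means.
4. **Cell segmentation** — whole-cell morphology by per-plane thresholding,
   opening and hole filling; 2-cell-stage embryos are split into their two
   blastomeres from contour concavities: concave points pooled over
   z-planes, clustered by 2-means, and the line joining the two cluster
   centres (extended parallel to z) cuts the mask.
5. **Statistics** — 5 μm³ size-binned unsaturation regression with 95%
   confidence bands, frequency distributions, and normality-gated
   two-group comparison (Shapiro–Wilk deciding between the two-sample
   t-test and an exact/asymptotic Mann–Whitney U).
6. **Phantoms** — a synthetic generator (spherical cells, lognormal
   droplets with known per-droplet unsaturation, depth attenuation,
   illumination bias, per-channel Gaussian noise) gives every stage a known
   ground truth; the whole pipeline is validated end-to-end against it.

A hyperspectral helper (2800–3050 cm⁻¹ stacks, per-voxel peak heights) lets
two-channel ratios be cross-checked against full spectra.

## Worked example

```python
import numpy as np
from srslipid import PipelineConfig, run_ld_pipeline
from srslipid.phantom import PhantomSpec, generate_embryo_phantom
from srslipid.unsaturation import average_unsaturation, weighted_unsaturation
from srslipid.stats_analysis import bin_by_size

spec = PhantomSpec(seed=1)                      # 40 droplets, SNR 10
stack2900, stack3010, truth = generate_embryo_phantom(spec)
result = run_ld_pipeline(stack2900, stack3010, PipelineConfig())

droplets = result.droplets
print(f"detected droplets:        {len(droplets)} (true: {len(truth.droplets)})")
print(f"total LD volume:          {sum(d.volume for d in droplets):.1f} um^3 "
      f"(true: {truth.droplets.analytic_volume_um3.sum():.1f})")
print(f"average unsaturation:     {average_unsaturation(droplets):.3f}")
print(f"weighted unsaturation:    {weighted_unsaturation(droplets):.3f}")
for b in bin_by_size(droplets)[:3]:
    print(f"size bin [{b.bin_lower:4.0f},{b.bin_upper:4.0f}) um^3: "
          f"{b.n_droplets:2d} droplets, mean unsaturation {b.mean_unsaturation:.3f}")
```

prints

```
detected droplets:        40 (true: 40)
total LD volume:          266.6 um^3 (true: 281.6)
average unsaturation:     0.290
weighted unsaturation:    0.299
size bin [   0,   5) um^3: 17 droplets, mean unsaturation 0.285
size bin [   5,  10) um^3: 18 droplets, mean unsaturation 0.289
size bin [  10,  15) um^3:  3 droplets, mean unsaturation 0.284
```

Every one of the 40 simulated droplets is recovered; the total volume is
within ~5% of the analytic truth; the volume-weighted unsaturation (0.299)
matches the generator's volume-weighted truth to three decimals. Real
acquisitions enter the same way through `srslipid.read_stack` with the
microscope's voxel geometry.

## Command line

```bash
srslipid phantom      --config cfg.yaml --seed 5 --out run/phantom
srslipid segment      --config cfg.yaml --seed 5 --out run/seg \
                      --stack2900 run/phantom/stack2900.tif \
                      --stack3010 run/phantom/stack3010.tif
srslipid split-cells  --config cfg.yaml --seed 5 --out run/split \
                      --stack2900 run/phantom/stack2900.tif \
                      --droplets run/seg/droplets.csv
srslipid calibrate    --out run/cal --table cc_ratios.csv
srslipid stats        --out run/stats --group-a a1.csv --group-a a2.csv \
                      --group-b b1.csv
```

Each command writes its outputs (label/ratio TIFFs, droplet and per-cell
CSVs, statistics tables), a `run.log`, and a full `config_used.yaml` echo;
reruns with the same inputs, config and seed are byte-identical. All
defaults live in one YAML configuration; unknown keys are rejected.

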