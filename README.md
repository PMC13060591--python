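# tntsim

Desk-scale simulation and outcome quantification for **tissue
nanotransfection (TNT)** of peripheral nerve — the delivery of plasmid DNA
into intact sciatic-nerve tissue through a nanochannel chip under brief
high-voltage pulses — together with the measurements used to score the
resulting regeneration: motor unit number estimation (MUNE), muscle torque
and grip metrics, and fluorescence quantification of nerve cross-sections.

It is written for computational biophysicists and neuroscience labs who
want a transparent, fully seeded model of the chip's electric field and
nanoporation footprint, and a reference implementation of the outcome
arithmetic, with synthetic-data generators that embed exact ground truth
for validating every metric.

## What it computes

**Field and poration.** The chip–nerve interface is rasterized onto a
100 × 100 grid (reservoir / silicon plate pierced by 0.9 µm nanochannels /
conical needles / nerve tissue, with a seeded 65% of channels open). Each
pulse (200 V, 10 ms, 10 pulses by default) is modelled quasi-statically by
solving the conduction equation

∇·(σ∇φ) = 0

with a flux-conservative finite-difference scheme (harmonic-mean face
conductances), Dirichlet electrode rows, and insulating side walls. The
field magnitude |E| = |∇φ| (the conduction form |J|/σ in heterogeneous
regions) is Gaussian-smoothed, mapped to a transmembrane-potential
magnitude by the steady-state Schwan relation ΔV_m = 1.5·E·r, and a tissue
cell nanoporates where |V_m| = |V_rest| + ΔV_m ≥ 200 mV. Action potentials
are capped per cell at ⌊pulse/refractory⌋ per pulse (−55 mV threshold,
1 ms refractory), and porated cells realize transfection as Bernoulli
draws of a clipped Gaussian efficiency.

**Electrophysiology.** CMAP amplitude (baseline-to-peak or peak-to-peak),
average SMUP as the mean of successive differences of 10 incremental
submaximal responses, and

MUNE = max CMAP (peak-to-peak) / average SMUP,

plus twitch/tetanic peak torque (150 Hz × 1 s trains), grip-strength
averaging, and recovery % = 100 × treated / healthy-control.

**Imaging.** Max-intensity projection, per-channel thresholding (manual,
negative-control mean + 3 SD, or Otsu), having/not-having myelination
percentages from NF–MBP component overlap, axons/mm² per fascicle ROI,
DAPI-confirmed CD31 capillaries/mm², and GFP–CD31 coassociation with an
explicit denominator.

## Worked example

```python
import json
from tntsim import (RunConfig, run_pipeline, gen_motor_pool,
                    gen_increment_series, gen_cmap_trace, cmap_amplitude,
                    smup_average, mune, gen_nerve_image, binarize,
                    myelination_fraction, capillary_density, recovery_percent)

# --- chip simulation with all defaults (200 V, 10 ms x 10, 65% open) ---
res = run_pipeline(RunConfig())
print(json.dumps(res.summary.to_dict(), indent=2, sort_keys=True))
```

```
{
  "max_field_V_per_m": 4775839.826270423,
  "max_vm_mV": 15538.263040965237,
  "porated_cells": 4831,
  "porated_fraction": 1.0,
  "realized_cells": 2896,
  "realized_fraction": 0.5994618091492445,
  "tissue_cells": 4831
}
```

All 4831 tissue cells exceed the 200 mV poration threshold — at 200 V
across a ~120 µm window the smoothed field (≈ 4.8 × 10⁶ V/m at the channel
mouths) is far above the ≈ 1.73 × 10⁴ V/m poration level — and 59.9% of
them realize transfection under the Gaussian-efficiency model (mean 0.6).

```python
# --- MUNE on a synthetic 30-unit pool (lognormal amplitudes, CV 0.3) ---
pool = gen_motor_pool(30, mean_amp=0.2, cv=0.3, seed=1)
series, _ = gen_increment_series(pool, n_increments=10, noise_sd=0.05, seed=2)
trace = gen_cmap_trace(pool, noise_sd=0.05, seed=3)
est = mune(cmap_amplitude(trace, "peak_to_peak"),
           smup_average(series, include_zero_baseline=True))
print(round(est, 2))          # 29.31  (true pool size: 30)

# --- image quantification with embedded ground truth ---
bundle, truth = gen_nerve_image(n_axons=50, n_myelinated=20, n_vessels=12, seed=0)
m = myelination_fraction(binarize(bundle.channels["NF"]),
                         binarize(bundle.channels["MBP"]))
print(m.pct_myelinated, m.pct_unmyelinated)   # 40.0 60.0
print(capillary_density(binarize(bundle.channels["CD31"]),
                        binarize(bundle.channels["DAPI"]),
                        bundle.rois["fascicle"], bundle.pixel_size))  # 120.0
print(recovery_percent(7.2, 10.0))            # 72.0
```

The 50-axon / 20-myelinated / 12-vessel section in a 0.1 mm² ROI
quantifies to exactly 40% myelinated, 60% unmyelinated and 120
capillaries/mm² — the generator's embedded truth recovered at default
thresholds.

A `tnt` CLI wraps the same functionality (`tnt run`, `tnt mune`,
`tnt quantify-image`, `tnt generate-synthetic`, ...); see `tnt --help`.

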