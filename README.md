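# petparam

Parametric kinetic modelling for dynamic brain PET with a reversible,
high-binding tracer: regional compartment fitting, voxel-wise parametric
images, and the statistics used to decide whether a parametric method is
good enough to replace the gold standard.

## The problem

Regional non-linear regression of the one-tissue compartment model with
blood volume (1T2k_VB),

    C(t) = (1 − V_B)·K₁·[C_p ⊛ e^(−k₂t)](t) + V_B·C_wb(t),    V_T = K₁/k₂,

is the gold standard for quantifying such tracers, but it needs arterial
blood sampling and is too unstable to run voxel by voxel.  Parametric
methods trade model fidelity for linearity or basis-function structure:
plasma-input Logan and spectral analysis (V_T, K₁ images); reference-region
Logan, the multilinear reference tissue models (MRTMo–4), receptor
parametric mapping (RPM), and SRTM2 (DVR/BP_ND/R₁ images, using a
white-matter reference).  Whether their images are quantitatively accurate
— and repeatable across a 28-day test–retest interval — is an empirical
question.  This package implements the whole chain and answers it on
synthetic data with known ground truth: generator → weighted fits →
parametric maps → agreement (r², slope), % bias, test–retest repeatability
(TRT = (retest − test)/(retest + test) × 200) and the two-way
absolute-agreement average-measures ICC.

## Worked example

```python
import petparam as pp

schedule = pp.FrameSchedule.default()            # 19 frames / 60 min
inp      = pp.make_input_function(schedule=schedule)
weights  = pp.frame_weights(schedule)            # w = 1/sigma^2 from the count model

truth = pp.GroundTruth(K1=0.3, k2=0.06, VB=0.05) # V_T = 5 mL/cm^3
tac   = pp.make_tissue_tac(truth, inp, schedule)

fit = pp.fit_1t2kvb(tac, inp, schedule, weights)
print({k: round(float(v), 4) for k, v in fit.params.items()})
# {'K1': 0.3, 'k2': 0.06, 'VB': 0.05, 'VT': 5.0}

noisy = pp.add_noise(tac, weights, level=0.10, seed=7)
print(round(pp.logan_vt(noisy, inp, tstar=10.0)["VT"], 3))
# 4.001   <- graphical analysis of the same noisy curve: the classic downward bias
```

The fit recovers the generating parameters exactly on noise-free data
(V_T = 5.0), while the Logan estimate of this noisy realization lands
~20 % low — the noise-induced negative bias of graphical methods that the
validation suite quantifies systematically (the Monte-Carlo median bias at
10 % COV is smaller; see `analysis/04_validate.py`).

## Analysis scripts

The numbered drivers under `analysis/` run the full study on a digital
phantom and write tidy tables under `results/`:

1. `01_simulate.py` — three-region dynamic phantom + curves (NIfTI/TSV)
2. `02_fit_roi.py` — regional gold-standard and parametric fits
3. `03_fit_voxelwise.py` — parametric maps and map-vs-ROI consistency
4. `04_validate.py` — noise-free recovery grid, grid-refinement and
   noise-bias Monte Carlo
5. `05_trt.py` — 8-subject paired test–retest cohort (null and −25 %
   effect), TRT and ICC

A thin CLI (`petparam simulate|fit-roi|fit-voxel|validate|trt`) exposes the
same steps on files.

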