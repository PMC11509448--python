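# aortaflow

Quantification of simple and complex aortic flow indices from 2D
through-plane phase-contrast (velocity-encoded) cine MRI, together with the
digital phantoms and method-agreement statistics needed to validate an
automated segmentation pipeline against a manual one.

## Who this is for

Phase-contrast imaging at the aortic root encodes the through-plane blood
velocity of every pixel over the cardiac cycle. Beyond the routine volumes
and velocities, the velocity map carries *complex* flow information —
eccentricity of the systolic jet and systolic retrograde flow — that is
clinically informative (aortopathy risk, valve disease) but rarely
quantified because the analysis is laborious. `aortaflow` provides the full
index set, a phantom generator with analytically known ground truth for
verifying any such pipeline, and the agreement statistics used to compare
two contouring pipelines case by case.

## The indices

Given per-frame velocity maps `v_k` (cm/s, positive = antegrade) and lumen
masks, the net flow rate is `q_k = Σ_mask v · a_px / 100` (mL/s).

**Simple indices** — aortic forward/backward flow `Σ max(q_k,0)·dt` /
`Σ |min(q_k,0)|·dt` over the cycle; systolic forward and retrograde flow
(SFF/SRF), the *pixelwise* antegrade and retrograde volumes within the
systolic window; mean and peak systolic in-mask velocity.

**Complex indices** —

- maximum lumen area over the cycle (cm²);
- systolic flow reversal ratio `sFRR = 100 · SRF / SFF` (%);
- flow displacement `FD = 100 · ‖x_cov − x_c‖ / d_eff` (%), where `x_cov`
  is the antegrade-velocity-weighted centre of velocity, `x_c` the lumen
  centroid and `d_eff = 2√(A/π)`; averaged over systole (FDs_avg) and late
  systole (FDls_avg);
- the rotational angle `RA = atan2` of the centroid→COV vector, unwrapped
  over time; `ΔRA` is its signed change from the first post-peak frame
  where the angle stabilises to end systole. Frames with FD ≤ 12% carry no
  meaningful jet direction and are excluded from angle work.

The systolic window is read off the flow curve: peak = argmax `q`, onset =
where `q` last rose above 10% of peak, end systole = first non-positive
crossing after the peak.

**Agreement statistics** — per index: Pearson r; single-measures two-way
absolute-agreement intraclass correlation
`ICC(A,1) = (MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))`
with its F-based 95% CI; and Bland–Altman bias `d̄` (differences taken
reference − automated), limits of agreement `d̄ ± 1.96·s_d`, bias CI
`d̄ ± t·s_d/√n` and LoA CI `LoA ± t·√(3/n)·s_d`.

## Worked example

A noise-free phantom with a Gaussian jet displaced 25% of the lumen
diameter and a programmed 10% systolic retro fraction, quantified at the
protocol resolution (20 frames, 1.8 mm pixels, venc 200 cm/s):

```python
import aortaflow as af

params = af.PhantomParams(jet_offset_frac=0.25, retro_frac=0.10, noise_sd_cm_s=0.0)
vel, masks, truth = af.generate_phantom(params)
rec = af.quantify_case(vel, masks)
print(f"forward flow : {rec.ao_forward_mL:6.2f} mL   (truth {truth.ao_forward_mL:6.2f})")
print(f"sFRR         : {rec.sfrr_pct:6.2f} %    (programmed 10.00)")
print(f"FDs_avg      : {rec.fds_avg_pct:6.2f} %    (offset 25% of diameter)")
print(f"max area     : {rec.ao_max_area_cm2:6.2f} cm^2 (pi R^2 = 8.04)")
```

```
forward flow :  47.68 mL   (truth  47.58)
sFRR         :   9.99 %    (programmed 10.00)
FDs_avg      :  22.95 %    (offset 25% of diameter)
max area     :   8.13 cm^2 (pi R^2 = 8.04)
```

Forward volume lands within 0.3% of the fine-grid truth and sFRR within
0.01 points of the programmed ratio; FDs_avg sits ~2 points under the
geometric 25% because the jet is truncated by the lumen wall, which pulls
the centre of velocity slightly inward — the fine-grid oracle shows the
same value, so this is jet physics, not discretisation.

Agreement between two pipelines, statsmodels-style:

```python
results = af.MethodAgreement(table_manual, table_auto).fit()
results.summary()            # per-index r, ICC (CI), bias, LoA (CI)
results.ba_points("sfrr_pct")  # Bland-Altman plot data
```

A command line covers the same flow: `aortaflow simulate`, `aortaflow
quantify`, `aortaflow compare`, and `aortaflow run-study` (phantom cohort →
two mask pipelines → agreement tables).

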