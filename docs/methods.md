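# Methods

## Quantification model

All indices derive from a stack of 2D through-plane velocity maps
`v_k(x)` (cm/s, antegrade positive) with per-frame binary lumen masks on
the same grid. The pipeline assumes the data are already in physical
units and unwrapped (no velocity aliasing handling), that the imaging
plane is fixed over the cycle (no valve-plane tracking), and that
background phase offsets have been corrected upstream.

The net flow rate per frame is the mask-restricted Riemann sum
`q_k = Σ v · a_px / 100` (mL/s, with `a_px` in mm²). Frame durations come
from the trigger times; the last frame closes the cycle to the R–R
interval when it is known, otherwise the mean inter-frame spacing is
reused — the convention of retrospectively gated cine covering the full
cycle.

Two sign conventions coexist by design. The cycle-level forward/backward
volumes split the **net** rate by sign, while SFF/SRF accumulate
**pixelwise** antegrade/retrograde velocities within systole only. The
pixelwise pair double-counts opposing flows inside a single frame, so SFF
always bounds the systolic net-positive volume from above; this is the
only reading under which a cohort can show SFF larger than total forward
flow, as validated clinical datasets do.

### Cardiac phases

The systolic window is read off the flow curve: `peak = argmax q`; onset
is the earliest frame of the contiguous run above `onset_frac · max(q)`
ending at the peak (default 10%); end systole is the first non-positive
crossing after the peak, falling back to the post-peak minimum for
curves that never cross zero (e.g. severe diastolic run-off absent). Late
systole spans peak → end systole. These thresholds are config keys
(`RunConfig`), not constants, because the phase definitions are
conventions rather than physics.

### Flow displacement and rotational angle

The centre of velocity uses antegrade weights only, `w = max(v, 0)`:
displacement describes the forward jet, and retrograde pixels would
cancel meaninglessly against it. The "vessel centreline" available on a
single 2D plane is the lumen centroid. Normalisation uses the effective
diameter `d_eff = 2√(A/π)` (radius normalisation available via config).
Angles are measured counterclockwise from the +column axis with the row
axis flipped to standard orientation, and unwrapped over time with a 180°
jump threshold; any fixed convention suffices since only angle
*differences* are reported.

Frames with FD ≤ 12% (config key `fd_gate_pct`) are excluded from
rotational-angle work — at small displacement the direction is noise —
but **not** from the FD averages. The stabilisation point is the first
ungated post-peak frame from which `stab_len` consecutive angle steps
stay within `stab_tol_deg` (defaults 2 steps, 15°; a truncated run at the
window end may qualify with fewer steps). When no frame qualifies the
first ungated post-peak frame is used and a fallback flag is raised;
when fewer than two ungated frames exist, ΔRA is undefined and reported
as NaN rather than a silent number.

### Agreement statistics

ICC is the single-measures two-way absolute-agreement form, computed from
the explicit ANOVA mean squares with the F-based confidence procedure of
the McGraw–Wong framework (the absolute-agreement single-measures point
estimate coincides with the two-way random form). Bland–Altman
differences are taken reference − automated. The LoA multiplier is a
fixed 1.96 (not a t quantile): this is the arithmetic that reproduces
published LoA/CI tables, verified in the acceptance suite by
reconstructing a cohort of n = 125 from printed summary numbers. Bias CI
uses `t·s/√n`, LoA CI uses the standard large-sample approximation
`t·√(3/n)·s`. No multiple-testing correction is applied across indices;
raw p-values are reported. Shapiro–Wilk p on the differences is emitted
as a diagnostic only.

## The phantom

The generator emulates a 1.5 T aortic-root protocol: 20 frames over a
1000 ms cycle, 1.8 mm isotropic pixels, venc 200 cm/s, a circular lumen
of 16 mm radius (area ≈ 8 cm²). It is a *continuous field* sampled at
pixel centres of whatever grid is requested; ground truth is the same
pipeline run on a 10× refined, noise-free sampling, so recovery at
protocol resolution measures genuine discretisation error.

Components and the reasoning behind them:

- **Waveform**: half-sine over the systolic fraction (default 0.35) —
  the simplest smooth, analytically integrable shape matching a normal
  aortic flow curve; diastole carries zero forward flow, plus an optional
  regurgitant half-sine scaled analytically to a programmed volume in mL.
- **Spatial profile**: plug, parabolic, or an eccentric Gaussian jet with
  σ = 0.3 of the lumen radius, centred at `jet_offset_frac` of the
  diameter along `jet_angle_deg`. The width is deliberately on the narrow
  side so the centre of velocity tracks the programmed jet centre; wall
  truncation still pulls FD ~2 points below the geometric offset at 25%
  eccentricity, which the fine-grid oracle confirms is a property of the
  field, not of the discretisation.
- **Retrograde rim**: a smooth crescent (radial band 0.55–0.95 R, ±60°)
  diametrically opposite the jet, mimicking inner-curvature reverse flow.
  Its amplitude is solved by Brent root finding on a fine quadrature grid
  of the continuous profile so the systolic retrograde/forward pixel-flow
  ratio equals `retro_frac` exactly in the continuum; because forward and
  rim share the waveform, the ratio is frame-independent.
- **Noise**: additive Gaussian inside the lumen only (default SD
  5 cm/s); the background is exactly zero — background phase noise and
  offsets are out of scope. Magnitude-image realism is not attempted.
- **Alignment**: the default lumen centre sits a quarter pixel off the
  grid-symmetric position; an exactly symmetric centre is a degenerate
  rasterisation case whose boundary ties inflate the discretised disk
  area.
- **Masks** are the exact rasterised lumen disks (pixel-centre-in-circle).
  Observer emulation perturbs them on the signed distance transform with
  a low-order (4-mode) random Fourier series in boundary angle plus a
  constant bias, both in mm; zero perturbation is the exact identity and
  outputs are bit-reproducible per seed.

What passing phantom tests does **not** show about patient data: no
velocity aliasing or unwrapping, no background offsets, no in-plane
motion or valve excursion, no magnitude contrast for segmentation, a
circular lumen, and noise that is Gaussian rather than Rician. The
phantom validates the *quantification*, not a segmentation model.

With the default 5 cm/s noise the pixelwise SRF acquires a positive
rectification bias (near-zero pixels whose noise flips sign), so sFRR on
noisy phantoms runs above the programmed ratio. Parameter-recovery checks
therefore run noise-free — they characterise discretisation fidelity
against the analytically known truth — while the synthetic repeatability
study keeps the noise on, where it affects both pipelines symmetrically.

## Synthetic validation study

The `run-study` pipeline draws a cohort (default 50 cases) with
case-to-case spread emulating a mixed clinical population: radius
N(16, 1.5) mm with 4% systolic distension, jet peak U(120, 195) cm/s,
eccentricity U(0.15, 0.35) of the diameter (above the 12% gate so ΔRA is
defined for every case), retro fraction U(0.02, 0.20), occasional
diastolic regurgitation, random jet direction with a late-systolic swing
N(0°, 30°). Pipeline A quantifies with the true masks, pipeline B with
0.5 mm-perturbed masks, and the agreement module compares the two index
tables. Problem sizes (50 cases, 64×64 grids, 10× oracle refinement) were
chosen to keep a full study in seconds while leaving discretisation error
well below the recovery tolerances.

## Numerical choices and degenerate inputs

- Unit bookkeeping: cm/s × mm² / 100 → mL/s; ms durations / 1000 → mL.
- Ties in the maximum-area search break to the first frame.
- `vs_peak` is the single maximum in-mask systolic velocity by default; a
  95th-percentile variant is available (`vs_peak_mode="p95"`).
- The sFRR denominator is SFF by default; `sff_plus_srf` is available as
  a bounded-fraction variant. sFRR is an error when SFF = 0.
- COV is undefined (flagged NaN) on frames with no antegrade pixel;
  angles are NaN when COV coincides with the centroid; unwrapping skips
  undefined entries.
- Empty masks, grid mismatches, non-binary mask files, missing sidecar
  fields and non-increasing frame times are rejected with named
  diagnostics; velocities beyond venc without the `unwrapped` flag warn
  but do not fail.
- All randomness flows from explicit integer seeds
  (`numpy.random.default_rng`); phantom, perturbation and study outputs
  are pure functions of (parameters, seed).

## Known limitations

- The cardiac-phase rules (10% onset, zero-crossing end systole, 15°/2
  stabilisation) are reasonable conventions, exposed as config, but other
  software may partition the cycle differently; absolute index values are
  only comparable under matched conventions.
- Reported lumen areas are in cm² (a 16 mm radius ≈ 8.0 cm²); published
  tables sometimes label the same magnitudes mm².
- FD of a wall-truncated jet systematically underestimates the geometric
  jet offset; comparisons should be within-method.
- The agreement module assumes two raters (k = 2); the ICC generalisation
  to more raters is not implemented.
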