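# Methods

## Signal model

The package models one-dimensional longitudinal Bloch dynamics of a voxel
under a periodic RF pulse train. Between pulses the magnetization relaxes
exponentially toward equilibrium, `Mz(t0+dt) = M0 + (Mz(t0) − M0)·e^(−dt/T1)`;
a pulse of flip angle α maps `Mz → Mz·cos α`, and an imaging pulse
additionally emits a readout proportional to `Mz·sin α` at the pulse
instant. Assumptions baked into this model:

- **Perfect spoiling.** No transverse coherence survives between pulses;
  each readout samples only the longitudinal state. This is why the model
  contains no T2 dynamics.
- **Ideal inversions.** Inversion pulses are adiabatic 180° pulses
  (`Mz → −Mz`) and are treated as exact even under B1 inhomogeneity; only
  imaging flip angles are perturbed in the robustness study.
- **Steady state.** Signals are evaluated in the periodic steady state,
  computed in closed form as the fixed point `Mz_eq = B/(1−A)` of the
  per-TR affine map (every relaxation interval and pulse is affine in Mz).
  The physical scanner needs a few warm-up repetitions to get there; those
  are a scan-time consideration, not part of the signal model. A literal
  period-by-period recursion is kept as an independent oracle and the test
  suite verifies closed-form/recursion agreement to 1e−8 on hundreds of
  random pulse trains.
- **Readout timing.** The sample is taken at the pulse time; the EPI echo
  time enters only through the SNR calibration (as T2* amplitude loss),
  never through the signal equation.
- **Gaussian noise on signed signals.** Acquisition noise is additive,
  white, zero-mean Gaussian on the signed model signal — the high-SNR limit
  of Rician magnitude noise. No magnitude operation is applied, even at
  SNR 5 where this approximation is stretched.

Units: milliseconds for all times, degrees at every interface (radians
internally), signals in the arbitrary units of M0. SNR is defined as M0/σ
throughout, not per-readout amplitude over σ.

SPGR signals use the steady-state closed form
`S = M0(1−E1)sin α/(1−E1 cos α)`, `E1 = e^(−TR/T1)`.

## Cramér-Rao bound

For joint (M0, T1) estimation under the Gaussian model the 2×2 Fisher
information has the familiar closed-form entries in `Σh²`, `Σh·∂h/∂T1`,
`Σ(∂h/∂T1)²`, and the T1 bound factors as
`CRB = (SNR·‖∂h/∂T1‖·sin φ)⁻²` with φ the principal angle between **h**
and ∂**h**/∂T1. Numerical choices:

- The sensitivity ∂**h**/∂T1 is a central finite difference with relative
  step `1e−4·T1` (a 4th-order stencil is the accuracy oracle in tests;
  agreement to 1e−6). Finite differences were preferred over symbolic
  differentiation of the piecewise closed form for robustness.
- `cos φ` is clipped to [−1, 1] before `sin φ = √(1−cos²φ)`.
- A design with `sin φ = 0` or zero sensitivity returns `CRB = +∞` rather
  than raising, so the optimizer can penalize unidentifiable designs
  smoothly. A Schur complement below 1e−12 of I22 is treated as zero
  (parallel vectors at rounding level).
- Orthogonality summaries average `sin φ` on a uniform 10 ms grid over
  700–5000 ms and are reported at 2 decimals. The source study does not
  state its grid; the summary is insensitive to steps between 10 and
  100 ms at that precision.

## Min-max design optimization

The design metric is the worst-case relative error `max √CRB(T1)/T1` over
a T1 grid (default 700–2000 ms, 50 ms step — the worst case sits at the
range endpoints for all designs examined, so the result is grid-robust).
Feasibility constraints: TR ≤ 6000 ms, inter-pulse gaps ≥ 100 ms (EPI
readout time), ≥ 100 ms tail after the last pulse, imaging flips in
[0°, 90°]. Infeasible designs are evaluated with a prohibitive additive
penalty of 1e3 rather than rejected; structurally unevaluable geometries
(non-increasing pulse times) get the penalty scaled by the violation so
the simplex is steered back.

The search is annealed Nelder-Mead: vertex ranking and trial-point
acceptance compare costs perturbed by `T·log p` (p uniform), which accepts
uphill moves while T is large; the schedule multiplies T by 0.985 and the
simplex scales by 0.998 per outer iteration from T₀ = 0.8 and scales of
100 ms / 30°, with 2000 simplex iterations per temperature and 1000
temperatures as configuration defaults. The inner count is simplex
iterations (not cost evaluations — the distinction is not pinned down in
the source description). Each outer iteration rebuilds the simplex around
the incumbent best with the shrunken scales; standard Nelder-Mead
coefficients (1, 2, 0.5, 0.5) are used. Multi-start: 3 jittered starts by
default, best feasible result kept; deterministic in the seed. The
initialization is TR 5500 ms, evenly spread pulse times, 45° flips.

The test suite exercises a scaled-down schedule (3 starts × 80 outer × 120
inner iterations, ~15 s) which reaches a worst-case relative error of
0.0173 — slightly better than the published design's 0.0176 — so the full
schedule is not needed to validate the machinery.

## Estimators

- **Separable NLSE (variable projection).** The model is linear in M0, so
  the 2-parameter least-squares fit reduces to minimizing
  `J(T1) = s'[I − h(h'h)⁻¹h']s` over T1, with `M0 = h's/h'h` recovered at
  the optimum. The search is a coarse grid scan (default 100–10000 ms,
  10 ms step) followed by quadratic interpolation on the best grid triple
  (offset clipped to one grid step); ties break toward the smallest T1 and
  boundary hits are flagged but included in Monte-Carlo summaries. The
  joint 2-D fit (`nlse_full`) is retained as the oracle for the variable
  projection identity.
- **DESPOT1 linear fit.** Regress `S/sin α` on `S/tan α`; the slope is E1,
  `T1 = −TR/ln(slope)`. Noise can push the slope outside (0, 1); such
  trials are clipped to the search-grid bounds and flagged. How the source
  study handled invalid slopes is unstated; clipping-and-including is this
  package's convention.

The search range matters at low SNR: the projection objective is nearly
flat in T1 when noise dominates, so estimates spread toward the grid edges
and the *measured bias* is largely a function of where the grid is
truncated. The default (100–10000 ms) spans all plausible brain T1 with
generous headroom; consequences for the low-SNR bias numbers are discussed
under Limitations.

## Monte-Carlo experiments and SNR calibration

The experiment drivers regenerate every signal from the Bloch model at run
time (there are no stored datasets): precision experiments report
`sd(T̂1)/T1` per T1 grid point next to the CRB prediction, accuracy
experiments report `100·|mean(T̂1) − T1|/T1` per SNR at a nominal T1 of
1500 ms, and the B1 study recomputes the CRB relative-error curve with all
imaging flips scaled by 1 + f for f ∈ [−0.2, 0.2]. Study conditions follow
the published setup: M0 = 3000 a.u., 5000 trials per condition, SNR 125
for TSI / 1000 for SPGR in precision runs, SNR 5–60 (TSI scale) in
accuracy runs. All drivers are bit-reproducible given a seed.

What the generator emulates is exactly the estimation-theoretic content of
the study: steady-state amplitudes and white Gaussian noise. What it does
not emulate — Rician magnitude statistics at low SNR, B0/B1 field maps,
slice profiles, imperfect spoiling, EPI readout artifacts, inter-voxel
correlations — means passing tests certify the estimator/bound machinery,
not the behavior of these sequences on a scanner.

Comparing sequences acquired on the same scanner requires adjusting SNR
for acquisition differences. The calibration composes three factors into
the SPGR-over-TSI SNR ratio: receiver bandwidth (SNR ∝ 1/√BW;
±244.1 kHz for the TSI EPI readout vs ±31.3 kHz for SPGR), T2* decay over
the different echo times (e^(−(35−2.4)/48.9) ≈ 0.5), and SENSE rate-2
undersampling (1/√2). The product is ≈ 7.7, i.e. SPGR must be simulated
with 8× the TSI SNR — hence the 125/1000 pairing.

## Design decisions on open points

- **SPGR flip angles.** The study never states the flip angles used in its
  SPGR simulations. The package default {2°, 14°} is drawn from the
  published clinical protocol set {2°, 3°, 14°, 17°} and selected because
  it reproduces the two SPGR quantities the study does print — average
  orthogonality 0.58 and worst-case relative error ≤ 7% over 700–2000 ms
  at SNR 1000. The often-quoted {3°, 17°} pair gives 0.46 and 7.4%,
  inconsistent with both printed values.
- **Eq-level ambiguities.** The printed closed-form weighting expressions
  in the source are typographically garbled; the affine Bloch composition,
  derived from first principles and validated against the explicit
  recursion, is normative here.
- **Mz0 vs M0.** The steady-state expression's initial magnetization
  symbol is read as M0 itself (thermal equilibrium), which the recursion
  oracle confirms is self-consistent.

## Known limitations

- Three published numbers are not reproduced by the exact model, and the
  corresponding checks are intentionally left failing rather than relaxed:
  the original TSI design's average orthogonality computes to 0.927 (prints
  as 0.93, not 0.92); the optimized design's worst-case relative error
  over 700–2000 ms computes to 1.76% at both range endpoints (an equalized
  min-max profile), marginally above the stated 1.7%; and the B1 study's
  deviation over 700–2000 ms reaches 0.26 percentage points at −20%
  scaling, above the stated 0.1 (the companion figures — 0.9 pp for the
  original design and 0.4 pp at T1 = 5000 ms — are reproduced, which
  localizes the discrepancy to that single claim).
- The low-SNR (SNR 5) bias numbers are dominated by the T1 search-range
  convention (see Estimators) and land far above the published 4.19% /
  8.17% under the default range; no defensible range reproduces both, so
  these are treated as qualitative orderings (optimized < original,
  bias shrinking with SNR), which do hold.
- CRBs are for two parameters only (M0, T1); no Rician-likelihood bound,
  no joint T1/T2 extension, no B1 estimation.
- The optimizer fixes the 5-pulse topology (3 imaging + 2 inversions);
  the number of pulses is not a design variable.
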