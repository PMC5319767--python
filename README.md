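# relaxdesign

Estimation-theoretic design and evaluation of MRI pulse sequences for
wide-range T1 relaxometry.

Quantitative T1 mapping estimates the longitudinal relaxation time of
tissue voxel-by-voxel from signals acquired with a repeated RF pulse train.
How precisely T1 can be estimated is not a property of the estimator alone
— it is limited by the pulse times, flip angles, and repetition time of the
sequence itself. `relaxdesign` is for sequence designers and qMRI
methodologists who want to *predict* that limit from the Cramér-Rao bound
(CRB), *optimize* a sequence against it over a broad T1 range, and *verify*
by Monte Carlo that practical estimators reach it.

## The model and the bound

The acquired signal at readout *i* is `s_i = M0 · h_i(T1) + w_i`, with
equilibrium magnetization M0, per-readout signal weighting `h_i(T1)`
derived exactly from the longitudinal Bloch equations (perfect spoiling,
ideal 180° inversions), and white Gaussian noise `w_i` of standard
deviation σ. For joint (M0, T1) estimation the variance of any unbiased T1
estimator satisfies

    var(T̂1) ≥ CRB(T1) = ( SNR · ‖∂h/∂T1‖ · sin φ )⁻² ,   SNR = M0/σ,

where φ is the principal angle between the weighting vector **h** and the
sensitivity vector ∂**h**/∂T1. The three factors — SNR, sensitivity, and
orthogonality — are the only levers a designer has. Sequences are scored by
the worst-case relative error `max_{T1} √CRB(T1)/T1` over a target T1 range
and optimized under scan-time and hardware constraints by a hybrid
Nelder-Mead / simulated-annealing search.

The package ships the two published tissue-specific-imaging (TSI) designs —
a 5-pulse train (3 imaging + 2 inversion pulses) per 6 s TR — and an
SPGR/DESPOT1 protocol for comparison, plus separable-NLSE (variable
projection) and DESPOT1 linear estimators and seeded Monte-Carlo
experiment drivers.

## Worked example

```python
import numpy as np
import relaxdesign as rd

seq = rd.tsi_optimized()                      # published optimized design
print("avg sin(phi) optimized:", round(rd.average_orthogonality(seq), 2))
print("avg sin(phi) original :", round(rd.average_orthogonality(rd.tsi_original()), 2))

grid = np.arange(700.0, 2001.0, 100.0)        # normal brain tissue at 3 T
ps = rd.run_precision_experiment(seq, "nlse", grid, snr=125.0, n_trials=5000, seed=1)
print("max sd(T1)/T1 over 700-2000 ms: %.2f%%  (CRB bound %.2f%%)"
      % (100 * ps.rel_sd.max(), 100 * ps.rel_crb.max()))
```

prints

```
avg sin(phi) optimized: 0.88
avg sin(phi) original : 0.93
max sd(T1)/T1 over 700-2000 ms: 1.77%  (CRB bound 1.76%)
```

The orthogonality summary says the optimized design keeps **h** and
∂**h**/∂T1 at an average `sin φ` of 0.88 across 700–5000 ms, so M0 and T1
changes are well separated in the data. The Monte-Carlo relative standard
deviation of the separable-NLSE estimates (1.77% worst case over the
normal-brain range at SNR 125) sits on top of the CRB prediction (1.76%) —
the estimator is efficient, and the bound is a reliable design metric.

A command-line interface mirrors the library:

```bash
relaxdesign crb --sequence seq.yaml --snr 125 --t1-min 700 --t1-max 5000 --t1-step 10 --out crb.csv
relaxdesign optimize --t1-min 700 --t1-max 2000 --snr 125 --seeds 3 --out result.json
relaxdesign montecarlo precision --sequence seq.yaml --estimator nlse --snr 125 --trials 5000 --seed 1 --out prec.csv
relaxdesign calibrate-snr
```

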