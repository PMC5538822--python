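# hetquant

Quantification toolkit for the cell-biology experiments used to study
RNA-dependent localization of heterochromatin proteins (such as SUV39H1) at
pericentric heterochromatin. It packages, as tested and reusable code, the
five quantitative computations those studies rely on:

1. **Spread-image quantification** (`hetquant.imagequant`) — detect
   centromere spots in a marker channel, match sister pairs, build
   DNA-constrained pericentric regions within a fixed pixel radius, and
   report background-subtracted, control-normalized measurement-channel
   signal per condition.
2. **FRAP kinetics** (`hetquant.frapkit`) — double-normalize
   fluorescence-recovery traces,
   `Inorm(t) = (I(t) − I(bleach)) / (I(0) − I(bleach))` with
   `I(t) = (ROI(t)/ROI(0)) / (total(t)/total(0))`, and fit the
   single-exponential recovery
   `Y = Ymax (1 − e^{−(ln 2 / t_{1/2})(x − x_0)})`
   for the half-time t½ and the mobile fraction Ymax.
3. **Equilibrium binding** (`hetquant.bindfit`) — fraction bound from EMSA
   or filter-binding intensities, Hill-isotherm fits
   `f([P]) = B_max [P]^n / (K_d^n + [P]^n)` for Kd and Hill slope n with
   standard errors, 10-fold affinity classification of mutants, and
   competition-series checks.
4. **Repeat-family RNA enrichment** (`hetquant.repeatstats`) — per-repeat
   read frequencies, knockout/control fold changes, a strict >300-read
   inclusion filter and a mean + 2 SD outlier rule, as a rank-ordered table.
5. **qPCR / RIP arithmetic** (`hetquant.qpcr`) — standard-curve
   amplification efficiency, abundance via `signal = expAmp^{−Ct}`, −RT
   background subtraction, reference-gene normalization, and IP/input
   enrichment folds optionally renormalized to a control sample.

A sixth module, `hetquant.synthdata`, generates synthetic inputs with known
ground truth for every stage (spread images, FRAP traces, titrations,
repeat tables, Ct tables), which is how the whole pipeline is validated:
generate at known parameters, analyze, and check the recovery. See
`docs/methods.md` for models, defaults and limitations.

## Worked example

Simulate 19 wild-type-like FRAP cells (true half-time 27 s, true mobile
fraction 58%, Gaussian noise sd 0.02 on the normalized intensity), fit each
cell, and summarize; then fit a noiseless binding titration generated with
Kd = 23 nM on a 2-fold dilution series from 2.5 µM:

```python
import numpy as np
from hetquant import synthdata as sd, frapkit as fk, bindfit as bf

seeds = np.random.default_rng(1).integers(2**31, size=19)
fits = []
for s in seeds:
    spec = sd.FrapTraceSpec(t_half=27.0, mobile_fraction=0.58, bleach_depth=0.2,
                            acq_bleach=0.995, noise_sd=0.02, seed=int(s))
    fits.append(fk.fit_recovery(fk.normalize_trace(sd.make_frap_trace(spec))))
summary = fk.summarize_frap(fits, "WT")
print(f"{summary.condition}: n={summary.n}  "
      f"t1/2 = {summary.t_half_mean:.1f} +/- {summary.t_half_sd:.1f} s  "
      f"mobile = {summary.mobile_pct_mean:.1f} +/- {summary.mobile_pct_sd:.1f} %")

series = sd.make_titration(sd.TitrationSpec(kd=0.023, hill=1.0, start=2.5,
                                            factor=2.0, n_points=10))
fit = bf.fit_binding(series)
print(f"Kd = {fit.kd*1000:.1f} nM  (Hill slope {fit.hill:.2f})")
```

which prints

```
WT: n=19  t1/2 = 26.9 +/- 2.1 s  mobile = 57.9 +/- 1.7 %
Kd = 23.0 nM  (Hill slope 1.00)
```

The fitted mean half-time and plateau recover the generating kinetics
within sampling error (the per-cell spread reflects the injected noise),
and the noiseless titration returns the generating dissociation constant
essentially exactly.

Every analysis is also reachable from the command line via the `hetquant`
console script (`hetquant simulate ...`, `hetquant quantify spreads ...`,
`hetquant frap fit ...`, `hetquant binding fit ...`,
`hetquant repeats enrich ...`, `hetquant qpcr analyze ...`); run any
subcommand with `--help` for its options.

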