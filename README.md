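# ergocardia

Ergodicity-centered heart-rate-variability (HRV) analysis.

Conventional HRV practice reduces a long RR-interval recording to a handful
of descriptors — mean RR (M), RMS, NN50, pNN50, a DFA exponent, a
multifractal width — and compares them across groups, implicitly assuming
each descriptor is *ergodic*: that any sufficiently long snapshot represents
the subject. `ergocardia` makes that assumption testable and measures what
it costs when it fails. It provides:

- **Synthetic generators**: exact fractional Gaussian noise / Brownian
  motion (Davies–Harte), conservative binomial cascades with a closed-form
  singularity-spectrum oracle, and a cascade-modulated RR-interval model
  with optional ectopic contamination.
- **Preprocessing**: ectopic-interval correction, artifact flagging, cubic
  spline resampling onto an even 2 Hz grid, epoch splitting.
- **Descriptors**: linear epoch series (M, RMS/RMSSD, NN50, pNN50), DFA
  Hurst exponents, Chhabra–Jensen singularity spectra, and the
  surrogate-based multifractal-nonlinearity statistic t_MF (32 IAAFT
  surrogates).
- **Ergodicity analysis**: the Thirumalai–Mountain ergodicity-breaking
  factor E_B for raw series and for descriptor epoch series, original vs
  shuffled, with log-log decay slopes.
- **Monte-Carlo specificity**: repeated short-segment sampling with
  per-iteration group tests, quantifying how descriptor nonergodicity
  degrades snapshot-based group comparisons; plus a pooled mixed-effects
  alternative.
- A `click` CLI (`ergocardia simulate|clean|descriptors|eb|tmf|mc|report`)
  and a fully seeded, byte-reproducible report pipeline.

See `docs/methods.md` for the statistical model, estimator conventions, and
numerical decisions.

## Worked example

```python
from ergocardia import (generate_rri_series, clean_rri, resample_rri,
                        compare_shuffled, tmf, descriptor_epoch_series)

# ~3.7 h of cascade-modulated RR intervals with 0.5% ventricular ectopics
rri = generate_rri_series(cascade_p=0.75, hurst=0.75, length=2**14,
                          ectopic_rate=0.005, seed=42, subject_id="demo")
clean, report = clean_rri(rri)
print(report.n_corrected, report.n_flagged)   # 74 corrected, 1043 flagged

# multifractal nonlinearity of the beat-to-beat intervals
t = tmf(clean.rr_ms, n_surr=32, seed=0)
print(round(t.t_mf, 2), t.significant)        # 4.26 True

# ergodicity breaking of the interpolated series, original vs shuffled
uniform = resample_rri(clean)                 # 26558 samples at 2 Hz
orig, shuf, gap = compare_shuffled(uniform.values, mode="raw", seed=0)
print(round(orig.slope_loglog, 2), round(shuf.slope_loglog, 2))
# -0.50 -1.07  -> the original decays far slower than its shuffle:
# temporal organization, not the value distribution, breaks ergodicity

# 500-beat epoch series of the mean RR descriptor
m = descriptor_epoch_series(clean, "M", epoch_len=500)
print(len(m), m.values[:3].round(1))          # 32 [799.9 788.7 796.6]
```

The same stages are available from the shell:

```bash
ergocardia simulate --seed 3 --out cohort/
ergocardia clean cohort/healthy-000.csv --out clean.csv
ergocardia tmf clean.csv --seed 0
ergocardia eb clean.csv --seed 0
ergocardia mc cohort/ --descriptor M --n-iter 1000 --out rates.csv
ergocardia report --seed 0 --out report/     # full bundle + manifest
```

## Layout

```
src/ergocardia/     library (series, synthetic, preprocess, descriptors,
                    dfa, multifractal, surrogates, ergodicity, montecarlo,
                    pipeline, plotting, cli)
tests/              unit, property-based and acceptance tests
scripts/            acceptance.py
docs/methods.md     model, conventions, numerical decisions
```
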