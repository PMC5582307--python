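# dopbeat

Beat-to-beat fetal heart rate estimation from continuous Doppler
ultrasound (DUS), for researchers in fetal monitoring and biomedical
signal processing.

Routine cardiotocography derives fetal heart rate from the Doppler
envelope by autocorrelation, which averages several beats per
measurement and misstates short-term heart-rate variability (SDNN,
RMSSD). `dopbeat` implements a beat-resolved alternative: the denoised
DUS record is decomposed into intrinsic mode functions (IMFs) by
ensemble empirical mode decomposition,

```
x(t) = Σ_i c_i(t) + r_N(t),
```

and each informative IMF is scanned with a sliding-window kurtosis

```
k(x) = (N − 1) Σ_n x⁴(n) / (Σ_n x²(n))²,
```

a non-centered fourth-moment ratio that is large exactly where a window
contains an impulsive Doppler burst. Kurtosis vectors are computed for
an I×W grid of (IMF level, window size) cells — windows 50–600 ms in
50 ms steps, shifted 1 ms at a time — the best cells are selected
(against reference beats when available, otherwise IMFs 1–3 with
300–400 ms windows), summed, and beats are detected as peaks of the sum
under a 300 ms refractory constraint. Beat-count mismatch, successive
beat error `100·|trueRR(i) − estBB(i)|/trueRR(i)`, beat-location
spread, HRV summaries and Bland–Altman agreement are built in, along
with an adaptive-window autocorrelation (AF) baseline and a synthetic
DUS generator with known ground-truth beats (no clinical corpus with
beat-level truth is publicly available). See `docs/methods.md` for the
full model description.

## Worked example

```python
from dopbeat import EMDKurtosis, AutocorrelationFHR, RunConfig, simulate

# a synthetic 1-min record: 150 beats, mean RR 400 ms, SDNN 13.5 ms,
# RMSSD 9.5 ms, 10 dB burst SNR, with known ground-truth beat times
rec = simulate.make_record(seed=1, snr_db=10.0)

res = EMDKurtosis(rec.dus, RunConfig(ensemble_size=20, seed=3)).fit()
print(res.summary())
report = res.evaluate(rec.true_beats)
print(f"mismatch {report.mismatch_pct:+.1f}%  "
      f"successive beat error {report.mean_successive_beat_error_pct:.1f}%  "
      f"varB_loc {report.var_b_loc_ms:.1f} ms")
```

prints

```
             Beat-to-beat estimation results
==========================================================
Method:                     EMD-kurtosis
Record:                     synthetic DUS
Duration (s):               60.0
Sampling rate (Hz):         1000
----------------------------------------------------------
Beats detected:             143
Mean beat-to-beat (ms):     416.9
Mean FHR (bpm):             143.9
SDNN (ms):                  54.5
RMSSD (ms):                 66.6
Vector selection mode:      default
Vectors summed:             9
Config hash:                5a21c7ed7537
==========================================================
mismatch +4.7%  successive beat error 8.6%  varB_loc 38.9 ms
```

Seven of 150 true beats were missed on this record (+4.7% mismatch; the
cohort RMS is ~2%, see below); the mean interval is recovered within a
few percent, while the estimated SDNN (54.5 ms vs. 13.5 ms target)
overshoots because per-beat detection errors add variance — the known
trade-off of beat-resolved DUS estimation.
`AutocorrelationFHR(rec.dus).fit()` runs the smoother AF baseline on the
same record, and `res.plot_intervals(truth=rec.true_beats)` overlays
estimated and true interval traces.

The same pipeline is scriptable from the shell:

```bash
dopbeat simulate --n-beats 150 --snr-db 10 --seed 1 --out-prefix rec
dopbeat detect --input rec.wav --out beats.csv --seed 3
dopbeat evaluate --truth rec_beats.csv --est beats.csv --out report.json
```

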