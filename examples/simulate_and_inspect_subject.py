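"""Simulate one subject and inspect the lag / spectral structure.

Generates a paired CVP / IJV-CSA recording in which the vein's pulse trails
the pressure wave by 0.24 s, then shows why the time-domain correlation is
misleading while the autocorrelation curves stay aligned.
"""

from jvpulse import (
    WaveformSpec,
    acf_similarity,
    autocorrelation,
    cross_correlation_lag,
    generate_subject,
    pearson_r,
    periodogram_topk,
)

spec = WaveformSpec(lag_s=0.24, dt=0.008)
rec = generate_subject(spec, seed=42, subject_id="demo")

lag = cross_correlation_lag(rec.cvp, rec.csa)
print(f"cross-correlation lag : {lag.incremental_lag} samples = {lag.lag_time:.3f} s "
      f"(negative: the CSA pulse trails the CVP pulse)")

r_time = pearson_r(rec.cvp, rec.csa)
acf_cvp = autocorrelation(rec.cvp, 360)
acf_csa = autocorrelation(rec.csa, 360)
r_acf = acf_similarity(acf_cvp, acf_csa)
print(f"time-domain Pearson r : {r_time:+.3f}  (degraded by the physiological lag)")
print(f"ACF-curve similarity  : {r_acf:+.3f}  (lag-invariant; stays high)")

top = periodogram_topk(rec.cvp, k=3)
print("dominant CVP frequencies (Hz):",
      ", ".join(f"{f:.2f}" for f in top.frequencies_hz))
print("-> cardiac fundamental near 1 Hz with its second harmonic, the")
print("   spectral structure the autocorrelation features encode.")
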