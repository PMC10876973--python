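"""Anesthesia analysis on one synthetic subject: tau1 tracking, effect-site
pharmacokinetics and detrended delta power around loss of consciousness.

Generates a synthetic propofol-induction EEG (known ground truth), runs
the multitaper spectrogram, fits the aperiodic trend per window, and
prints the baseline inhibitory timescale, the fitted dose-response points,
and raw vs detrended delta power around LOC — showing that the raw delta
rise before LOC is a synaptic-kinetics confound while the detrended rise
is locked to LOC itself.
"""

import numpy as np

from aperspectra.cohort import CohortTruth, synth_subject
from aperspectra.pipeline import (band_power, detrended_band_power,
                                  marsh_effect_site, multitaper_spectrogram,
                                  rescale_time, track_tau1)

truth = CohortTruth()  # latency 135 s, tau1 16.7 ms, EC50 3.7 uM, n 1.6
record = synth_subject(truth, rng_seed=1)
print(f"subject: {record.eeg.size / record.fs:.0f} s at {record.fs:.0f} Hz, "
      f"infusion at {record.t_infusion:.0f} s, LOC at {record.t_loc:.0f} s")

spectrogram = multitaper_spectrogram(record.eeg, record.fs, fmax=80)
track = track_tau1(spectrogram, record.t_infusion, stride=20)
print(f"baseline tau1: {track.baseline * 1e3:.1f} ms "
      f"(generator: {truth.tau1_base * 1e3:.1f} ms)")

t_pk, ce = marsh_effect_site(record, t_end=record.eeg.size / record.fs)
print(f"effect-site concentration at LOC: "
      f"{np.interp(record.t_loc, t_pk, ce):.1f} uM")

raw = np.interp(track.times, spectrogram.times, band_power(spectrogram, "delta"))
raw = raw / raw[track.times < record.t_infusion].mean()
det = detrended_band_power(spectrogram, track, "delta",
                           baseline_interval=(1.0, record.t_infusion - 1.0))
rescaled = rescale_time(track.times, record.t_infusion, record.t_loc)
print("rescaled time   raw delta   detrended delta   (1.0 = baseline)")
for lo, hi in [(-0.75, -0.5), (-0.5, -0.25), (-0.25, -0.05), (-0.05, 0.05),
               (0.05, 0.2)]:
    sel = (rescaled >= lo) & (rescaled < hi)
    print(f"[{lo:+5.2f},{hi:+5.2f})    {raw[sel].mean():7.2f}     "
          f"{det[sel].mean():7.2f}")
print("raw delta inflates steadily with tau1; detrended delta steps at 0 (LOC)")
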