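"""Transient-level QC: phase/frequency correction and peak thresholding.

Simulates 24 transients per condition with phase jitter (SD 0.3 rad),
frequency drift (SD 1.5 Hz) and 5 % motion-corrupted transients, runs the
QC chain, quantifies peak areas and fits the stick model to the recovered
decay.
"""

import numpy as np

from metabdiff import AstroSticksParams, DiffusionProtocol
from metabdiff.fitting import FitSpec, fit_model
from metabdiff.synthetic import TransientSpec, generate_transients
from metabdiff.transient_qc import (correct_phase_frequency,
                                    direction_average, quantify_and_average,
                                    threshold_transients)

protocol = DiffusionProtocol()
ts = generate_transients(
    AstroSticksParams(0.346), protocol,
    TransientSpec(snr_b0=20, phase_jitter_sd=0.3, drift_sd_hz=1.5,
                  corrupt_fraction=0.05), seed=11)

corrected, rep = correct_phase_frequency(ts)
_, thr = threshold_transients(corrected)
areas, _ = quantify_and_average(corrected, kept=thr.kept)
curve = direction_average(areas["tNAA"], protocol)
fr = fit_model(curve, FitSpec("astrosticks"), seed=0)

n_total = thr.kept.size
print(f"applied phase corrections: SD {np.std(rep.phase_rad):.3f} rad")
print(f"applied frequency shifts:  SD {np.std(rep.freq_shift_hz):.2f} Hz")
print(f"transients discarded: {n_total - int(thr.kept.sum())} / {n_total}")
print(f"recovered Dintra: {fr.params['Dintra']:.3f} um^2/ms "
      f"(ground truth 0.346)")
print("\nThe threshold removes motion-corrupted (low-amplitude) transients "
      "so the averaged spectra keep their nominal SNR at every b-value.")
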