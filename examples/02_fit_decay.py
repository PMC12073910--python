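"""Fit all four models to one noisy synthetic decay curve.

Generates a direction-averaged tNAA decay from the stick model with
study-matched area noise, fits each model over its b-range, and prints
estimates with 1-sigma uncertainties and bound flags.
"""

from metabdiff import AstroSticksParams, DiffusionProtocol
from metabdiff.fitting import default_specs, fit_model
from metabdiff.synthetic import AreaNoiseSpec, generate_decay

protocol = DiffusionProtocol()
curve = generate_decay(AstroSticksParams(0.346), protocol,
                       AreaNoiseSpec(0.03, 0.04), seed=7)

print("ground truth: stick model, Dintra = 0.346 um^2/ms\n")
for spec in default_specs():
    fr = fit_model(curve, spec, seed=0)
    parts = [f"{k} = {v:.4f} +/- {fr.stderr[k]:.4f}"
             + (" [at lower bound]" if fr.at_lower_bound[k] else "")
             for k, v in fr.params.items()]
    print(f"{spec.model:16s} ({fr.n_points} b-values)  " + ",  ".join(parts))

print("\nThe monoexponential ADC sits near Dintra/3 (orientation average "
      "of a stick), and the modified-stick Kintra stays near zero because "
      "the generating model had none.")
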