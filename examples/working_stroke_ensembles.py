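"""Measure a myosin working stroke by ensemble averaging.

Simulates five molecules under wild-type-like two-substep conditions
(first substep 3.32 nm at attachment, second substep 1.09 nm at ~99/s,
detachment at ~4.6/s), runs the full pipeline, and prints the recovered
working-stroke decomposition.
"""

import trapstroke as ts

traces = []
for i, seed in enumerate((11, 12, 13, 14, 15)):
    config = ts.preset_config("wt", seed=seed, molecule_id=f"molecule-{i}")
    config.duration = ts.duration_for_events(config, 120)
    trace, _ = ts.simulate_dumbbell(config)
    traces.append(trace)

config = ts.PipelineConfig(extension_span_s=1.0)
report = ts.run_pipeline(traces, config)

for mol in report.molecules:
    print(f"{mol.molecule_id}: {mol.n_events} events, "
          f"{'included' if mol.included else 'excluded (' + str(mol.exclusion_reason) + ')'}")

steps = report.combined_steps
print(f"\ncombined over {steps.n_molecules} molecules ({steps.n_events} events):")
print(f"  total working stroke d_total = {steps.total_step:.2f} nm (generator: 4.41)")
print(f"  substep 1 = {steps.substep1:.2f} nm, substep 2 = {steps.substep2:.2f} nm "
      f"(detected: {steps.substep2_detected})")
print(f"  forward rise k = {steps.k_forward:.0f} +/- {steps.k_forward_se:.0f} /s "
      f"(generator substep-2 rate: 99.1)")
print(f"  reverse rise k = {steps.k_reverse:.2f} +/- {steps.k_reverse_se:.2f} /s "
      f"(generator detachment rate: 4.59)")
# The total step and both rise rates recover the generator values; the
# substep split is compressed because the ~10 ms first-substep dwell is
# comparable to the instrument dead time (see docs/methods.md).
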