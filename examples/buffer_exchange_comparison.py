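"""Paired comparison of one molecule under two solution conditions.

Emulates a buffer-exchange experiment: the same molecule is recorded first
with a drug that restores a 3.42 nm two-substep working stroke, then after
washout with a 1.29 nm single-step stroke.  Each segment runs through the
full pipeline independently and the paired difference is reported.
"""

import numpy as np

import trapstroke as ts

seg_duration = 120.0
drug = ts.preset_config("r712l_om200", seed=31, duration=seg_duration,
                        molecule_id="mol-exchange")
washout = ts.preset_config("r712l", seed=32, duration=seg_duration,
                           molecule_id="mol-exchange")
trace_a, _ = ts.simulate_dumbbell(drug)
trace_b, _ = ts.simulate_dumbbell(washout)

# Concatenate the two segments into one continuous recording.
trace = ts.TrapTrace(
    sample_interval=trace_a.sample_interval,
    bead_a=np.concatenate([trace_a.bead_a, trace_b.bead_a]),
    bead_b=np.concatenate([trace_a.bead_b, trace_b.bead_b]),
    molecule_id="mol-exchange", condition="exchange",
)

segments = [
    ts.ConditionSegment("200 uM drug", (0.0, seg_duration)),
    ts.ConditionSegment("washout", (seg_duration, 2 * seg_duration)),
]
config = ts.PipelineConfig(min_events_per_molecule=20, extension_span_s=1.0)
per_condition, differences = ts.compare_conditions(trace, segments, config)

for name, steps in per_condition.items():
    print(f"{name}: d_total = {steps.total_step:.2f} nm over {steps.n_events} events "
          f"(d2 detected: {steps.substep2_detected})")
for name, delta in differences.items():
    print(f"paired change {name}: {delta:+.2f} nm")
# Washing the drug out collapses the working stroke of this single molecule
# from ~3.4 nm to ~1.3 nm; the paired difference isolates the drug effect
# from molecule-to-molecule variability.
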