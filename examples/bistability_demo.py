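"""Partial-cue retrieval and persistent activity in the desk-scale network.

Runs the three-phase bistability protocol on the `mini` preset: a ground
phase (no stimulus), a 300 ms layer-4 cue to one memory pattern's
minicolumns in half of the hypercolumns, and a persistence phase.  A
successful trial completes the pattern (the uncued minicolumns join) and
keeps it active after the cue is removed, while background cells fall
below their ground-state rates.
"""

import columnet as cn
from columnet.protocols import test_bistability

spec = cn.get_preset("mini")
trial = test_bistability(
    spec,
    gain=spec.excitation_gain,
    seed=1,
    phases_ms=(1500.0, 300.0, 3000.0),
    noise_ramp_ms=500.0,
)

print(f"gain {trial.gain}, seed {trial.seed}")
print(f"  ground stable : {trial.ground_stable}")
print(f"  completed     : {trial.completed}")
print(f"  persisted     : {trial.persisted}")
print(f"  PASS          : {trial.passed}")
print(f"  ground rate   : {trial.ground_rate:.2f} /s (all pyramidal)")
print(f"  foreground    : {trial.foreground_rate:.2f} /s")
print(f"  background    : {trial.background_rate:.2f} /s")
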