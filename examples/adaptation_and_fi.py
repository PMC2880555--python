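"""Spike-frequency adaptation of the three cell classes, and a pyramidal
f-I curve.

The adaptation index is the ratio of the last to the first inter-spike
interval under a 1 s current step: pyramidal cells adapt strongly
(index >> 1, a Ca-dependent K+ current builds up with each spike), RSNP
cells moderately, basket cells barely at all.
"""

import numpy as np

import columnet as cn

print("adaptation under a 30 pA somatic step (1 s):")
for ct in ("pyramidal", "RSNP", "basket"):
    res = cn.characterize_adaptation(cn.baseline_neuron(ct), 30.0,
                                     duration=1000.0)
    print(f"  {ct:>10}: {len(res.spike_times):3d} spikes, "
          f"adaptation index {res.adaptation_index:.2f}")

print("\npyramidal f-I curve (1 s steps):")
spec = cn.baseline_neuron("pyramidal")
for amp in np.arange(0.0, 51.0, 10.0):
    spikes, _ = cn.simulate_single_cell(spec, duration=1000.0, i_inj=amp)
    print(f"  {amp:5.1f} pA -> {len(spikes):3d} spikes/s")
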