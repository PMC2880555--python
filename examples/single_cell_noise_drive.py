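"""Fire a pyramidal cell with the standard background noise source.

Each pyramidal cell receives an independent 300 /s Poisson train through
weak (0.08 nS) AMPA synapses on its second apical and basal dendrites.
This source alone should drive the cell at ~8 spikes/s with irregular
spiking (local ISI variability <CV2> ~ 0.69) — the single-cell operating
point of the network's ground state machinery.
"""

import numpy as np

import columnet as cn
from columnet.analysis import cv2

DURATION_MS = 30_000.0

spec = cn.baseline_neuron("pyramidal")
spikes, _ = cn.simulate_single_cell(
    spec, duration=DURATION_MS, noise_rate=300.0, noise_seed=1
)
rate = len(spikes) / (DURATION_MS * 1e-3)
print(f"spikes: {len(spikes)} over {DURATION_MS/1000:.0f} s")
print(f"mean rate: {rate:.2f} /s   (target regime ~8 /s)")
print(f"CV2: {cv2(spikes):.3f}      (1 = Poisson-like, 0 = clock-like)")
print("ISI histogram (ms):",
      np.histogram(np.diff(spikes), bins=[0, 50, 100, 200, 400, 10_000])[0])
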