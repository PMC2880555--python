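"""Excitation-inhibition decomposition at the soma of a hyperpolarized cell.

A background pyramidal cell is injected with a negative somatic current
so it cannot spike while the network retrieves a memory pattern around
it.  (These cells have a high input resistance, so a small holding
current suffices; it keeps the soma between the GABA_A reversal and
threshold, where the sign convention is intuitive.)  All somatic fluxes are then known from the recorded
voltages except the basket (GABA_A) conductance, which is solved from
the flux balance; excitatory (dendritic core influx) and inhibitory
(solved GABA_A) currents can then be compared per activity state.
"""

import numpy as np

import columnet as cn
from columnet.engine import stimulate_pattern

spec = cn.get_preset("mini")
net = cn.build_network(spec)

# hold a background cell (pattern 1) while pattern 0 is cued and active
cell = int(net.pyr_cells_of_mc(int(net.patterns.minicolumns(1)[0]))[0])
cue = stimulate_pattern(net, 0, range(3), onset=800.0, duration=300.0)

res = cn.measure_current_balance(
    net,
    cell_id=cell,
    i_inj_nA=-0.02,
    duration=3000.0,
    stimuli=[cue],
    windows={"ground": (400.0, 800.0), "active": (1300.0, 3000.0)},
)

print(f"measurement valid (no spikes): {res.valid}")
for name in ("ground", "active"):
    m = res.window_means[name]
    print(f"{name:>7}: excitatory {m['excitatory']:+7.1f} pA   "
          f"inhibitory {m['inhibitory']:+7.1f} pA   "
          f"net {m['net']:+7.1f} pA   g_FS {m['g_fs']:.2f} nS")
print(f"median |solved - recorded| GABA conductance: "
      f"{np.median(np.abs(res.residual)):.3f} nS")
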