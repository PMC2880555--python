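"""Build the standard network and report its structural statistics.

The full model is 9 hypercolumns x 49 minicolumns x (30 pyramidal + 1
basket + 2 RSNP) = 14,553 neurons, wired by local (within-minicolumn),
within-hypercolumn (basket feedback) and long-range (pattern-specific)
projections — about 1.9 million synaptic connections in total.  The
realized edge count is compared against the closed-form expectation of
the connectivity rules.
"""

import numpy as np

import columnet as cn
from columnet.network import count_synapses

spec = cn.get_preset("standard9")
net = cn.build_network(spec)
realized, report = count_synapses(net.connectivity, spec)

print(f"cells: {cn.count_cells(spec)}")
print(f"synaptic connections: {realized:,} "
      f"(expected {report['total']['mean']:,.0f} "
      f"± {np.sqrt(report['total']['var']):,.0f})")
print(f"{'projection':>18} {'realized':>10} {'expected':>10}")
for name, row in report.items():
    if name == "total" or "realized" not in row:
        continue
    print(f"{name:>18} {row['realized']:>10,} {row['mean']:>10,.0f}")
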