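"""Simulate one whole-cell recording and run the full per-cell analysis.

Builds the calibrated default neuron, records the activation and
inactivation series with their P/4 subpulse families plus a -10 mV
capacitance test pulse, then measures everything the pipeline extracts:
passive properties, the peak I-V curve, current density and the QC verdict.
"""

import navclamp as nc

config = nc.SimulatorConfig(seed=7)
cell = nc.default_cell_parameters(config)
meta = nc.RecordingMetadata(cell_id="demo-cell", seed=7)

bundle = nc.simulate_cell(cell, config, metadata=meta)
result = nc.analyze_cell(bundle)

print(f"capacitance:      {result.passive.Cm:.1f} pF   (ground truth {cell.Cm:.1f})")
print(f"series resistance:{result.passive.Rs:6.1f} MOhm (ground truth {cell.Rs:.1f})")
print(f"holding leak:     {result.passive.leak_holding_current:+.1f} pA")
print(f"peak current at -12 mV: {result.peak_at_test:.0f} pA")
print(f"current density:  {result.current_density:.1f} pA/pF")
print(f"QC: {'PASS' if result.qc.passed else 'FAIL ' + ','.join(result.qc.reasons)}")
# The density is the study's primary endpoint: the peak inward Na+ current at
# the I-V maximum (-12 mV) normalized to membrane capacitance.  QC requires
# leak <= 100 pA, Rs <= 20 MOhm and an activation voltage range >= 20 mV.
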