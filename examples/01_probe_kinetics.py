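"""Characterize the fluorescent probe: global 1:1 association/chase fit.

Simulates a probe titration (eight twofold dilutions from 10 nM, 240 s
association, then a chase with excess unlabeled ligand) and fits one shared
(k1, k2, Bmax) triple across the whole family.  k1/k2 are the probe's on/off
rates; their ratio is the kinetic KD, which should match the equilibrium
affinity of the probe (~1.1 nM for the wild-type target).
"""

from moafit.kinetics import fit_probe_kinetics
from moafit.synthetic import DEFAULT_PROBE, NoiseModel, simulate_probe_traces

traces = simulate_probe_traces(DEFAULT_PROBE, noise=NoiseModel(cv=0.01), seed=7)
probe = fit_probe_kinetics(traces)

print(f"k1  = {probe.k1:.3e} M^-1 s^-1   (true {DEFAULT_PROBE.k1:.1e})")
print(f"k2  = {probe.k2:.3e} s^-1        (true {DEFAULT_PROBE.k2:.1e})")
print(f"KD  = {probe.kd * 1e9:.2f} nM    (kinetic KD = k2/k1; true 1.10 nM)")
print(f"k2 wide-interval flag: {probe.k2_wide_interval}")
# The kinetic KD from a 1%-noise titration lands within a few percent of the
# probe's equilibrium affinity — the internal consistency check the platform
# relies on before any competitor is measured.
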