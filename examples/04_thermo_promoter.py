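"""Thermodynamic promoter model for a three-input G2/M promoter.

Statistical-mechanics alternative to the Hill-logic forms: promoter
occupancy states are Boltzmann-weighted from TF affinities, cooperative
interactions, and per-configuration polymerase attraction.  The example
prints the admissible occupancy states of the Kip2-like architecture
(overlapping forkhead platforms, recruited coactivator) and a 1-D
dose-response of the coactivator at fixed platform levels.
"""

import numpy as np

from grfkit import (enumerate_states, evaluate_thermo, kip2_architecture,
                    kip2_parameter_names, kip2_params)

arch = kip2_architecture()
states = enumerate_states(arch)
print(f"{len(states)} admissible occupancy states:")
for s in sorted(states, key=lambda s: (len(s), sorted(s))):
    print("   {" + ", ".join(sorted(s)) + "}" if s else "   {} (empty promoter)")

params = kip2_params({
    "affinity_fkh2": 1.0, "affinity_fkh1": 0.8, "affinity_ndd1": 1.2,
    "coop_fkh2_ndd1": 4.0, "coop_fkh1_ndd1": 2.0,
    "coop_mcm1_fkh2": 5.0, "coop_mcm1_ndd1": 1.5,
    "pol_fkh2_ndd1": 8.0, "pol_fkh1_ndd1": 4.0, "pol_fkh1": 1.5,
    "basal": 0.05, "scale": 0.1,
})
print(f"\nfree parameters: {len(kip2_parameter_names())}")
print("coactivator dose-response (platforms at 1.0):")
for c in np.geomspace(0.01, 10.0, 6):
    rate = evaluate_thermo(arch, params,
                           {"Mcm1": 1.0, "Fkh2": 1.0, "Fkh1": 1.0, "Ndd1": float(c)})
    print(f"  Ndd1 = {c:6.2f} -> synthesis rate {rate:.4f}")
print("\nThe rate rises from near-basal to saturation as the recruited")
print("coactivator fills the activating configurations.")
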