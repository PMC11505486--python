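"""Parameter recovery of the counting estimator across selection regimes.

For each planted omega the mean estimate over 20 simulated pairs is shown.
Recovery is monotone; under transition-biased mutation (kappa = 2) the
equal-weight site counting slightly underestimates omega — the classic
limitation of counting methods, quantified here.
"""

import numpy as np

from evorate import SimulationParams, estimate_pair, simulate_pair

for omega in (0.1, 0.5, 1.0):
    vals = [
        estimate_pair(*simulate_pair(SimulationParams(
            omega_true=omega, kappa=2.0, t=0.3, n_codons=2000, seed=s)
        )).omega
        for s in range(20)
    ]
    m = np.mean(vals)
    print(f"planted omega {omega:.1f}: mean estimate {m:.3f} "
          f"(relative error {100 * (m - omega) / omega:+.1f}%)")
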