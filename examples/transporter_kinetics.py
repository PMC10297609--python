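"""Transporter binding and unbinding statistics.

Shows the three building blocks of the transporter model: the first-order
binding law P = 1 - exp(-t/Psi) for a particle dwelling near an astroglial
surface, the ~0.35 / 0.65 split between unbinding and translocation fates,
and the S-shaped (cumulative Gaussian) release schedule with median 4 ms.
"""

import numpy as np

from gluspill import (TransporterSpec, assign_fate_and_schedule,
                      binding_probability, release_schedule_cdf)
from gluspill.transporters import FATE_UNBIND

spec = TransporterSpec()          # Psi = 1 ms, p_unbind = 0.35, 4 +/- 2 ms
print("contact time ->  cumulative binding probability (Psi = 1 ms)")
for t in (0.1, 0.5, 1.0, 2.0, 5.0):
    print(f"  {t:4.1f} ms     ->  {binding_probability(t, spec.psi_ms):.4f}")

rng = np.random.default_rng(0)
fates, release = assign_fate_and_schedule(np.arange(100_000), 0.0, spec, rng)
frac = np.mean(fates == FATE_UNBIND)
delays = release[fates == FATE_UNBIND]
print(f"\nfraction of bindings that unbind: {frac:.4f} (model value 0.35)")
print(f"median release delay: {np.median(delays):.3f} ms "
      f"(schedule median 4 ms; zero-truncation shifts it by ~0.06 ms)")
print(f"S-function CDF at 4 ms: {release_schedule_cdf(4.0):.3f} (exactly 0.5)")
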