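"""Physical decay data for Lu-177 (configurable for other nuclides).

Lu-177 decays with a half-life of 6.647 days. Its absorbed dose is dominated
by beta particles and conversion/Auger electrons; the mean electron energy
emitted per decay (``DELTA_E_MEV``) drives the local-deposition sphere model
in :mod:`hybridose.dosimetry`. The 208 keV gamma line (10.4% abundance) is
what the gamma camera images.
"""

import numpy as np

#: Lu-177 physical half-life in hours (6.647 d).
LU177_HALF_LIFE_H: float = 6.647 * 24.0

#: Lu-177 physical decay constant, 1/h.
LU177_LAMBDA_PHYS: float = float(np.log(2.0) / LU177_HALF_LIFE_H)

#: Mean electron (beta + conversion + Auger) energy per decay, MeV.
LU177_DELTA_E_MEV: float = 0.1479

#: Abundance of the imaged 208 keV photon (documentation value).
LU177_ABUNDANCE_208KEV: float = 0.104

MEV_TO_J: float = 1.602176634e-13
#: Number of decays per MBq·h of time-integrated activity.
DECAYS_PER_MBQ_H: float = 1e6 * 3600.0


def decay_factor(t_h: float, lambda_per_h: float = LU177_LAMBDA_PHYS) -> float:
    """Fraction of activity remaining after ``t_h`` hours."""
    return float(np.exp(-lambda_per_h * t_h))
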