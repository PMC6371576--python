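"""Unit conventions and conversions.

Airway and alveolar pressures are carried in cmH2O, vascular pressures in
mmHg, volumes in ml, flows in ml/s (blood) or ml/min (gas), time in s.
Compliances follow their pressure convention (ml/cmH2O for the lung,
ml/mmHg for vessels).  Every cross-domain conversion goes through the two
constants below so there is exactly one place to audit.
"""

MMHG_PER_CMH2O = 0.735559
CMH2O_PER_MMHG = 1.0 / MMHG_PER_CMH2O

#: Standard barometric pressure, mmHg.
P_BAROMETRIC = 760.0
#: Saturated water-vapour pressure at 37 C, mmHg.
P_H2O = 47.0


def cmh2o_to_mmhg(p: float) -> float:
    return p * MMHG_PER_CMH2O


def mmhg_to_cmh2o(p: float) -> float:
    return p * CMH2O_PER_MMHG
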