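"""Unit system and physical constants.

All quantities are kept O(1) at tissue scale:

================  =========================
length            µm
time              ms
diffusivity       µm²/ms
gradient          mT/m
b-value           ms/µm²  (1 ms/µm² = 1000 s/mm²)
permeability      µm/ms
================  =========================
"""

#: Gyromagnetic ratio of ¹H, 2.675153e8 rad s⁻¹ T⁻¹, expressed in
#: rad · ms⁻¹ · (mT/m)⁻¹ · µm⁻¹ so that ``GAMMA * g[mT/m] * x[µm]`` is a
#: phase rate in rad/ms.
GAMMA = 2.675153e8 * 1e-3 * 1e-3 * 1e-6  # = 2.675153e-4

#: Conversion factor: 1 ms/µm² = 1000 s/mm².
B_MS_UM2_PER_S_MM2 = 1e-3
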