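# Ex-vivo acquisition set: two PGSE diffusion times, one 50 Hz cosine OGSE,
# one STEAM long diffusion time; single gradient direction, g_max 360 mT/m.
# b-values are filled in at load time (five values, log-spaced from 0 to
# 1 ms/um^2 or the hardware maximum, whichever is lower).
protocols:
  - kind: PGSE
    delta_ms: 3.0
    Delta_ms: 11.0
    g_max_mT_per_m: 360.0
    TE_ms: 55.0
    protocol_id: pgse_3_11
  - kind: PGSE
    delta_ms: 3.0
    Delta_ms: 31.0
    g_max_mT_per_m: 360.0
    TE_ms: 55.0
    protocol_id: pgse_3_31
  - kind: OGSE_cosine
    delta_ms: 20.0
    Delta_ms: 25.0
    frequency_hz: 50.0
    g_max_mT_per_m: 360.0
    TE_ms: 55.0
    protocol_id: ogse50_20_25
  - kind: STEAM
    delta_ms: 3.0
    Delta_ms: 71.0
    g_max_mT_per_m: 360.0
    TE_ms: 55.0
    protocol_id: steam_3_71
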