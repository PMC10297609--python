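# Five-state NMDA receptor kinetic scheme
#
#   U <-> C1 <-> C2 <-> O
#                 ^
#                 v
#                 D
#
# Glutamate-dependent forward binding (kon, per mM per ms) on U->C1 and
# C1->C2; all other rates in per ms. Values are the published set of the
# standard five-state NMDAR model of Destexhe, Mainen & Sejnowski
# (1994/1998; the widely redistributed "nmda5" parameter set:
# Rb = 5e6 M^-1 s^-1, Ru = 12.9 s^-1, Rd = 8.4 s^-1, Rr = 6.8 s^-1,
# Ro = 46.5 s^-1, Rc = 73.8 s^-1). Swap this file to use another scheme.
states: [U, C1, C2, D, O]
rates:
  kon_per_mM_ms: 5.0        # U->C1 and C1->C2, times [glu]
  koff_per_ms: 0.0129       # C2->C1 and C1->U
  k_desens_per_ms: 0.0084   # C2->D
  k_resens_per_ms: 0.0068   # D->C2
  k_open_per_ms: 0.0465     # C2->O
  k_close_per_ms: 0.0738    # O->C2
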