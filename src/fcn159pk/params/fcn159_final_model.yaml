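# Final population-PK model parameters for FCN-159 (adult melanoma + NF1).
# omegas are SDs of the lognormal between-subject random effects
# (reported percentages / 100); sigma_prop is the proportional residual SD.
fixed_effects:
  cl_typ: 13.2      # CL/F, L/h
  vc_typ: 48.7      # Vc/F, L
  q_typ: 35.1       # Q/F, L/h
  vp_typ: 314.0     # Vp/F, L
  ka: 0.5           # 1/h
  alag: 0.211       # h
  f_nf1: 1.29       # relative bioavailability, NF1 vs melanoma
  exp_cl_bsa: 1.11
  exp_q_bsa: 2.20
  exp_vp_bsa: 3.84
  exp_vc_bsa: 2.41
  exp_vc_tp: -3.1
  frac_vp_female: 0.751
  bsa_ref: 1.66     # m^2
  tp_ref: 68.95     # g/L
random_effects:
  omega_cl: 0.19
  omega_vc: 0.694
  omega_q: 0.26
  omega_vp: 0.265
  sigma_prop: 0.258
  sigma_add: 0.0
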