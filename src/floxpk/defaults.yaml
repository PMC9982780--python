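# Default population-model configurations (one block per model variant).
# Final model: CL_tot = f_r * CLcr, f_u = f_u_pop * (Alb/alb_ref)^-ex.
# Units: v_typ L per 70 kg; cl_typ_base L/h per 70 kg^0.75; iiv and sigma CV%.
# Note: the published parameter table also lists the final-model unbound
# fraction as a summary percentage (25%); the covariate equation constants
# (f_u_pop 0.217 at alb_ref 21.2 g/L) are the operative defaults here.
final:
  variant: final
  f_r: 19.0
  v_typ: 330.0
  f_u_pop: 0.217
  alb_ref: 21.2
  ex: 0.67
  cl_typ_base: 52.8
  iiv: {fr: 71.0, v: 84.0, fu: 26.0, ex: 88.0}
  sigma_total: 42.0
  sigma_unbound: 35.0

base:
  variant: base
  cl_typ_base: 52.8
  v_typ: 324.0
  f_u_pop: 0.24
  alb_ref: 21.2
  ex: 0.0
  f_r: 19.0
  iiv: {cl: 127.0, v: 79.0, fu: 31.0}
  sigma_total: 44.0
  sigma_unbound: 35.0

egfr_only:
  variant: egfr_only
  f_r: 19.0
  v_typ: 330.0
  f_u_pop: 0.24
  alb_ref: 21.2
  ex: 0.0
  cl_typ_base: 52.8
  iiv: {fr: 71.0, v: 84.0, fu: 31.0}
  sigma_total: 42.0
  sigma_unbound: 35.0

albumin_only:
  variant: albumin_only
  cl_typ_base: 52.8
  v_typ: 324.0
  f_u_pop: 0.217
  alb_ref: 21.2
  ex: 0.67
  f_r: 19.0
  iiv: {cl: 127.0, v: 79.0, fu: 26.0, ex: 88.0}
  sigma_total: 42.0
  sigma_unbound: 35.0
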