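# Final published population PK/PD model of remimazolam and its inactive
# metabolite CNS 7054 (healthy adult volunteers, 60 kg reference weight).
# Units: clearances L/min, volumes L, rate constants 1/min, IC50 ng/mL.
pk:
  CL_p: 1.21
  V1: 16.0
  Q2: 2.61
  V2: 22.6
  Q3: 0.227
  V3: 23.5
  K_tr: 0.447
  CL_m: 0.0637
  V5: 3.72
  Q4: 0.166
  V6: 5.15
pd:
  Imax: 54.5
  IC50: 504.0
  BIS_baseline: 92.5
  ke0: 1.38
  Hill: 1.44
variability:
  omega:
    CL_p: 0.20
    V1: 0.55
    Q2: 0.243
    V2: 0.321
    K_tr: 0.401
    CL_m: 0.221
    V5: 0.301
    V6: 0.175
    Imax: 0.272
    Hill: 0.488
  sigma_prop_parent: 0.232
  sigma_prop_metab: 0.064
  sigma_add_metab: 43.13
  rho_pm: 0.0066
  sigma_prop_bis: 0.112
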