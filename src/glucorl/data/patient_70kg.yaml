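# Nominal 70 kg Hovorka virtual patient with type 1 diabetes.
# Rates per minute, volumes L/kg, sensitivities per mU/L.
body_weight: 70.0
k12: 0.066
ka1: 0.006
ka2: 0.06
ka3: 0.03
s_it: 0.00512
s_id: 0.00082
s_ie: 0.052
ke: 0.138
v_i: 0.12
v_g: 0.16
ag: 0.8
t_max_g: 40.0
t_max_i: 55.0
egp_0: 0.0161
f_01: 0.0097
k_int: 0.073
sensor_compartment: interstitial
# Insulin-to-carb ratio (g of CHO per U of bolus insulin), frozen from the
# packaged calibration routine: largest bolus that causes no hypoglycemia
# over 8 h for a nominal 60 g meal on top of b*, sized from the worst-case
# +30% overestimated carb count (see glucorl.env.calibrate_icr).
icr_g_per_u: 27.21868038177490
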