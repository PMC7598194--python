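# Age-dependent physiology (maturation) snapshot, indexed by postmenstrual age (PMA)
# in weeks (PMA = gestational age + 52.14 * chronological age in years).
# body_weight/height: typical values for age (used only when the caller does not
# supply them). hematocrit: age profile with the physiologic nadir around 2-3 months.
# *_vol_mult columns: organ volume multipliers relative to weight-proportional adult
# body composition (e.g. the brain claims a much larger share of body volume at term
# birth); organs without a column scale proportionally to body weight. blood_vol_mult
# scales total blood volume per kg (neonates carry more blood per kg than adults).
# *_flow_mult columns: multipliers on the adult fraction-of-cardiac-output (fractions
# are renormalized to sum to 1 after applying them). Values between knots are
# interpolated linearly; outside the knot range the nearest knot value is used.
pma_weeks,body_weight_kg,height_cm,hematocrit,brain_vol_mult,liver_vol_mult,kidney_vol_mult,fat_vol_mult,muscle_vol_mult,skin_vol_mult,blood_vol_mult,brain_flow_mult,kidney_flow_mult
24,0.65,31,0.47,6.2,1.35,1.9,0.08,0.50,1.9,1.30,1.35,0.28
28,1.10,37,0.48,6.0,1.30,1.8,0.15,0.55,1.8,1.25,1.40,0.30
32,1.80,42,0.50,5.8,1.25,1.7,0.25,0.55,1.7,1.20,1.45,0.32
40,3.50,51,0.53,5.5,1.20,1.6,0.60,0.58,1.5,1.15,1.60,0.35
48,4.50,55,0.42,5.3,1.20,1.55,0.90,0.60,1.4,1.10,1.80,0.50
66,7.50,67,0.35,4.8,1.15,1.5,1.00,0.62,1.3,1.05,2.00,0.65
92,10.0,75,0.36,4.3,1.15,1.4,0.95,0.65,1.25,1.00,2.20,0.75
191.2,14.0,95,0.37,4.0,1.10,1.3,0.80,0.72,1.15,1.00,2.40,0.85
300,18.0,109,0.38,2.8,1.10,1.2,0.70,0.78,1.10,1.00,2.30,0.90
561,32.0,138,0.40,2.2,1.05,1.1,0.75,0.85,1.05,1.00,1.80,0.95
1083,70.0,176,0.44,1.02,1.00,1.0,1.00,1.00,1.00,1.00,1.05,1.00
1604,73.0,176,0.45,1.00,1.00,1.0,1.00,1.00,1.00,1.00,1.00,1.00
4212,73.0,176,0.45,1.00,1.00,1.0,1.00,1.00,1.00,1.00,1.00,1.00
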