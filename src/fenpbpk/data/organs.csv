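# Adult reference anatomy/physiology snapshot (30-year-old European male, 73 kg).
# Organ volumes (L, including regional blood) and blood-flow fractions of cardiac
# output follow ICRP-style reference-man tables; regional vascular fractions are set
# so that total blood volume sums to ~5.3 L with the arterial/venous/portal pools.
# Tissue composition columns (fractional water, neutral lipid, neutral phospholipid,
# acidic phospholipid in mg/g, intracellular pH) are the standard tissue-composition
# tables used by perfusion-limited partition-coefficient methods for ionizable drugs.
# albumin_ratio is the interstitial:plasma binding-protein ratio used for interstitial
# binding; lipoprotein_ratio is carried for completeness. pgp_destination: where P-gp
# efflux from the cellular space is routed (excreta = terminal efflux accumulator,
# vascular = back into the organ's vascular space, none = no P-gp in this organ).
# Blood pools (arterial_blood, venous_blood, portal_vein) have no tissue spaces.
name,total_volume_l,flow_frac,frac_vascular,frac_interstitial,f_water_ec,f_water_ic,f_neutral_lipid,f_neutral_phospholipid,acidic_phospholipid_mg_g,ph_ic,albumin_ratio,lipoprotein_ratio,pgp_destination
lung,1.00,1.0,0.50,0.19,0.336,0.446,0.0220,0.0130,3.91,7.0,0.5,0.5,none
brain,1.45,0.12,0.04,0.16,0.162,0.620,0.0390,0.0015,0.40,7.0,0.5,0.5,vascular
heart,0.33,0.04,0.18,0.14,0.320,0.456,0.0115,0.0166,2.25,7.0,0.5,0.5,none
muscle,29.0,0.17,0.035,0.12,0.118,0.630,0.0100,0.0072,1.53,7.0,0.5,0.5,none
bone,10.5,0.05,0.07,0.10,0.100,0.346,0.0174,0.0016,0.67,7.0,0.5,0.5,none
skin,3.30,0.05,0.08,0.30,0.382,0.291,0.0603,0.0044,1.32,7.0,0.5,0.5,none
fat,18.2,0.05,0.015,0.14,0.135,0.017,0.8530,0.0016,0.40,7.0,0.5,0.5,none
gonads,0.035,0.0005,0.04,0.14,0.255,0.525,0.0048,0.0057,2.00,7.0,0.5,0.5,none
kidney,0.31,0.19,0.16,0.20,0.273,0.483,0.0121,0.0240,5.03,7.0,0.5,0.5,excreta
liver,2.30,0.065,0.23,0.16,0.161,0.573,0.0135,0.0238,4.56,7.0,0.5,0.5,excreta
stomach,0.15,0.01,0.08,0.10,0.268,0.475,0.0375,0.0154,2.41,7.0,0.5,0.5,none
small_intestine,0.64,0.10,0.08,0.13,0.282,0.475,0.0375,0.0125,2.41,7.0,0.5,0.5,excreta
large_intestine,0.37,0.04,0.08,0.13,0.282,0.475,0.0375,0.0125,2.41,7.0,0.5,0.5,excreta
pancreas,0.14,0.01,0.08,0.12,0.120,0.664,0.0403,0.0093,1.67,7.0,0.5,0.5,none
spleen,0.19,0.03,0.22,0.15,0.207,0.579,0.0077,0.0113,3.18,7.0,0.5,0.5,none
gallbladder,0.05,0.0005,0.08,0.13,0.161,0.573,0.0135,0.0238,4.56,7.0,0.5,0.5,none
arterial_blood,0.55,,1.0,0.0,,,,,,,,,none
venous_blood,1.20,,1.0,0.0,,,,,,,,,none
portal_vein,0.07,,1.0,0.0,,,,,,,,,none
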