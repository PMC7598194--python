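# Ontogeny snapshot: protein abundance as fraction of the adult level, indexed by
# postmenstrual age in weeks. Piecewise-linear between knots, clamped outside.
# CYP3A4 rises from very low fetal/preterm levels to the adult level over the first
# years of life (shape mirrors published hepatic CYP3A4 ontogeny databases).
# CYP3A7 is the major fetal CYP3A form: it peaks around term birth at >10x the small
# adult remnant level and decays over the first months.
# PGP (P-glycoprotein): piecewise-linear fit to published age-group medians from
# proteomic quantification (low in neonates, adult level reached in adolescence).
# AAG (alpha-1-acid glycoprotein): plasma-concentration ratio to adults; the 32-week
# and 191.2-week (2.9 y) knots anchor the scaled unbound fentanyl fractions of 33%
# and 29% produced by AAG-based unbound-fraction scaling from fu_adult = 20.8%.
protein,pma_weeks,factor
CYP3A4,24,0.02
CYP3A4,32,0.05
CYP3A4,40,0.11
CYP3A4,44,0.16
CYP3A4,53,0.30
CYP3A4,66,0.48
CYP3A4,92,0.72
CYP3A4,144,0.88
CYP3A4,248,0.96
CYP3A4,400,1.00
CYP3A4,1604,1.00
CYP3A7,24,11.0
CYP3A7,36,13.0
CYP3A7,40,12.5
CYP3A7,44,9.0
CYP3A7,53,4.5
CYP3A7,66,2.2
CYP3A7,92,1.5
CYP3A7,144,1.2
CYP3A7,300,1.05
CYP3A7,600,1.00
CYP3A7,1604,1.00
PGP,24,0.22
PGP,32,0.28
PGP,40,0.34
PGP,53,0.42
PGP,66,0.50
PGP,92,0.60
PGP,191.2,0.74
PGP,400,0.85
PGP,561,0.90
PGP,1100,0.97
PGP,1604,1.00
AAG,24,0.500
AAG,28,0.515
AAG,32,0.533211
AAG,40,0.556
AAG,66,0.580
AAG,92,0.600
AAG,191.2,0.642983
AAG,300,0.700
AAG,561,0.820
AAG,1100,0.950
AAG,1604,1.000
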