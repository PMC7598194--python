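# Effective adult enzyme/transporter concentrations in the cellular space of the
# organs carrying each protein (umol/L of cellular volume). The CYP3A4 value is the
# published Open Systems Pharmacology reference concentration for hepatic CYP3A4;
# CYP3A7 is the small adult remnant (its ontogeny multiplier exceeds 10 at birth).
# P-gp values are effective transport capacities chosen small: the printed adult
# elimination pathway split attributes essentially no terminal elimination to P-gp
# and local sensitivity of exposure to P-gp is negligible.
# Vmax (umol/min) for a Michaelis-Menten process = kcat * ref_conc * ontogeny *
# expression multiplier * cellular volume of the organ.
protein,organ,ref_conc_umol_l
CYP3A4,liver,4.32
CYP3A7,liver,0.35
PGP,liver,0.05
PGP,kidney,0.03
PGP,small_intestine,0.04
PGP,large_intestine,0.02
PGP,brain,0.04
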