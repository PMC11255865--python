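"""Literature-reported biophysical parameters for human gamma-D-crystallin.

Two-state unfolding parameters (GdnHCl midpoint Cm in M and m-value in
kcal/mol/M; the unfolding free energy follows as dG = m * Cm) and diffusion
interaction parameters (kd, mL/g) for the wild-type protein and the
cumulative Asn->Asp ("N-less") deamidation variants. These serve as the
ground-truth conditions for the synthetic-data generators.
"""

GDCRYSTALLIN_VARIANTS = {
    "wild-type": {"Cm": 3.0, "m": 2.4, "kd": -3.0},
    "N-less": {"Cm": 2.4, "m": 1.9, "kd": -4.0},
    "N-less NTD": {"Cm": 2.6, "m": 1.8, "kd": -5.0},
    "N-less CTD": {"Cm": 2.4, "m": 1.9, "kd": -5.0},
}

#: Asn->Asp substitution sites in the N-terminal and C-terminal domains.
NTD_SITES = (24, 33, 49)
CTD_SITES = (118, 124, 137, 160)

#: Reference diffusion coefficient for gamma-D-crystallin, cm^2/s.
D0_CM2_S = 8.0e-7
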