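"""Physical constants for CsCl-gradient qSIP calculations with heavy water.

All published qSIP constants used by both the estimator and the forward
simulator live here, so an alternative calibration can be swapped in one
place.
"""

#: Slope of unlabeled DNA buoyant density (g/mL) per unit GC content.
DENSITY_PER_GC = 0.083506

#: Buoyant density (g/mL) of unlabeled DNA at GC = 0.
DENSITY_GC0 = 1.646057

#: Slope of the mean nucleotide molecular weight (g/mol) per unit GC content.
MW_PER_GC = 0.496

#: Mean nucleotide molecular weight (g/mol) of unlabeled DNA at GC = 0.
MW_GC0 = 307.691

#: Maximum mass gain (g/mol per average nucleotide) when every exchangeable
#: oxygen atom in DNA is replaced by 18O.
MAX_MASS_GAIN_18O = 12.07747

#: Natural abundance of 18O (atom fraction).
NAT_ABUND_18O = 0.002000429
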