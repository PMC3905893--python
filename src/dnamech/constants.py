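"""Physical constants and unit conversions (CGS where the field uses CGS).

Torsional rigidity C is handled internally in erg.cm, the unit in which
nucleic-acid torsion moduli are conventionally reported; all I/O surfaces
use the 1e-19 erg.cm scale with unit-suffixed keys.
"""

#: Boltzmann constant, erg/K (CGS).
K_B_ERG_PER_K = 1.380649e-16

#: Avogadro's constant, 1/mol.
N_AVOGADRO = 6.02214076e23

#: Reference absolute temperature, K (ligation assays at ~22 C).
T_REF_K = 295.15

#: Axial rise per base pair for B-form DNA, nm/bp.
RISE_NM_PER_BP = 0.34

#: Gas constant in thermochemical calories, cal/(mol K).
R_CAL = 1.987204

#: Conversion: number density in molecules/nm^3 -> molar concentration (mol/L).
#: 1 molecule/nm^3 = 1e24 molecules/L = 1e24/N_A mol/L.
MOLEC_PER_NM3_TO_M = 1.0e24 / N_AVOGADRO

#: nm per cm.
NM_PER_CM = 1.0e7
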