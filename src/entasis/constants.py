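"""Physical constants in the package's single unit system.

Energies are kcal/mol, lengths Å, times ps, temperatures K. The per-mole
convention is used for hbar so that the Marcus prefactor |V|^2/ħ comes out
in s^-1 when the coupling V is given in kcal/mol.
"""

#: Boltzmann constant, kcal mol^-1 K^-1 (CODATA, per-mole convention).
KB_KCAL_MOL_K: float = 1.987204e-3

#: Reduced Planck constant, kcal s mol^-1 (CODATA, per-mole convention).
HBAR_KCAL_S_MOL: float = 1.51787e-14

#: Default simulation temperature in K ("room temperature").
DEFAULT_TEMPERATURE_K: float = 300.0
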