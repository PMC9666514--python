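"""Physical constants and pipeline-wide defaults.

All energies are in kJ/mol, distances in nm unless a function says otherwise
(the structure module works in Å, the native PDB unit).
"""

import numpy as np

#: Boltzmann constant, kJ mol^-1 K^-1.
K_B = 0.0083145

#: Simulation temperature, K.
DEFAULT_T = 298.0

#: Standard-state volume at 1 M, nm^3 per molecule.
V_STANDARD = 1.661

#: Harmonic umbrella force constant, kJ mol^-1 nm^-2.
DEFAULT_FORCE_CONSTANT = 500.0

#: Umbrella bias centers: 0.4 to 1.9 nm in 0.1 nm steps (16 windows).
DEFAULT_CENTERS = tuple(float(c) for c in np.round(np.arange(0.4, 1.95, 0.1), 10))

#: Histogram bin width, nm (>= 5 bins per bias sigma at k = 500, T = 298).
DEFAULT_BIN_WIDTH = 0.02

#: Interval over which the PMF is zeroed (large-separation plateau), nm.
DEFAULT_PLATEAU = (1.7, 1.9)

#: Split-half convergence threshold on |dG1 - dG2|, kJ/mol.
CONVERGENCE_THRESHOLD = 1.5

#: Replicate-SD reporting threshold, kJ/mol.
REPLICATE_SD_THRESHOLD = 0.58


def kt(temperature: float = DEFAULT_T) -> float:
    """Thermal energy k_B*T in kJ/mol (2.478 at 298 K)."""
    return K_B * temperature
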