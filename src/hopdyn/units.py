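"""Physical constants for the internal unit system.

Everything in the package is carried in a single consistent set of
"molecular" units: lengths in angstrom (A), times in femtoseconds (fs),
energies in electronvolt (eV), masses in atomic mass units (amu) and
temperatures in kelvin.  With these choices kinetic energy is

    E_kin [eV] = 0.5 * m [amu] * v^2 [A^2/fs^2] * EV_PER_AMU_ANG2_FS2

and the electronic time scale enters through hbar in eV*fs.
"""

# hbar in eV * fs (CODATA: 6.582119569e-16 eV*s)
HBAR_EV_FS = 0.6582119569

# Boltzmann constant in eV / K
KB_EV = 8.617333262e-5

# 1 amu * (A/fs)^2 expressed in eV:
# 1.66053906660e-27 kg * (1e-10 m / 1e-15 s)^2 / 1.602176634e-19 J/eV
EV_PER_AMU_ANG2_FS2 = 103.64269574711572


def kinetic_energy(masses, velocities) -> float:
    """Total classical kinetic energy in eV for per-DOF masses (amu) and velocities (A/fs)."""
    import numpy as np

    m = np.asarray(masses, dtype=float)
    v = np.asarray(velocities, dtype=float)
    return 0.5 * EV_PER_AMU_ANG2_FS2 * float(np.sum(m * v * v))
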