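"""Physical constants in the internal unit system.

The internal units are GROMACS-like: length nm, time ps, mass u (g/mol),
charge e, energy kJ/mol, temperature K.  Magnetic flux density is accepted in
tesla on every interface; the single conversion constant ``K_OMEGA`` maps
``q·B/m`` (e·T/u) to an angular frequency in rad/ps, so the Lorentz coupling
never has to be expressed in force units.

A convenient identity of this unit system: 1 u·nm²/ps² = 1 kJ/mol exactly,
so kinetic energies need no conversion factor.
"""

# Larmor-frequency conversion: Ω [rad/ps] = K_OMEGA * q[e] * B[T] / m[u].
# Equals (elementary charge / atomic mass constant) * 1e-12.
K_OMEGA = 9.6485332e-5

# Boltzmann constant, kJ mol^-1 K^-1.
KB = 0.00831446

# Coulomb prefactor 1/(4 pi eps0) in kJ mol^-1 nm e^-2.
F_ELEC = 138.935458

# 1 nm^2/ps = 1e-6 m^2/s (1e-18 m^2 / 1e-12 s); used for diffusion output.
NM2_PER_PS_TO_M2_PER_S = 1.0e-6
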