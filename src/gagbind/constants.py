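"""Physical constants and unit conventions.

Internal units throughout the package: length in Å, energy in kcal/mol,
charge in elementary charges (e), time in ps, temperature in K.
"""

import numpy as np

#: e^2 / (4 pi eps0) in kcal mol^-1 Å e^-2 (the Coulomb prefactor)
COULOMB_K = 332.063713

#: Boltzmann constant in kcal mol^-1 K^-1
KB = 1.987204259e-3

#: Avogadro's number
N_AVOGADRO = 6.02214076e23

#: conversion: ionic strength mol/L -> particles per Å^3
MOLAR_TO_PER_A3 = N_AVOGADRO / 1.0e27


def water_viscosity(temperature: float) -> float:
    """Dynamic viscosity of water in Pa s (Vogel-type empirical fit).

    Valid roughly 273-373 K; at 310.15 K gives ~6.9e-4 Pa s.
    """
    return 2.414e-5 * 10.0 ** (247.8 / (temperature - 140.0))


def bjerrum_length(dielectric: float, temperature: float) -> float:
    """Bjerrum length in Å: distance at which two unit charges interact at kT."""
    return COULOMB_K / (dielectric * KB * temperature)


def stokes_einstein_dt(radius: float, temperature: float,
                       viscosity: float) -> float:
    """Translational diffusion coefficient in Å^2/ps.

    ``radius`` in Å, ``viscosity`` in Pa s.  D = kT / (6 pi eta a).
    """
    kbt_j = 1.380649e-23 * temperature          # J
    a_m = radius * 1e-10                        # m
    d_m2_s = kbt_j / (6.0 * np.pi * viscosity * a_m)
    return d_m2_s * 1.0e8                       # m^2/s -> Å^2/ps


def stokes_einstein_dr(radius: float, temperature: float,
                       viscosity: float) -> float:
    """Rotational diffusion coefficient in rad^2/ps (Stokes-Einstein-Debye)."""
    kbt_j = 1.380649e-23 * temperature
    a_m = radius * 1e-10
    d_s = kbt_j / (8.0 * np.pi * viscosity * a_m ** 3)
    return d_s * 1.0e-12                        # 1/s -> 1/ps
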