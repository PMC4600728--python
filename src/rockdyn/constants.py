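"""Physical constants for NMR relaxation calculations.

Values are CODATA 2018. Gyromagnetic ratios in rad s^-1 T^-1; the 15N
ratio is negative (magnetic moment antiparallel to spin), but only its
magnitude enters the rate expressions used here.
"""

MU0 = 1.25663706212e-6  # vacuum permeability, N A^-2
HBAR = 1.054571817e-34  # reduced Planck constant, J s

GAMMA_H = 2.6752218744e8  # 1H gyromagnetic ratio, rad s^-1 T^-1
GAMMA_N = -2.7126e7  # 15N gyromagnetic ratio, rad s^-1 T^-1
GAMMA_C = 6.728284e7  # 13C gyromagnetic ratio, rad s^-1 T^-1

ANGSTROM = 1e-10  # m


def dipolar_coupling_constant(r_nh_angstrom: float,
                              gamma_i: float = GAMMA_H,
                              gamma_s: float = GAMMA_N) -> float:
    """Rigid-limit heteronuclear dipolar coupling d = (mu0/4pi) g_I g_S hbar / r^3.

    Returned in rad/s (magnitude). For an NH pair at 1.02 A this is about
    2*pi*11.5 kHz.
    """
    r = r_nh_angstrom * ANGSTROM
    return abs(MU0 / (4.0 * 3.141592653589793) * gamma_i * gamma_s * HBAR / r ** 3)
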