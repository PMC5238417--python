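"""Package-wide physical constants and default acquisition parameters.

Units used throughout the package: lengths in cm, times in ps, absorption
and reduced scattering coefficients in cm^-1, wavelengths in nm.
"""

# Speed of light in vacuum, cm/ps
C_VACUUM_CM_PS = 0.0299792458

#: Operating wavelengths of the optical mammograph (nm)
WAVELENGTHS_NM = (635, 685, 785, 905, 930, 975, 1060)

#: Tissue refractive index; the instrument geometry does not constrain it,
#: 1.4 is the standard soft-tissue value.
DEFAULT_REFRACTIVE_INDEX = 1.4

#: Mildly compressed breast thickness (cm); a configuration parameter.
DEFAULT_SLAB_THICKNESS_CM = 4.0

#: Scan pitch of the tandem source/detector stage (mm)
SCAN_PITCH_MM = 1.0

#: Number of equal-count time windows and the (1-based) analysis window,
#: which collects late, absorption-sensitive photons.
N_TIME_WINDOWS = 10
ANALYSIS_WINDOW = 8

#: Instrument response function FWHM range (ps), wavelength dependent.
IRF_FWHM_RANGE_PS = (460.0, 930.0)


def light_speed(refractive_index: float) -> float:
    """Phase velocity of light in the medium, cm/ps."""
    if refractive_index < 1:
        raise ValueError("refractive index must be >= 1")
    return C_VACUUM_CM_PS / refractive_index


def internal_reflection_coefficient(refractive_index: float) -> float:
    """Boundary mismatch factor A(n) for the extrapolated-boundary distance.

    Uses the Groenhuis polynomial fit of the internal diffuse reflectance
    r_d; A = (1 + r_d) / (1 - r_d).  A = 1 for matched boundaries.
    """
    n = refractive_index
    if n < 1:
        raise ValueError("refractive index must be >= 1")
    if n == 1.0:
        return 1.0
    r_d = -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
    return (1.0 + r_d) / (1.0 - r_d)
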