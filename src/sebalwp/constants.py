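"""Physical constants used across the energy-balance and reference-ET chain."""

STEFAN_BOLTZMANN = 5.67e-8  # W m-2 K-4
SOLAR_CONSTANT = 1367.0  # W m-2
SOLAR_CONSTANT_MJ_MIN = 0.0820  # MJ m-2 min-1 (FAO-56 daily radiation chain)
CP_AIR = 1004.0  # J kg-1 K-1, specific heat of air at constant pressure
VON_KARMAN = 0.41
GRAVITY = 9.81  # m s-2
R_DRY_AIR = 287.05  # J kg-1 K-1
MU_M2 = 666.667  # m2 per mu (1/15 hectare); yields are reported in kg/mu
SECONDS_PER_DAY = 86400.0
MJ_DAY_TO_W = 1e6 / SECONDS_PER_DAY  # MJ m-2 d-1 -> W m-2 (11.574)

# Single-channel brightness-temperature emissivity correction
LAMBDA_EFF_M = 10.9e-6  # effective thermal wavelength (m)
RHO_C_MK = 1.438e-2  # h*c/k (m K)

# Planck calibration defaults for a 10.6-11.2 um thermal band
K1_DEFAULT = 774.8853  # W m-2 sr-1 um-1
K2_DEFAULT = 1321.0789  # K
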