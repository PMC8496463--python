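"""Physical constants and fixed protocol settings shared across modules."""

# Avogadro constant, mol^-1 (2019 SI exact value).
AVOGADRO = 6.02214076e23

# Unit conversions.
UMOL_TO_MOL = 1e-6
M2_TO_NM2 = 1e18

# Measuring/actinic wavelengths of the multi-color PAM head (nm).
WAVELENGTHS = (440, 480, 540, 590, 625)

# Wavelength transposition origin for the mixed-model stage: 440 nm maps to 0.
WL_ORIGIN = 440

# Spectral bands (nm) used for light-quality ratios.  Blue and green
# deliberately overlap at 480-490 nm.
BAND_BLUE = (410.0, 490.0)
BAND_GREEN = (480.0, 580.0)
BAND_RED = (600.0, 700.0)

# Euphotic depth is where downwelling PAR falls to 1% of surface: ln(100).
EUPHOTIC_LN_FRACTION = 4.6

# Density difference (kg m^-3) between the 0-1.5 m surface layer and the
# bottom beyond which a water column is considered stratified.
STRATIFICATION_THRESHOLD = 0.086
SURFACE_BAND = (0.0, 1.5)

# PAR values (umol quanta m^-2 s^-1) at which fitted NPQ curves are evaluated.
NPQ_EVAL_LOW = 300.0
NPQ_EVAL_HIGH = 1200.0

# Plausibility window for the QA-reduction time constant tau (s).
TAU_MIN = 1e-5
TAU_MAX = 5e-3

# The eight parameters carried into the K-table (PTA/RDA) stage.
PTA_PARAMETERS = (
    "etrmax_ii",
    "ek",
    "alpha_ii",
    "eop_ii",
    "sigma_nm2",
    "fvfm",
    "npq300",
    "npq1200",
)
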