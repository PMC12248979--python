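"""Study design constants and published calibration values.

The experimental design: a central disk and a surrounding periphery separated
by an isoluminant circular colour boundary.  Colour contrast is the DKL
azimuth difference between centre and periphery (10/20/30 deg azimuth);
boundary eccentricity is the disk radius (2/4/6 deg visual angle).  The RGB
anchors below are fixtures describing the stimuli on the calibrated display;
no colour conversion is performed in this package.

The ``*_COEFS`` dictionaries are published fixed-effect estimates from linear
mixed models of the task outcomes, on the standardized log-outcome scale.
They serve as the default ground-truth coefficients of the synthetic-data
generator, so parameter-recovery studies simulate from — and re-fit against —
the reported effect structure.
"""

from __future__ import annotations

# --- stimulus design ---------------------------------------------------------

CONTRAST_LEVELS = (10, 20, 30)  # DKL azimuth difference centre vs periphery, deg
ECCENTRICITY_LEVELS_DEG = (2.0, 4.0, 6.0)  # disk radius, deg visual angle

CENTER_DKL_AZIMUTH = 270
PERIPHERY_DKL_AZIMUTH = {10: 280, 20: 290, 30: 300}

# RGB fixtures (8-bit) for the calibrated display; kept for reference only.
RGB_BACKGROUND = (77, 77, 77)
RGB_CENTER = (77, 75, 83)
RGB_PERIPHERY = {10: (83, 73, 82), 20: (88, 71, 82), 30: (92, 69, 82)}

DEFAULT_BLOCKS = tuple((c, e) for c in CONTRAST_LEVELS for e in ECCENTRICITY_LEVELS_DEG)

# --- reported task-level summaries used as generator calibration -------------

MEAN_FT_S = 7.51              # mean filling-in time across participants, s
MEAN_MS_RATE_HZ = 0.89        # mean microsaccade rate across the task, Hz
ZERO_EVENT_TRIAL_FRAC = 0.102  # fraction of trials with no microsaccades/blinks

# --- published fixed-effect estimates (standardized log-outcome scale) -------

# Primary filling-in-time model: log FT ~ stimulus + oculomotor covariates
# with per-participant random intercept and slopes.
FT_PRIMARY_COEFS = {
    "intercept": 0.310,
    "contrast": 0.115,
    "eccentricity": -0.00939,
    "ms_presence": 0.302,
    "num_blinks": 0.265,
    "trial_num": -0.101,
    "contrast:trial_num": -0.0152,
    "ms_presence:contrast": -0.00757,
    "ms_presence:eccentricity": -0.0715,
    "num_blinks:contrast": -0.0160,
    "num_blinks:eccentricity": 0.0126,
}

# Balanced-subset models: trials with at least one microsaccade and no blinks
# vs. trials with neither; random intercept only.
FT_SUBSET_MS_COEFS = {
    "intercept": 0.498,
    "contrast": 0.156,
    "eccentricity": -0.0876,
    "trial_num": -0.101,
    "ocular_drift": 0.104,
}
FT_SUBSET_NO_MS_COEFS = {
    "intercept": 0.176,
    "contrast": 0.166,
    "eccentricity": -0.00389,
    "trial_num": -0.0762,
    "ocular_drift": 0.0453,
}

# Trial-wise log microsaccade-rate model.
MS_RATE_COEFS = {
    "intercept": -0.0845,
    "contrast": -0.000870,
    "eccentricity": 0.0350,
    "trial_num": 0.134,
}

# Log immobilization-time model (last microsaccade to report).
IMMOBILIZATION_COEFS = {
    "intercept": -0.165,
    "contrast": 0.0283,
    "eccentricity": -0.0587,
    "trial_num": -0.105,
    "ms_amplitude": 0.0110,
}
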