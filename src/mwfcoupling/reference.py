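"""Published left-hemisphere reference values for the 33 Desikan-Killiany
cortical regions of the 1-6 year developmental cohort.

Two constant tables drive the synthetic-data generators and the worked
examples:

``TRAJECTORY_COEFFICIENTS``
    Logarithmic growth-curve coefficients ``(a, b)`` per region and measure,
    where the fitted model is ``value = a * ln(age_days) + b``.  Measures are
    cortical thickness (mm), adjacent white-matter MWF (fraction), and
    cortical MWF (fraction).

``RESIDUAL_COUPLING``
    Age-residualized Pearson correlations between the three measures per
    region, for the pairs (thickness, adjacent MWF), (thickness, cortical
    MWF) and (cortical MWF, adjacent MWF), with the reported two-sided
    p-values at n = 177 pooled scans.

Region names are the lower-case Desikan-Killiany labels.  Both tables cover
the left hemisphere; the generators reuse them for the right hemisphere by
default since no separate right-hemisphere coefficients were reported.
"""

from __future__ import annotations

import numpy as np

MEASURES = ("thickness_mm", "adjacent_mwf", "cortical_mwf")

#: pairs of measures compared region-wise, in canonical order
COUPLING_PAIRS = (
    ("thickness_mm", "adjacent_mwf"),
    ("thickness_mm", "cortical_mwf"),
    ("cortical_mwf", "adjacent_mwf"),
)

#: number of pooled scans behind the reference correlations
REFERENCE_N_SCANS = 177

# region -> (thickness a, thickness b, adjacent a, adjacent b, cortical a, cortical b)
_COEF = {
    "caudal anterior cingulate": (-0.179, 4.566, 0.029, -0.07, 0.016, -0.058),
    "caudal middle frontal": (-0.23, 4.452, 0.022, -0.035, 0.017, -0.056),
    "cuneus": (-0.267, 4.096, 0.014, 0.005, 0.013, -0.031),
    "entorhinal": (0.0, 2.86, 0.01, 0.025, 0.015, -0.057),
    "frontal pole": (-0.09, 3.963, 0.019, -0.051, 0.016, -0.057),
    "fusiform": (-0.22, 4.399, 0.014, 0.011, 0.012, -0.024),
    "inferior parietal": (-0.142, 3.609, 0.011, 0.029, 0.012, -0.021),
    "inferior temporal": (-0.303, 4.902, 0.014, 0.02, 0.019, -0.063),
    "insula": (-0.145, 4.5, 0.011, 0.031, 0.014, -0.051),
    "isthmus cingulate": (-0.297, 5.172, 0.016, 0.019, 0.009, -0.011),
    "lateral occipital": (-0.196, 3.687, 0.01, 0.034, 0.012, -0.008),
    "lateral orbitofrontal": (-0.092, 3.908, 0.029, -0.087, 0.02, -0.086),
    "lingual": (-0.275, 4.286, 0.014, 0.01, 0.008, 0.003),
    "medial orbitofrontal": (-0.331, 5.443, 0.024, -0.064, 0.02, -0.091),
    "middle temporal": (-0.264, 4.514, 0.015, 0.016, 0.014, -0.036),
    "paracentral": (-0.141, 3.605, 0.017, -0.001, 0.01, -0.019),
    "parahippocampal": (-0.061, 3.09, 0.016, -0.025, 0.01, -0.022),
    "pars opercularis": (-0.23, 4.488, 0.024, -0.037, 0.015, -0.049),
    "pars orbitalis": (-0.38, 5.952, 0.015, -0.001, 0.016, -0.06),
    "pars triangularis": (-0.276, 4.662, 0.026, -0.06, 0.016, -0.053),
    "pericalcarine": (-0.199, 3.303, 0.016, -0.001, 0.01, 0.001),
    "postcentral": (-0.145, 3.26, 0.013, 0.023, 0.011, -0.011),
    "posterior cingulate": (-0.098, 3.807, 0.023, -0.035, 0.013, -0.036),
    "precentral": (-0.099, 3.188, 0.018, -0.004, 0.013, -0.027),
    "precuneus": (-0.137, 3.748, 0.021, -0.027, 0.012, -0.034),
    "rostral anterior cingulate": (-0.494, 7.172, 0.023, -0.029, 0.015, -0.055),
    "rostral middle frontal": (-0.368, 5.527, 0.03, -0.098, 0.019, -0.07),
    "superior frontal": (-0.259, 5.21, 0.028, -0.083, 0.015, -0.056),
    "superior parietal": (-0.071, 2.921, 0.016, -0.009, 0.013, -0.032),
    "superior temporal": (-0.035, 2.961, 0.017, -0.002, 0.012, -0.029),
    "supramarginal": (-0.19, 4.026, 0.015, 0.014, 0.011, -0.017),
    "temporal pole": (0.059, 2.846, 0.004, 0.065, 0.014, -0.055),
    "transverse temporal": (-0.108, 3.326, 0.018, -0.011, 0.011, -0.011),
}

#: region -> {measure: (log_slope a, intercept b)}
TRAJECTORY_COEFFICIENTS = {
    region: {
        "thickness_mm": (c[0], c[1]),
        "adjacent_mwf": (c[2], c[3]),
        "cortical_mwf": (c[4], c[5]),
    }
    for region, c in _COEF.items()
}

# region -> (r thickness/adjacent, p, r thickness/cortical, p, r cortical/adjacent, p)
_COUPLING = {
    "caudal anterior cingulate": (-0.184, 0.0144, -0.106, 0.162, 0.282, 0.000139),
    "caudal middle frontal": (-0.274, 0.00023, -0.27, 0.000274, 0.556, 8.88e-16),
    "cuneus": (0.159, 0.0347, 0.102, 0.177, 0.495, 2.41e-12),
    "entorhinal": (-0.024, 0.747, 0.007, 0.926, 0.16, 0.0335),
    "frontal pole": (0.202, 0.00692, -0.055, 0.469, 0.51, 4.13e-13),
    "fusiform": (-0.19, 0.0113, -0.146, 0.0527, 0.44, 8.67e-10),
    "inferior parietal": (-0.333, 6.11e-06, -0.32, 1.40e-05, 0.547, 3.33e-15),
    "inferior temporal": (-0.184, 0.0141, -0.416, 8.41e-09, 0.369, 4.24e-07),
    "insula": (0.05, 0.512, -0.063, 0.402, 0.61, 0.0),
    "isthmus cingulate": (0.0, 0.998, -0.007, 0.924, 0.313, 2.22e-05),
    "lateral occipital": (-0.139, 0.0645, -0.208, 0.00552, 0.414, 1.02e-08),
    "lateral orbitofrontal": (0.028, 0.709, -0.049, 0.515, 0.419, 6.19e-09),
    "lingual": (0.061, 0.419, 0.131, 0.081, 0.245, 0.00103),
    "medial orbitofrontal": (0.172, 0.022, 0.136, 0.0721, 0.465, 7.33e-11),
    "middle temporal": (-0.239, 0.00133, -0.474, 2.70e-11, 0.489, 5.14e-12),
    "paracentral": (0.097, 0.199, -0.038, 0.615, 0.458, 1.44e-10),
    "parahippocampal": (0.154, 0.0405, 0.049, 0.52, 0.439, 1.01e-09),
    "pars opercularis": (-0.252, 0.000717, -0.316, 1.81e-05, 0.518, 1.50e-13),
    "pars orbitalis": (-0.21, 0.00496, -0.237, 0.00151, 0.382, 1.49e-07),
    "pars triangularis": (-0.237, 0.0015, -0.264, 0.000385, 0.572, 0.0),
    "pericalcarine": (0.154, 0.0402, 0.142, 0.0601, 0.74, 0.0),
    "postcentral": (0.068, 0.372, -0.194, 0.0098, 0.545, 4.00e-15),
    "posterior cingulate": (-0.076, 0.312, -0.125, 0.0983, 0.312, 2.42e-05),
    "precentral": (-0.024, 0.748, -0.13, 0.0843, 0.53, 3.20e-14),
    "precuneus": (0.217, 0.00371, 0.005, 0.943, 0.297, 6.11e-05),
    "rostral anterior cingulate": (-0.209, 0.00528, -0.195, 0.00912, 0.317, 1.73e-05),
    "rostral middle frontal": (-0.318, 1.66e-05, -0.257, 0.000562, 0.592, 0.0),
    "superior frontal": (-0.28, 0.000164, -0.144, 0.0566, 0.553, 1.33e-15),
    "superior parietal": (0.123, 0.102, 0.058, 0.439, 0.566, 2.22e-16),
    "superior temporal": (-0.239, 0.00138, -0.316, 1.83e-05, 0.549, 2.44e-15),
    "supramarginal": (-0.374, 3.02e-07, -0.387, 1.01e-07, 0.607, 0.0),
    "temporal pole": (0.102, 0.178, 0.094, 0.214, 0.177, 0.0185),
    "transverse temporal": (0.249, 0.000851, -0.08, 0.287, 0.603, 0.0),
}

#: region -> {(measure_a, measure_b): (r, reported two-sided p at n=177)}
RESIDUAL_COUPLING = {
    region: {
        ("thickness_mm", "adjacent_mwf"): (v[0], v[1]),
        ("thickness_mm", "cortical_mwf"): (v[2], v[3]),
        ("cortical_mwf", "adjacent_mwf"): (v[4], v[5]),
    }
    for region, v in _COUPLING.items()
}

REGIONS = tuple(_COEF)


def coupling_correlation_matrix(region: str) -> np.ndarray:
    """3x3 residual correlation matrix over ``MEASURES`` for one region.

    Ordered (thickness, adjacent MWF, cortical MWF) to match ``MEASURES``.
    """
    c = RESIDUAL_COUPLING[region]
    r_ta = c[("thickness_mm", "adjacent_mwf")][0]
    r_tc = c[("thickness_mm", "cortical_mwf")][0]
    r_ca = c[("cortical_mwf", "adjacent_mwf")][0]
    return np.array(
        [
            [1.0, r_ta, r_tc],
            [r_ta, 1.0, r_ca],
            [r_tc, r_ca, 1.0],
        ]
    )
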