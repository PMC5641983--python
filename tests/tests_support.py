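"""Shared helpers for the test suite."""

import numpy as np


def g_generating_theta(gspec):
    """Plausible generating values for the common-factor structure, keyed by
    the builder's free labels (works for any invariance level)."""
    values = {
        "lambda_mat": 0.35, "lambda_mat_t1": 0.35, "lambda_mat_t2": 0.35,
        "g1_on_age": 0.8, "beta_g": -0.3, "age_var": 9.9, "g1_var": 30.0,
        "dg_var": 6.0, "voc1_resid_var": 25.0, "mat1_resid_var": 6.0,
        "voc2_resid_var": 25.0, "mat2_resid_var": 6.0,
        "voc_resid_cov": 10.0, "mat_resid_cov": 2.5,
        "age_mean": 0.0, "voc1_int": 58.6, "voc2_int": 59.0,
        "mat1_int": 29.0, "mat2_int": 29.6,
        "voc_int": 58.8, "mat_int": 29.3, "alpha_g": 0.3,
    }
    return np.array([values[l] for l in gspec.free_labels])
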