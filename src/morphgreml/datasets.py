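"""Bundled reference data for worked examples.

``cohort_model_comparison()`` returns the published restricted
log-likelihoods of the no-covariance and covariance (CORE) mixed models,
and the effect-correlation estimates, for 19 childhood traits from a large
population-based developmental cohort analysis of genomic and
cortical-thickness similarity.  The log-likelihood columns (printed to 0.1)
are the inputs of the model-comparison workflow
(:func:`morphgreml.greml.compare_models`); the correlation columns
illustrate report rendering.  The sleep-disturbance correlation is missing
because that covariance model did not converge in the source analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_ROWS = [
    # trait, loglik model 1, loglik model 2, r_bg, SE(r_bg)
    ("Height", -2718.9, -2718.9, 0.012, 0.131),
    ("Weight", -3064.4, -3063.8, 0.171, 0.157),
    ("Birth weight", -3010.4, -3009.6, 0.245, 0.215),
    ("Age at pregnancy", -3311.9, -3308.9, 0.693, 0.356),
    ("Parent education", -2352.1, -2351.0, 0.372, 0.268),
    ("Area deprivation", -2760.2, -2759.6, 0.202, 0.190),
    ("Child opportunity index", -2164.0, -2163.8, 0.169, 0.264),
    ("Picture vocabulary", -2763.6, -2763.3, -0.205, 0.248),
    ("Flanker task", -3554.5, -3554.5, 0.215, 0.651),
    ("Working memory", -3300.6, -3300.6, -0.048, 0.274),
    ("Card sorting", -3442.7, -3441.8, 0.567, 0.478),
    ("Pattern recognition", -3536.9, -3536.9, -0.127, 0.333),
    ("Reading", -3215.4, -3215.3, -0.107, 0.248),
    ("Fluid intelligence", -3102.2, -3102.2, 0.030, 0.207),
    ("Crystallized intelligence", -2755.8, -2755.6, -0.135, 0.203),
    ("CBCL Internalizing", -3617.5, -3617.5, -0.272, 0.917),
    ("CBCL Externalizing", -3564.6, -3564.4, -0.549, 1.019),
    ("Pre-psychosis", -2231.5, -2231.5, -0.060, 0.810),
    ("Sleep disturbance", -3804.5, -3804.4, np.nan, np.nan),
]


def cohort_model_comparison() -> pd.DataFrame:
    """Reference log-likelihood pairs and effect correlations for 19 traits."""
    return pd.DataFrame(_ROWS, columns=[
        "trait", "loglik_model1", "loglik_model2", "r_bg", "r_bg_se"])
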