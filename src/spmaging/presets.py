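"""Reference study conditions for simulation experiments.

One scalar physiological biomarker followed from age 40: the allostatic
trajectory rises slowly with age (f1(t) = 80 + 0.3 t, i.e. ~92 at entry),
the physiological norm rises more slowly (f0(t) = 80 + 0.2 t), so the
norm-to-allostatic gap (allostatic load) widens with age.  Adaptive
capacity a = -0.3/year gives a homeostatic relaxation time of ~3 years and
a stationary spread of sqrt(b^2 / 2|a|) ~ 3.9 around f1.  The baseline
hazard is Gompertz with a mortality-rate doubling time of ~8 years
(theta = 0.085) and level ~1e-3/year at age 40; the hazard curvature
Q(t) = Q0 (1 + 0.01 t) adds ~2e-3/year for a 10-unit deviation from the
norm at entry and grows with age (declining stress resistance).
Examinations run every 2 years for 30 years with administrative censoring
at age 100; biomarkers are recorded without measurement error, as in the
exact-observation model.
"""

from __future__ import annotations

import numpy as np

from .data import ObservationScheme
from .params import SPMParameters

__all__ = ["study_params", "study_scheme"]


def study_params(**overrides) -> SPMParameters:
    """The reference scalar-model parameter set (see module docstring)."""
    base = dict(
        dim=1,
        a0=-0.3, a1=0.0,
        f1_0=80.0, f1_1=0.3,
        f0_0=80.0, f0_1=0.2,
        b=3.0,
        Q0=2e-5, q1=0.01,
        mu0_c0=np.log(1e-3) - 0.085 * 40.0, mu0_theta=0.085,
        m0=88.0, gamma0=9.0,
        age_range=(0.0, 120.0),
    )
    base.update(overrides)
    return SPMParameters(**base)


def study_scheme(entry_age: float = 40.0, spacing: float = 2.0,
                 n_exams: int = 16, censor_age: float = 100.0,
                 **kw) -> ObservationScheme:
    """Examination schedule of the reference design (biennial exams over
    30 years, censoring at 100)."""
    return ObservationScheme(
        exam_ages=entry_age + spacing * np.arange(n_exams),
        censor_age=censor_age, **kw)
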