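"""YAML configuration: model templates, free/fixed flags, simulation schemes.

Schema (all sections optional except ``model``)::

    model:
      dim: 1
      age_range: [30, 110]
      covariates: []          # baseline covariate names
      parameters:             # field: {value: ..., free: true|false}
        a0:      {value: -0.3, free: true}
        f1_0:    {value: 90.0, free: true}
        f1_1:    {value: 0.3,  free: true}
        b:       {value: 3.0,  free: true}
        Q0:      {value: 2.0e-5, free: true}
        mu0_c0:  {value: -9.2, free: true}
        mu0_theta: {value: 0.08, free: true}
    simulate:
      n: 500
      entry_age: 40.0
      exam_spacing: 2.0       # years between examinations
      n_exams: 16
      censor_age: 100.0
      dt: 0.05
      genotyped_fraction: 1.0
      measurement_sd: 0.0
    mixture:                  # latent-class or genetic extension
      K: 2
      kind: latent            # or genetic
      beta0: [0.0]
      classes:                # per-regime overrides of model parameters
        - {f1_0: 85.0}
        - {f1_0: 95.0}
      free: [f1_0, Q0]
      shared: []              # genetic only
      action: [Q0, additive]  # genetic only
    fit:
      starts: 5
      seed: 1
      optimizer: BFGS

Matrix-valued fields accept scalars (broadcast to diagonal) exactly as the
:class:`~spmaging.params.SPMParameters` constructor does.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .data import ObservationScheme
from .estimation import FitOptions
from .mixture import GeneticModel, LatentClassModel
from .params import ConfigurationError, SPMParameters

__all__ = ["load_config", "model_from_config", "scheme_from_config",
           "mixture_from_config", "fit_options_from_config"]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "model" not in cfg:
        raise ConfigurationError(f"config {path} must contain a 'model' section")
    return cfg


def model_from_config(cfg: dict):
    """Build ``(template, free_fields)`` from the ``model`` section."""
    m = cfg["model"]
    kwargs = {"dim": int(m.get("dim", 1))}
    if "age_range" in m:
        kwargs["age_range"] = tuple(m["age_range"])
    if "covariates" in m:
        kwargs["covariates"] = tuple(m["covariates"])
    free = []
    for name, spec in (m.get("parameters") or {}).items():
        if isinstance(spec, dict):
            kwargs[name] = spec.get("value", 0.0)
            if spec.get("free", False):
                free.append(name)
        else:
            kwargs[name] = spec
    try:
        template = SPMParameters(**kwargs)
    except TypeError as e:
        raise ConfigurationError(f"bad model section: {e}")
    return template, tuple(free)


def scheme_from_config(cfg: dict) -> ObservationScheme:
    s = cfg.get("simulate") or {}
    entry = float(s.get("entry_age", 40.0))
    spacing = float(s.get("exam_spacing", 2.0))
    n_exams = int(s.get("n_exams", 16))
    return ObservationScheme(
        exam_ages=entry + spacing * np.arange(n_exams),
        censor_age=float(s.get("censor_age", entry + spacing * n_exams + 10)),
        jitter_sd=float(s.get("jitter_sd", 0.0)),
        miss_prob=float(s.get("miss_prob", 0.0)),
        measurement_sd=float(s.get("measurement_sd", 0.0)))


def mixture_from_config(cfg: dict, template: SPMParameters):
    """Build a LatentClassModel / GeneticModel from the ``mixture`` section."""
    mx = cfg.get("mixture")
    if not mx:
        return None
    K = int(mx.get("K", len(mx.get("classes", [])) or 1))
    overrides = mx.get("classes") or [{}] * K
    if len(overrides) != K:
        raise ConfigurationError("mixture.classes length must equal K")
    comps = []
    for ov in overrides:
        c = template.copy()
        for name, val in (ov or {}).items():
            if not hasattr(c, name):
                raise ConfigurationError(f"unknown parameter {name!r} in class override")
            setattr(c, name, val)
        comps.append(SPMParameters(**{f: getattr(c, f) for f in (
            "dim", "a0", "a1", "f1_0", "f1_1", "f0_0", "f0_1", "b", "Q0",
            "q1", "mu0_c0", "mu0_theta", "m0", "gamma0", "covariates",
            "f1_x", "f0_x", "mu0_x", "age_range")}))
    beta0 = np.asarray(mx.get("beta0", np.zeros(K - 1)), dtype=float)
    kind = mx.get("kind", "latent")
    if kind == "genetic":
        action = mx.get("action")
        return GeneticModel(comps, beta0, shared=tuple(mx.get("shared", ())),
                            action=tuple(action) if action else None)
    return LatentClassModel(comps, beta0)


def fit_options_from_config(cfg: dict, seed=None) -> FitOptions:
    f = dict(cfg.get("fit") or {})
    if seed is not None:
        f["seed"] = seed
    allowed = {k: v for k, v in f.items()
               if k in FitOptions.__dataclass_fields__}
    return FitOptions(**allowed)
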