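"""Cohort containers and delimited-text input/output.

A cohort is stored in two tables:

* a long-format longitudinal table, one row per individual per examination
  (``id, age, y1..yJ``), and
* a one-row-per-individual survival table
  (``id, t0, tau, delta, <covariates...>, genotype``),

with genotype blank for non-genotyped individuals.  Both are plain delimited
text; round trips are lossless at full float precision (``repr`` formatting).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ObservationScheme", "Individual", "Cohort",
           "read_cohort", "write_cohort", "cohort_from_frames"]


class DataError(ValueError):
    """Cohort data violating the documented schema."""


@dataclass
class ObservationScheme:
    """Examination schedule for simulated cohorts.

    ``exam_ages`` is the planned examination grid (ages, strictly
    increasing); visits after the event/censoring age are dropped.
    ``jitter_sd`` adds independent Gaussian jitter to each planned visit,
    ``miss_prob`` drops visits at random, ``measurement_sd`` adds i.i.d.
    Gaussian measurement noise to each recorded biomarker (0 = biomarkers
    observed exactly, the default in this model lineage).
    """

    exam_ages: np.ndarray
    censor_age: float
    jitter_sd: float = 0.0
    miss_prob: float = 0.0
    measurement_sd: float = 0.0

    def __post_init__(self) -> None:
        self.exam_ages = np.asarray(self.exam_ages, dtype=float)
        if self.exam_ages.ndim != 1 or self.exam_ages.size == 0:
            raise DataError("exam_ages must be a non-empty 1-d array")
        if np.any(np.diff(self.exam_ages) <= 0):
            raise DataError("exam_ages must be strictly increasing")
        if not self.censor_age > self.exam_ages[0]:
            raise DataError("censor_age must exceed the first examination age")
        for name in ("jitter_sd", "miss_prob", "measurement_sd"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be >= 0")
        if self.miss_prob > 1:
            raise DataError("miss_prob must lie in [0, 1]")


@dataclass
class Individual:
    """One study participant: entry age, examinations, terminal follow-up."""

    id: int | str
    t0: float
    tau: float
    delta: int
    obs_ages: np.ndarray
    obs_values: np.ndarray          # (n_obs, J)
    x: np.ndarray = field(default_factory=lambda: np.empty(0))
    genotype: int | None = None     # 1..K, None = not genotyped / latent

    def __post_init__(self) -> None:
        self.obs_ages = np.asarray(self.obs_ages, dtype=float)
        self.obs_values = np.asarray(self.obs_values, dtype=float)
        if self.obs_values.ndim == 1:
            self.obs_values = self.obs_values[:, None]
        self.x = np.asarray(self.x, dtype=float).ravel()
        if self.delta not in (0, 1):
            raise DataError(f"individual {self.id}: delta must be 0 or 1")
        if self.obs_ages.size:
            if np.any(np.diff(self.obs_ages) <= 0):
                raise DataError(
                    f"individual {self.id}: observation ages not strictly increasing")
            if self.obs_ages[-1] > self.tau + 1e-9:
                raise DataError(
                    f"individual {self.id}: observation after terminal age tau")
            if self.obs_values.shape[0] != self.obs_ages.size:
                raise DataError(f"individual {self.id}: ages/values length mismatch")
        if self.tau < self.t0:
            raise DataError(f"individual {self.id}: tau < entry age t0")

    @property
    def dim(self) -> int:
        return self.obs_values.shape[1] if self.obs_values.size else 1

    def history_up_to(self, s: float) -> "Individual":
        """Copy containing only observations at ages <= s (for dynamic
        prediction conditioning)."""
        keep = self.obs_ages <= s + 1e-12
        if not keep.any():
            raise DataError(f"individual {self.id}: no observation at or before {s}")
        return Individual(self.id, self.t0, max(s, self.obs_ages[keep][-1]), 0,
                          self.obs_ages[keep], self.obs_values[keep],
                          self.x, self.genotype)


@dataclass
class Cohort:
    individuals: list[Individual]
    covariate_names: tuple[str, ...] = ()
    truth: object = None            # generating model, when simulated
    seed: int | None = None
    true_classes: np.ndarray | None = None  # generating class/genotype labels

    def __post_init__(self) -> None:
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate individual ids in cohort")
        dims = {ind.dim for ind in self.individuals if ind.obs_ages.size}
        if len(dims) > 1:
            raise DataError(f"inconsistent biomarker dimension across cohort: {dims}")

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    @property
    def dim(self) -> int:
        for ind in self.individuals:
            if ind.obs_ages.size:
                return ind.dim
        return 1

    def subset(self, mask) -> "Cohort":
        mask = np.asarray(mask, dtype=bool)
        inds = [ind for ind, keep in zip(self.individuals, mask) if keep]
        tc = self.true_classes[mask] if self.true_classes is not None else None
        return Cohort(inds, self.covariate_names, self.truth, self.seed, tc)


# ----------------------------------------------------------------------
# readers / writers
# ----------------------------------------------------------------------

def write_cohort(cohort: Cohort, long_path, ind_path, sep: str = ",") -> None:
    """Write the two-table delimited-text representation of a cohort."""
    J = cohort.dim
    long_rows, ind_rows = [], []
    for ind in cohort:
        for age, y in zip(ind.obs_ages, ind.obs_values):
            long_rows.append([ind.id, repr(float(age))] +
                             [repr(float(v)) for v in y])
        row = [ind.id, repr(float(ind.t0)), repr(float(ind.tau)), ind.delta]
        row += [repr(float(v)) for v in ind.x]
        row += ["" if ind.genotype is None else int(ind.genotype)]
        ind_rows.append(row)
    long_cols = ["id", "age"] + [f"y{j + 1}" for j in range(J)]
    ind_cols = ["id", "t0", "tau", "delta"] + list(cohort.covariate_names) + ["genotype"]
    pd.DataFrame(long_rows, columns=long_cols).to_csv(long_path, sep=sep, index=False)
    pd.DataFrame(ind_rows, columns=ind_cols).to_csv(ind_path, sep=sep, index=False)


def read_cohort(long_path, ind_path, sep: str = ",") -> Cohort:
    """Read a cohort from the two-table layout, validating the schema.

    Observations are sorted by age per individual; blank genotype fields are
    read as missing (not category 0); an observation after an individual's
    terminal age raises a :class:`DataError` naming the id.
    """
    # float_precision="round_trip": pandas' fast parser is not 1-ulp exact
    return cohort_from_frames(
        pd.read_csv(long_path, sep=sep, float_precision="round_trip"),
        pd.read_csv(ind_path, sep=sep, float_precision="round_trip"))


def cohort_from_frames(long_df: pd.DataFrame, ind_df: pd.DataFrame) -> Cohort:
    """Build a :class:`Cohort` from in-memory long-format and survival tables
    (same schema as :func:`read_cohort`)."""
    for col in ("id", "age"):
        if col not in long_df.columns:
            raise DataError(f"longitudinal table missing column {col!r}")
    for col in ("id", "t0", "tau", "delta"):
        if col not in ind_df.columns:
            raise DataError(f"individual table missing column {col!r}")
    ycols = [c for c in long_df.columns if c.startswith("y")]
    if not ycols:
        raise DataError("longitudinal table has no biomarker columns y1..yJ")
    cov_names = tuple(c for c in ind_df.columns
                      if c not in ("id", "t0", "tau", "delta", "genotype"))
    grouped = {k: g.sort_values("age") for k, g in long_df.groupby("id")}
    individuals = []
    # dict records keep per-column dtypes (iterrows would upcast ids to float)
    for row in ind_df.to_dict("records"):
        iid = row["id"]
        g = grouped.get(iid)
        ages = g["age"].to_numpy(float) if g is not None else np.empty(0)
        vals = g[ycols].to_numpy(float) if g is not None else np.empty((0, len(ycols)))
        geno = row.get("genotype")
        geno = None if (geno is None or (isinstance(geno, float) and np.isnan(geno))
                        or geno == "") else int(geno)
        individuals.append(Individual(
            iid, float(row["t0"]), float(row["tau"]), int(row["delta"]),
            ages, vals, np.array([float(row[c]) for c in cov_names]), geno))
    return Cohort(individuals, cov_names)
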