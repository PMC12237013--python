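"""Synthetic complete-blood-count (CBC) cohorts for sepsis classification.

A cohort is a table of CBC measurements: one row per blood draw, grouped by
patient, ordered by a 1-based ``position`` within each patient's sequence.
Each row carries age, biological sex, the five CBC parameters (hemoglobin,
red blood cells, white blood cells, mean corpuscular volume, platelets), a
binary sepsis label, and a split tag.

The generator emulates the structural biases of routine hospital laboratory
data without using any real patient records:

* variable-length measurement sequences per patient (many singletons),
* strong class imbalance (sepsis is rare at the measurement level),
* roughly two thirds of sepsis measurements belonging to patients with a
  single measurement, and in-sequence sepsis concentrated at the final
  position of the patient's sequence,
* class-conditional feature shifts (elevated white blood cells, reduced
  platelets, reduced hemoglobin, elevated mean corpuscular volume, older
  age in the sepsis class),
* an "external" test split with a mild additive site shift and slightly
  different prevalence.

Cohorts are plain :class:`pandas.DataFrame` objects with the canonical
column set in :data:`COHORT_COLUMNS`, so they round-trip through CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FEATURES",
    "BLOOD_PARAMETERS",
    "COHORT_COLUMNS",
    "SPLITS",
    "ClassConditional",
    "GeneratorConfig",
    "CohortGenerator",
    "generate_cohort",
    "cohort_stats",
    "CohortStats",
    "write_cohort",
    "read_cohort",
]

#: The seven input features, in canonical column order.
FEATURES = ["age", "sex", "hemoglobin", "rbc", "wbc", "mcv", "platelets"]

#: The five blood parameters of a complete blood count.
BLOOD_PARAMETERS = ["hemoglobin", "rbc", "wbc", "mcv", "platelets"]

COHORT_COLUMNS = [
    "patient_id", "position", "age", "sex",
    "hemoglobin", "rbc", "wbc", "mcv", "platelets", "label", "split",
]

SPLITS = ("train", "validation", "internal_test", "external_test")


@dataclass(frozen=True)
class ClassConditional:
    """Truncated-normal parameters of one feature, per class.

    ``mean``/``sd`` describe the control class, ``sepsis_mean``/``sepsis_sd``
    the sepsis class; ``lower``/``upper`` truncate both.
    """

    mean: float
    sd: float
    sepsis_mean: float
    sepsis_sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.sd <= 0 or self.sepsis_sd <= 0:
            raise ValueError("standard deviations must be strictly positive")
        if self.lower >= self.upper:
            raise ValueError("lower truncation bound must be below upper")


def _default_feature_params() -> dict[str, ClassConditional]:
    # Clinically plausible ranges for adults hospitalised on normal wards.
    # Units: age years, hemoglobin mmol/L, rbc Tpt/L, wbc Gpt/L, mcv fL,
    # platelets Gpt/L. The white-blood-cell shift is the dominant effect
    # (leukocytosis), with thrombocytopenia, mild anemia, elevated MCV and
    # older age as secondary shifts.
    return {
        "age": ClassConditional(58.0, 18.0, 66.0, 16.0, 18.0, 100.0),
        "hemoglobin": ClassConditional(8.6, 1.0, 7.9, 1.1, 3.0, 12.5),
        "rbc": ClassConditional(4.6, 0.60, 4.25, 0.65, 1.5, 7.5),
        "wbc": ClassConditional(6.8, 1.9, 12.5, 4.5, 0.5, 60.0),
        "mcv": ClassConditional(89.0, 5.5, 92.5, 6.0, 60.0, 125.0),
        "platelets": ClassConditional(250.0, 70.0, 190.0, 80.0, 10.0, 1000.0),
    }


def _default_external_shift() -> dict[str, float]:
    # Mild additive site effect applied to every external-split measurement.
    return {
        "age": 2.0, "hemoglobin": 0.15, "rbc": 0.05,
        "wbc": 0.4, "mcv": 0.8, "platelets": -10.0,
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic cohort generator.

    Parameters
    ----------
    n_patients:
        Number of patients to simulate.
    seed:
        Seed of the generator; cohorts are pure functions of the config.
    sepsis_measurement_prevalence:
        Fraction of measurements labelled sepsis (before the external
        multiplier).
    singleton_sepsis_fraction:
        Target fraction of sepsis measurements that are a patient's only
        measurement.
    last_position_sepsis_fraction:
        Among sepsis measurements inside multi-measurement sequences, the
        target fraction placed at the final position.
    mean_sequence_length:
        Mean of the geometric sequence-length distribution (support >= 1).
    patient_effect_scale:
        Per-patient random intercept for each continuous feature, expressed
        as a multiple of the control-class SD. Models within-patient
        correlation of repeated draws.
    external_prevalence_multiplier:
        Prevalence of the external split relative to the base prevalence.
    split_fractions:
        Patient-level fractions of (train, validation, internal_test,
        external_test); must sum to 1.
    """

    n_patients: int = 5000
    seed: int = 0
    sepsis_measurement_prevalence: float = 0.02
    singleton_sepsis_fraction: float = 2.0 / 3.0
    last_position_sepsis_fraction: float = 0.9214
    mean_sequence_length: float = 2.5
    sex_female_fraction: float = 0.5
    patient_effect_scale: float = 0.25
    feature_params: Mapping[str, ClassConditional] = field(
        default_factory=_default_feature_params)
    external_shift: Mapping[str, float] = field(
        default_factory=_default_external_shift)
    external_prevalence_multiplier: float = 1.2
    split_fractions: tuple[float, float, float, float] = (0.60, 0.10, 0.15, 0.15)

    def __post_init__(self) -> None:
        for name in ("sepsis_measurement_prevalence", "singleton_sepsis_fraction",
                     "last_position_sepsis_fraction", "sex_female_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value!r}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.mean_sequence_length < 1.0:
            raise ValueError("mean_sequence_length must be >= 1")
        if self.patient_effect_scale < 0:
            raise ValueError("patient_effect_scale must be >= 0")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split_fractions must sum to 1")
        missing = set(FEATURES) - {"sex"} - set(self.feature_params)
        if missing:
            raise ValueError(f"feature_params missing entries for {sorted(missing)}")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


def _truncnorm_draw(rng, mean, sd, lower, upper, size):
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


class CohortGenerator:
    """Seeded generator of synthetic CBC cohorts.

    ``CohortGenerator(config).sample()`` returns a cohort DataFrame with the
    columns of :data:`COHORT_COLUMNS`. Identical configs (including seed)
    produce identical cohorts.
    """

    def __init__(self, config: GeneratorConfig | None = None):
        self.config = config if config is not None else GeneratorConfig()

    def sample(self) -> pd.DataFrame:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)

        # Sequence lengths: geometric on {1, 2, ...} so singletons occur
        # naturally; mean length is configurable.
        p = 1.0 / cfg.mean_sequence_length
        lengths = rng.geometric(p, size=cfg.n_patients)
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        n_meas = int(offsets[-1])

        # Patient-level split assignment (no patient straddles splits).
        order = rng.permutation(cfg.n_patients)
        bounds = np.floor(np.cumsum(cfg.split_fractions)[:-1]
                          * cfg.n_patients).astype(int)
        split_of_patient = np.empty(cfg.n_patients, dtype=object)
        for tag, chunk in zip(SPLITS, np.split(order, bounds)):
            split_of_patient[chunk] = tag

        label = np.zeros(n_meas, dtype=np.int64)
        external_mask = split_of_patient == "external_test"
        for pool_mask, prevalence in (
            (~external_mask, cfg.sepsis_measurement_prevalence),
            (external_mask, cfg.sepsis_measurement_prevalence
             * cfg.external_prevalence_multiplier),
        ):
            self._assign_sepsis(rng, lengths, offsets, label,
                                np.flatnonzero(pool_mask),
                                min(prevalence, 1.0))

        pid_of_meas = np.repeat(np.arange(cfg.n_patients), lengths)
        position = np.concatenate([np.arange(1, n + 1) for n in lengths])
        is_external = np.repeat(external_mask, lengths)
        patient_has_sepsis = np.zeros(cfg.n_patients, dtype=bool)
        np.maximum.at(patient_has_sepsis, pid_of_meas, label == 1)

        data = {
            "patient_id": np.array([f"P{i:06d}" for i in range(cfg.n_patients)],
                                   dtype=object)[pid_of_meas],
            "position": position,
            "label": label,
            "split": np.repeat(split_of_patient, lengths),
        }
        # sex and age are patient attributes, constant within a sequence
        sex = (rng.random(cfg.n_patients) < cfg.sex_female_fraction)
        data["sex"] = sex.astype(np.int64)[pid_of_meas]
        for f, cp in cfg.feature_params.items():
            effect = rng.normal(0.0, cfg.patient_effect_scale * cp.sd,
                                size=cfg.n_patients)
            if f == "age":
                mean = np.where(patient_has_sepsis, cp.sepsis_mean, cp.mean)
                sd = np.where(patient_has_sepsis, cp.sepsis_sd, cp.sd)
                x = _truncnorm_draw(rng, mean, sd, cp.lower, cp.upper,
                                    cfg.n_patients)[pid_of_meas]
            else:
                mean = np.where(label == 1, cp.sepsis_mean, cp.mean)
                sd = np.where(label == 1, cp.sepsis_sd, cp.sd)
                x = _truncnorm_draw(rng, mean, sd, cp.lower, cp.upper, n_meas)
                x = np.clip(x + effect[pid_of_meas], cp.lower, cp.upper)
            if f in cfg.external_shift:
                x = np.where(is_external,
                             np.clip(x + cfg.external_shift[f],
                                     cp.lower, cp.upper), x)
            data[f] = x
        return pd.DataFrame(data, columns=COHORT_COLUMNS)

    def _assign_sepsis(self, rng, lengths, offsets, label, pool, prevalence):
        """Place sepsis labels inside one pool of patients.

        Singleton patients take ~``singleton_sepsis_fraction`` of the sepsis
        measurements (one each); the remainder goes to multi-measurement
        patients, with ``last_position_sepsis_fraction`` of those placed at
        the final position and the rest uniformly among earlier positions.
        ``label`` is the flat per-measurement label array, indexed through
        ``offsets``.
        """
        if prevalence <= 0 or pool.size == 0:
            return
        cfg = self.config
        total = int(lengths[pool].sum())
        n_sepsis = int(round(prevalence * total))
        if n_sepsis == 0:
            return
        singles = pool[lengths[pool] == 1]
        multis = pool[lengths[pool] >= 2]
        n_single = min(int(round(cfg.singleton_sepsis_fraction * n_sepsis)),
                       singles.size)
        n_inseq = min(n_sepsis - n_single, multis.size)
        if n_single:
            chosen = rng.choice(singles, size=n_single, replace=False)
            label[offsets[chosen]] = 1
        if n_inseq:
            chosen = rng.permutation(
                rng.choice(multis, size=n_inseq, replace=False))
            n_last = int(round(cfg.last_position_sepsis_fraction * n_inseq))
            for j, pid in enumerate(chosen):
                if j < n_last:
                    pos = lengths[pid] - 1
                else:
                    pos = int(rng.integers(0, lengths[pid] - 1))
                label[offsets[pid] + pos] = 1


def generate_cohort(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Generate a synthetic cohort (thin wrapper over :class:`CohortGenerator`)."""
    return CohortGenerator(config).sample()


@dataclass(frozen=True)
class CohortStats:
    """Descriptor statistics of a cohort.

    ``singleton_sepsis_fraction`` and ``last_position_sepsis_fraction`` are
    ``None`` when their denominator is empty (no sepsis / no in-sequence
    sepsis) rather than raising a division error.
    """

    n_measurements: int
    n_patients: int
    sepsis_prevalence: float
    singleton_sepsis_fraction: float | None
    last_position_sepsis_fraction: float | None
    sequence_length_histogram: dict[int, int]

    def as_dict(self) -> dict:
        return {
            "n_measurements": self.n_measurements,
            "n_patients": self.n_patients,
            "sepsis_prevalence": self.sepsis_prevalence,
            "singleton_sepsis_fraction": self.singleton_sepsis_fraction,
            "last_position_sepsis_fraction": self.last_position_sepsis_fraction,
            "sequence_length_histogram": dict(self.sequence_length_histogram),
        }


def cohort_stats(cohort: pd.DataFrame) -> CohortStats:
    """Compute the structural descriptors of a cohort.

    Returns measurement count, sepsis prevalence, the fraction of sepsis
    measurements that are singletons (their patient has exactly one
    measurement), the fraction of in-sequence sepsis measurements at their
    patient's final position, and the sequence-length histogram.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    sizes = cohort.groupby("patient_id")["position"].transform("size")
    maxpos = cohort.groupby("patient_id")["position"].transform("max")
    is_sepsis = cohort["label"] == 1
    n_sepsis = int(is_sepsis.sum())

    singleton_fraction = None
    last_fraction = None
    if n_sepsis > 0:
        singleton_fraction = float((is_sepsis & (sizes == 1)).sum() / n_sepsis)
        inseq = is_sepsis & (sizes >= 2)
        n_inseq = int(inseq.sum())
        if n_inseq > 0:
            last_fraction = float(
                (inseq & (cohort["position"] == maxpos)).sum() / n_inseq)

    hist = (cohort.groupby("patient_id")["position"].max()
            .value_counts().sort_index())
    return CohortStats(
        n_measurements=len(cohort),
        n_patients=cohort["patient_id"].nunique(),
        sepsis_prevalence=float(is_sepsis.mean()),
        singleton_sepsis_fraction=singleton_fraction,
        last_position_sepsis_fraction=last_fraction,
        sequence_length_histogram={int(k): int(v) for k, v in hist.items()},
    )


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort to CSV with the canonical header."""
    cohort.loc[:, COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, validating columns and dtypes.

    Raises ``ValueError`` naming the offending column on missing/extra
    columns or non-numeric cells.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "split": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing column(s): {missing}")
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    if extra:
        raise ValueError(f"cohort file has unexpected column(s): {extra}")
    numeric = ["position", "age", "sex", "hemoglobin", "rbc", "wbc", "mcv",
               "platelets", "label"]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if len(df) and coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise ValueError(
                f"non-numeric value in column {col!r} at row {row}")
        df[col] = coerced
    if len(df):
        df["position"] = df["position"].astype(np.int64)
        df["sex"] = df["sex"].astype(np.int64)
        df["label"] = df["label"].astype(np.int64)
    else:
        df = df.astype({"position": np.int64, "sex": np.int64,
                        "label": np.int64})
    return df.loc[:, COHORT_COLUMNS]
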