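"""Synthetic paired DBS / DBS_wb / WB cohorts.

The generator emulates the statistical structure the agreement analysis
assumes, so the whole pipeline is testable without patient data:

* a latent capillary concentration per patient, drawn log-uniformly
  over the study's concentration range (3.7–33.3 µg/L), spreading
  points across the range without assuming a population PK model;
* duplicate capillary spots = latent level × independent lognormal
  replicate noise (median-1, small CV);
* DBS_wb = latent level × lognormal spotting noise;
* WB = (intercept + slope × latent) × lognormal ratio noise — the
  proportional bias between matrices (slope 0.89 by default) plus the
  between-method scatter whose default CV, 9.4%, is back-calculated
  from the width of the study's printed limits of agreement,
  (1.08 − 0.71) / (2 × 1.96);
* spots independently marked invalid at a small per-spot rate, so a
  patient loses their duplicate set only when both spots fail;
* hematocrit, daily dose and time after dose drawn from study-like
  ranges.

All noise is multiplicative lognormal (median 1): concentrations stay
positive and the relative spread is roughly constant, matching a
ratio-scale analysis.  A zero-noise configuration is an exact fixed
point of the pipeline: perfect agreement, all prediction errors zero.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

from .samples import PairedSample, write_samples

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_replicates",
    "write_cohort",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for one cohort.

    CVs are fractional SDs of the multiplicative lognormal noise terms;
    concentrations in µg/L, hematocrit in L/L, dose in mg, times in h.
    """

    n_patients: int = 20
    slope: float = 0.89
    intercept: float = 0.02
    dbs_range: tuple[float, float] = (3.7, 33.3)
    ratio_cv: float = 0.094
    duplicate_cv: float = 0.03
    dbswb_cv: float = 0.05
    hematocrit_range: tuple[float, float] = (0.25, 0.45)
    invalid_spot_rate: float = 0.025
    dose_choices: tuple[float, ...] = (5.0, 7.5, 10.0, 12.5, 15.0, 17.5)
    t_after_dose_range: tuple[float, float] = (20.0, 24.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("ratio_cv", "duplicate_cv", "dbswb_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("dbs_range", "hematocrit_range", "t_after_dose_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be an ordered (low, high) range")
        if not 0 <= self.invalid_spot_rate <= 1:
            raise ValueError("invalid_spot_rate must be a probability")
        if not self.slope > 0:
            raise ValueError("slope must be > 0")
        if self.dbs_range[0] <= 0:
            raise ValueError("dbs_range must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually drew, for cross-checking downstream."""

    latent: np.ndarray
    config: SyntheticConfig
    n_dbs_excluded: int  # patients with both spots invalid


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    # unit-mean multiplicative noise with fractional SD cv; the mean-1
    # parameterisation keeps E[measured] equal to the model line, so the
    # slope estimator is unbiased under the generator
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size))


def generate_cohort(config: SyntheticConfig) -> tuple[list[PairedSample], GroundTruth]:
    """Draw one cohort; deterministic given ``config`` (incl. its seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    lo, hi = config.dbs_range
    latent = np.exp(rng.uniform(np.log(lo), np.log(hi), n))

    spot_a = latent * _lognormal_factor(rng, config.duplicate_cv, n)
    spot_b = latent * _lognormal_factor(rng, config.duplicate_cv, n)
    dbs_wb = latent * _lognormal_factor(rng, config.dbswb_cv, n)
    wb = (config.intercept + config.slope * latent) * _lognormal_factor(
        rng, config.ratio_cv, n
    )
    valid = rng.random((n, 2)) >= config.invalid_spot_rate
    hct = rng.uniform(*config.hematocrit_range, n)
    dose = rng.choice(np.asarray(config.dose_choices, dtype=float), n)
    t_after = rng.uniform(*config.t_after_dose_range, n)

    width = len(str(n))
    samples = [
        PairedSample(
            patient_id=f"P{i + 1:0{width}d}",
            dbs_spot_a=float(spot_a[i]),
            dbs_spot_a_valid=bool(valid[i, 0]),
            dbs_spot_b=float(spot_b[i]),
            dbs_spot_b_valid=bool(valid[i, 1]),
            dbs_wb=float(dbs_wb[i]),
            wb=float(wb[i]),
            hematocrit=float(hct[i]),
            dose_mg=float(dose[i]),
            time_after_dose_h=float(t_after[i]),
        )
        for i in range(n)
    ]
    truth = GroundTruth(
        latent=latent,
        config=config,
        n_dbs_excluded=int(np.sum(~valid.any(axis=1))),
    )
    return samples, truth


def subseed(master_seed: int, k: int) -> int:
    """Deterministic sub-seed for replicate k of a master seed (< 2^31)."""
    return int(np.random.SeedSequence((master_seed, k)).generate_state(1)[0] % 2**31)


def generate_replicates(
    config: SyntheticConfig, n_reps: int
) -> Iterator[tuple[list[PairedSample], GroundTruth]]:
    """Independent replicate cohorts under sub-seeds of ``config.seed``.

    Replicate k regenerated alone (via :func:`subseed`) equals replicate
    k from the stream.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    for k in range(n_reps):
        yield generate_cohort(
            dataclasses.replace(config, seed=subseed(config.seed, k))
        )


def write_cohort(
    samples: list[PairedSample],
    truth: GroundTruth,
    path: str | Path,
    *,
    sidecar: bool = True,
) -> None:
    """Write the cohort CSV plus a ground-truth JSON sidecar."""
    path = Path(path)
    write_samples(samples, path)
    if sidecar:
        cfg = dataclasses.asdict(truth.config)
        meta = {
            "config": cfg,
            "latent": truth.latent.tolist(),
            "n_dbs_excluded": truth.n_dbs_excluded,
        }
        path.with_suffix(".truth.json").write_text(json.dumps(meta, indent=2))
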