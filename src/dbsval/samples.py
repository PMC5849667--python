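"""Paired-sample I/O, quality control, and pairing.

One row of the study table holds, for a single patient, the duplicate
capillary dried-blood-spot (DBS) concentrations, a spot prepared from
venous whole blood (DBS_wb), the venous whole-blood (WB) concentration,
hematocrit, daily dose, and time after the last dose.  Units are fixed
throughout the package: concentrations in µg/L, hematocrit as a fraction
(L/L), dose in mg/day, times in hours.

Every input row is accounted for exactly once: analysed, flagged and
analysed, or rejected/excluded with a reason.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PairedSample",
    "AnalysisPair",
    "PairingError",
    "SchemaError",
    "CSV_COLUMNS",
    "read_samples",
    "write_samples",
    "write_qc_report",
    "resolve_dbs",
    "flag_hematocrit",
    "build_pairs",
    "PAIR_NAMES",
]

#: canonical CSV schema, in column order
CSV_COLUMNS = (
    "patient_id",
    "dbs_spot_a",
    "dbs_spot_a_valid",
    "dbs_spot_b",
    "dbs_spot_b_valid",
    "dbs_wb",
    "wb",
    "hematocrit",
    "dose_mg",
    "time_after_dose_h",
)

#: QC flag codes
FLAG_SINGLE_SPOT = "single_spot"
FLAG_DBS_EXCLUDED = "dbs_excluded"
FLAG_LOW_HEMATOCRIT = "low_hematocrit"
FLAG_HCT_HIGH_CONC = "low_hct_high_conc"

PAIR_NAMES = ("dbs_vs_wb", "dbswb_vs_wb", "dbs_vs_dbswb")


class SchemaError(ValueError):
    """A mandatory column is missing from the input table."""


class PairingError(ValueError):
    """Too few complete pairs to run an agreement analysis."""


@dataclass
class PairedSample:
    """One patient's paired concentrations plus covariates and QC state.

    Missing concentrations are ``None``.  ``flags`` accumulates QC warning
    codes; it never silently drops a sample — exclusion is itself a flag.
    """

    patient_id: str
    dbs_spot_a: float | None
    dbs_spot_b: float | None
    wb: float
    hematocrit: float
    dose_mg: float
    time_after_dose_h: float
    dbs_spot_a_valid: bool = True
    dbs_spot_b_valid: bool = True
    dbs_wb: float | None = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name in ("dbs_spot_a", "dbs_spot_b", "dbs_wb", "wb"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(
                    f"{self.patient_id}: {name}={v!r} must be a positive concentration"
                )
        if not 0 < self.hematocrit < 1:
            raise ValueError(
                f"{self.patient_id}: hematocrit={self.hematocrit!r} outside (0, 1)"
            )
        if not self.dose_mg > 0:
            raise ValueError(f"{self.patient_id}: dose_mg must be > 0")
        if self.time_after_dose_h < 0:
            raise ValueError(f"{self.patient_id}: time_after_dose_h must be >= 0")


@dataclass
class AnalysisPair:
    """Aligned comparator (x) and reference (y) concentration vectors."""

    x: np.ndarray
    y: np.ndarray
    labels: tuple[str, ...]
    pair_name: str

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D and the same length")
        if len(self.x) < 3:
            raise PairingError(
                f"{self.pair_name}: need at least 3 complete pairs, got {len(self.x)}"
            )
        if np.any(self.x <= 0) or np.any(self.y <= 0):
            raise ValueError(f"{self.pair_name}: concentrations must be positive")

    @property
    def n(self) -> int:
        return len(self.x)


def _parse_float(value, *, allow_missing: bool) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        if allow_missing:
            return None
        raise ValueError("mandatory value missing")
    return float(value)


def _parse_bool(value) -> bool:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return False
    s = str(value).strip().lower()
    if s in {"1", "true", "t", "yes", "y"}:
        return True
    if s in {"0", "false", "f", "no", "n"}:
        return False
    raise ValueError(f"cannot interpret {value!r} as a validity flag")


def read_samples(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> tuple[list[PairedSample], list[dict]]:
    """Read a paired-sample CSV.

    Parameters
    ----------
    path:
        Comma-separated file with a mandatory header row; decimal point;
        missing values as empty fields.
    schema:
        Optional mapping from canonical column names (`CSV_COLUMNS`) to
        the names actually used in the file.

    Returns
    -------
    samples, rejections:
        Parsed records, and one dict per rejected row with keys
        ``row`` (1-based data row number), ``patient_id`` and ``reason``.

    Raises
    ------
    SchemaError
        If a mandatory column is absent after applying ``schema``.
    """
    schema = dict(schema or {})
    rename = {schema.get(c, c): c for c in CSV_COLUMNS}
    df = pd.read_csv(path, sep=",", decimal=".", float_precision="round_trip")
    df = df.rename(columns=rename)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    samples: list[PairedSample] = []
    rejections: list[dict] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        r = row._asdict()
        pid = str(r["patient_id"])
        try:
            samples.append(
                PairedSample(
                    patient_id=pid,
                    dbs_spot_a=_parse_float(r["dbs_spot_a"], allow_missing=True),
                    dbs_spot_a_valid=_parse_bool(r["dbs_spot_a_valid"]),
                    dbs_spot_b=_parse_float(r["dbs_spot_b"], allow_missing=True),
                    dbs_spot_b_valid=_parse_bool(r["dbs_spot_b_valid"]),
                    dbs_wb=_parse_float(r["dbs_wb"], allow_missing=True),
                    wb=_parse_float(r["wb"], allow_missing=False),
                    hematocrit=_parse_float(r["hematocrit"], allow_missing=False),
                    dose_mg=_parse_float(r["dose_mg"], allow_missing=False),
                    time_after_dose_h=_parse_float(
                        r["time_after_dose_h"], allow_missing=False
                    ),
                )
            )
        except (ValueError, TypeError) as exc:
            rejections.append({"row": i, "patient_id": pid, "reason": str(exc)})
    return samples, rejections


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "1" if v else "0"
    return repr(float(v)) if isinstance(v, float) else str(v)


def write_samples(samples: Iterable[PairedSample], path: str | Path) -> None:
    """Write samples in the canonical CSV schema (round-trips with
    :func:`read_samples`; full float precision via ``repr``)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CSV_COLUMNS)
        for s in samples:
            w.writerow([_fmt(getattr(s, c)) for c in CSV_COLUMNS])


def resolve_dbs(sample: PairedSample) -> float | None:
    """Resolve the duplicate capillary spots to one DBS concentration.

    Both spots valid: their arithmetic mean.  Exactly one valid: that
    spot's value, with a ``single_spot`` flag.  Neither valid: ``None``
    (sample excluded from DBS comparisons but still usable for the
    DBS_wb/WB pair), with a ``dbs_excluded`` flag.  Missing spot values
    are treated as invalid.
    """
    a_ok = sample.dbs_spot_a_valid and sample.dbs_spot_a is not None
    b_ok = sample.dbs_spot_b_valid and sample.dbs_spot_b is not None
    if a_ok and b_ok:
        return (sample.dbs_spot_a + sample.dbs_spot_b) / 2.0
    if a_ok or b_ok:
        sample.flags.add(FLAG_SINGLE_SPOT)
        return sample.dbs_spot_a if a_ok else sample.dbs_spot_b
    sample.flags.add(FLAG_DBS_EXCLUDED)
    return None


def flag_hematocrit(
    sample: PairedSample,
    *,
    hard_limit: float = 0.20,
    caution_limit: float = 0.25,
    high_conc: float = 20.0,
) -> set[str]:
    """Apply hematocrit QC flags and return the sample's updated flag set.

    Spot assays under-recover at low hematocrit; the effect is worst for
    high concentrations.  Hematocrit ≤ 0.20 L/L earns a hard warning;
    hematocrit < 0.25 L/L combined with any spot concentration > 20 µg/L
    earns a caution flag.
    """
    if sample.hematocrit <= hard_limit:
        sample.flags.add(FLAG_LOW_HEMATOCRIT)
    dbs_values = [
        v for v in (sample.dbs_spot_a, sample.dbs_spot_b, sample.dbs_wb) if v is not None
    ]
    if sample.hematocrit < caution_limit and dbs_values and max(dbs_values) > high_conc:
        sample.flags.add(FLAG_HCT_HIGH_CONC)
    return sample.flags


def build_pairs(
    samples: Sequence[PairedSample],
) -> dict[str, AnalysisPair]:
    """Build the three method-comparison pairs.

    Returns ``dbs_vs_wb`` (x = resolved capillary DBS, y = WB),
    ``dbswb_vs_wb`` (x = DBS_wb, y = WB) and ``dbs_vs_dbswb``
    (x = resolved DBS, y = DBS_wb), each restricted to samples where
    both members are present.

    Raises
    ------
    PairingError
        If any pair ends up with fewer than 3 complete pairs.
    """
    dbs = {s.patient_id: resolve_dbs(s) for s in samples}

    def collect(getter_x, getter_y, name) -> AnalysisPair:
        xs, ys, labels = [], [], []
        for s in samples:
            x, y = getter_x(s), getter_y(s)
            if x is not None and y is not None:
                xs.append(x)
                ys.append(y)
                labels.append(s.patient_id)
        if len(xs) < 3:
            raise PairingError(
                f"{name}: need at least 3 complete pairs, got {len(xs)}"
            )
        return AnalysisPair(np.array(xs), np.array(ys), tuple(labels), name)

    return {
        "dbs_vs_wb": collect(lambda s: dbs[s.patient_id], lambda s: s.wb, "dbs_vs_wb"),
        "dbswb_vs_wb": collect(lambda s: s.dbs_wb, lambda s: s.wb, "dbswb_vs_wb"),
        "dbs_vs_dbswb": collect(
            lambda s: dbs[s.patient_id], lambda s: s.dbs_wb, "dbs_vs_dbswb"
        ),
    }


def write_qc_report(samples: Iterable[PairedSample], path: str | Path) -> None:
    """Write a per-patient QC action log (patient_id, action, flags)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "action", "flags"])
        for s in samples:
            action = "excluded_dbs" if FLAG_DBS_EXCLUDED in s.flags else "analyzed"
            w.writerow([s.patient_id, action, ";".join(sorted(s.flags))])
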