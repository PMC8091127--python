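"""Containers and CSV I/O for longitudinal SOFA trial data.

The modelling dataset is NONMEM-flavoured: one row per subject-day with
columns ID, ARM, DAY, DV (SOFA score), BASE (baseline SOFA) and AUC
(steady-state AUC0-8h in h*ng/mL, 0 for placebo).  Missing values are
written as "." and blank cells are accepted on read.  Time is in days
for SOFA observations and in hours for concentration profiles; the NCA
module is the only place the two meet.

SOFA is stored as a real number, not an integer: observed scores are
integers in 0..24, but model predictions and simulated DVs are
continuous and may stray slightly outside the observable range.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ARMS",
    "MISSING_TOKEN",
    "ObservationRecord",
    "SubjectRecord",
    "TrialDataset",
    "ConcentrationProfile",
    "SchemaError",
    "ValidationError",
    "read_dataset",
    "write_dataset",
    "read_concentrations",
    "write_concentrations",
]

logger = logging.getLogger(__name__)

#: Recognised treatment arms: placebo and the three dose levels in mg/kg.
ARMS = ("placebo", "0.06", "0.12", "0.24")

MISSING_TOKEN = "."

_DATASET_COLUMNS = ("ID", "ARM", "DAY", "DV", "BASE", "AUC")
_CONC_COLUMNS = ("ID", "OCC", "TIME_H", "CONC")

_OCCASIONS = ("first_dose", "last_dose")


class SchemaError(ValueError):
    """A required column is absent or the file layout is unusable."""


class ValidationError(ValueError):
    """The data violate a dataset invariant."""


@dataclass(frozen=True)
class ObservationRecord:
    """One SOFA measurement: ``day`` is time since first dose in days."""

    day: float
    sofa: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.day) or self.day < 0:
            raise ValidationError(f"observation day must be finite and >= 0, got {self.day}")
        if not np.isfinite(self.sofa):
            raise ValidationError(f"SOFA value must be finite, got {self.sofa}")
        if not (0.0 <= self.sofa <= 24.0):
            logger.warning("SOFA value %.3g outside the observable 0-24 range", self.sofa)


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: arm label, baseline SOFA, exposure, and observations.

    ``auc`` is the steady-state AUC0-8h in h*ng/mL used as the exposure
    metric driving the drug effect; it is exactly 0 for placebo subjects.
    ``base`` is the observed pre-dose baseline SOFA, a covariate (never
    an estimated parameter).
    """

    id: str
    arm: str
    base: float
    auc: float
    observations: tuple[ObservationRecord, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations", tuple(self.observations))
        if self.arm not in ARMS:
            raise ValidationError(f"subject {self.id}: unknown arm {self.arm!r}; expected one of {ARMS}")
        if not np.isfinite(self.base) or self.base <= 0:
            raise ValidationError(f"subject {self.id}: baseline SOFA must be > 0, got {self.base}")
        if not np.isfinite(self.auc) or self.auc < 0:
            raise ValidationError(f"subject {self.id}: AUC must be >= 0, got {self.auc}")
        if (self.arm == "placebo") != (self.auc == 0.0):
            raise ValidationError(
                f"subject {self.id}: arm={self.arm} with AUC={self.auc}; "
                "placebo subjects must have AUC=0 and drug subjects AUC>0"
            )
        days = [o.day for o in self.observations]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValidationError(f"subject {self.id}: observation days must be strictly increasing")
        for o in self.observations:
            if o.day == 0 and abs(o.sofa - self.base) > 1e-9:
                raise ValidationError(
                    f"subject {self.id}: day-0 observation ({o.sofa}) must equal baseline ({self.base})"
                )

    @property
    def days(self) -> np.ndarray:
        return np.array([o.day for o in self.observations], dtype=float)

    @property
    def sofa(self) -> np.ndarray:
        return np.array([o.sofa for o in self.observations], dtype=float)


@dataclass(frozen=True)
class TrialDataset:
    """All subjects of one trial, pooled across placebo and drug arms."""

    subjects: tuple[SubjectRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "subjects", tuple(self.subjects))
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate subject ids: {dupes}")
        if self.subjects and self.n_observations == 0:
            raise ValidationError("dataset contains subjects but no observations")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return sum(len(s.observations) for s in self.subjects)

    @property
    def n_drug_subjects(self) -> int:
        return sum(1 for s in self.subjects if s.arm != "placebo")

    def subject(self, id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.id == id:
                return s
        raise KeyError(id)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (s.id, s.arm, o.day, o.sofa, s.base, s.auc)
            for s in self.subjects
            for o in s.observations
        ]
        return pd.DataFrame(rows, columns=list(_DATASET_COLUMNS))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TrialDataset":
        """Build a validated dataset from a long-format frame.

        Expects the canonical columns ID, ARM, DAY, DV, BASE, AUC.  Rows
        with missing DV are dropped (and counted in the log), matching
        the reader's behaviour.
        """
        missing = [c for c in _DATASET_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        n_missing_dv = int(df["DV"].isna().sum())
        if n_missing_dv:
            logger.info("dropping %d row(s) with missing DV", n_missing_dv)
            df = df.dropna(subset=["DV"])
        dup = df.duplicated(subset=["ID", "DAY"])
        if dup.any():
            first = df.loc[dup, ["ID", "DAY"]].iloc[0]
            raise ValidationError(
                f"duplicate (ID, DAY) record: id={first['ID']!r}, day={first['DAY']}"
            )
        subjects = []
        for sid, g in df.groupby("ID", sort=False):
            g = g.sort_values("DAY")
            arms = g["ARM"].unique()
            bases = g["BASE"].unique()
            aucs = g["AUC"].unique()
            if len(arms) > 1 or len(bases) > 1 or len(aucs) > 1:
                raise ValidationError(f"subject {sid!r}: ARM/BASE/AUC must be constant within subject")
            obs = tuple(ObservationRecord(day=float(d), sofa=float(v)) for d, v in zip(g["DAY"], g["DV"]))
            subjects.append(
                SubjectRecord(
                    id=str(sid),
                    arm=str(arms[0]),
                    base=float(bases[0]),
                    auc=float(aucs[0]),
                    observations=obs,
                )
            )
        dataset = cls(subjects=tuple(subjects))
        logger.info(
            "loaded %d subject(s) contributing %d SOFA observation(s)",
            dataset.n_subjects,
            dataset.n_observations,
        )
        return dataset


@dataclass(frozen=True)
class ConcentrationProfile:
    """Plasma concentration-time samples for one dosing occasion.

    Times are in hours after the start of the (first or last) infusion;
    concentrations in ng/mL.
    """

    id: str
    occasion: str
    samples: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple((float(t), float(c)) for t, c in self.samples))
        if self.occasion not in _OCCASIONS:
            raise ValidationError(
                f"profile {self.id}: occasion must be one of {_OCCASIONS}, got {self.occasion!r}"
            )
        times = [t for t, _ in self.samples]
        if any(not (0.0 <= t <= 24.0) for t in times):
            raise ValidationError(f"profile {self.id}: sample times must lie within [0, 24] h")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError(f"profile {self.id}: sample times must be strictly increasing")
        if any(c < 0 for _, c in self.samples):
            raise ValidationError(f"profile {self.id}: concentrations must be >= 0")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.samples], dtype=float)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for _, c in self.samples], dtype=float)


def _resolve_columns(df: pd.DataFrame, required: Sequence[str], schema: Mapping[str, str] | None) -> pd.DataFrame:
    """Case-insensitive column resolution with an optional rename map."""
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    upper = {c.upper(): c for c in df.columns}
    rename = {}
    for col in required:
        if col in df.columns:
            continue
        if col.upper() in upper:
            rename[upper[col.upper()]] = col
        else:
            raise SchemaError(f"missing required column: {col}")
    return df.rename(columns=rename)


def _to_numeric(df: pd.DataFrame, columns: Iterable[str], path: Path) -> pd.DataFrame:
    df = df.copy()
    for col in columns:
        raw = df[col]
        as_str = raw.astype(str).str.strip()
        is_missing = raw.isna() | (as_str == MISSING_TOKEN) | (as_str == "")
        converted = pd.to_numeric(raw.where(~is_missing), errors="coerce")
        bad = (~is_missing) & converted.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{path}: non-numeric value {raw.iloc[row]!r} in column {col}, data row {row + 1}"
            )
        df[col] = converted
    return df


def read_dataset(path: str | Path, schema: Mapping[str, str] | None = None) -> TrialDataset:
    """Read a NONMEM-style SOFA dataset CSV into a validated :class:`TrialDataset`.

    Parameters
    ----------
    path
        CSV file with a header row; required columns ID, ARM, DAY, DV,
        BASE, AUC (case-insensitive).
    schema
        Optional mapping from canonical column name to the name used in
        the file, e.g. ``{"DV": "SOFA"}``.

    Rows whose DV is missing ("." or blank) are dropped and counted in
    the log; a duplicate (ID, DAY) pair or a violated subject invariant
    raises :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
    df = _resolve_columns(df, _DATASET_COLUMNS, schema)
    df = _to_numeric(df, ("DAY", "DV", "BASE", "AUC"), path)
    df["ID"] = df["ID"].astype(str).str.strip()
    df["ARM"] = df["ARM"].astype(str).str.strip().str.lower()
    return TrialDataset.from_dataframe(df[list(_DATASET_COLUMNS)])


def write_dataset(dataset: TrialDataset, path: str | Path) -> None:
    """Write a dataset as CSV with deterministic column order ID,ARM,DAY,DV,BASE,AUC."""
    path = Path(path)
    df = dataset.to_dataframe()
    df.to_csv(path, index=False, na_rep=MISSING_TOKEN, float_format="%.17g")


def read_concentrations(path: str | Path) -> list[ConcentrationProfile]:
    """Read concentration-time profiles from CSV (ID, OCC, TIME_H, CONC)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"concentration file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
    df = _resolve_columns(df, _CONC_COLUMNS, None)
    df = _to_numeric(df, ("TIME_H", "CONC"), path)
    df["ID"] = df["ID"].astype(str).str.strip()
    occ_map = {"FIRST": "first_dose", "LAST": "last_dose",
               "FIRST_DOSE": "first_dose", "LAST_DOSE": "last_dose"}
    df["OCC"] = df["OCC"].astype(str).str.strip().str.upper().map(occ_map)
    if df["OCC"].isna().any():
        raise ValidationError(f"{path}: OCC values must be FIRST or LAST")
    profiles = []
    for (sid, occ), g in df.groupby(["ID", "OCC"], sort=False):
        g = g.dropna(subset=["CONC"]).sort_values("TIME_H")
        profiles.append(
            ConcentrationProfile(
                id=str(sid),
                occasion=str(occ),
                samples=tuple(zip(g["TIME_H"], g["CONC"])),
            )
        )
    return profiles


def write_concentrations(profiles: Sequence[ConcentrationProfile], path: str | Path) -> None:
    """Write concentration profiles as CSV (ID, OCC, TIME_H, CONC)."""
    rows = [
        (p.id, "FIRST" if p.occasion == "first_dose" else "LAST", t, c)
        for p in profiles
        for t, c in p.samples
    ]
    df = pd.DataFrame(rows, columns=list(_CONC_COLUMNS))
    df.to_csv(Path(path), index=False, na_rep=MISSING_TOKEN, float_format="%.17g")
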