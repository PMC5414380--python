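"""Cohort container: per-individual follow-up, demographics and covariates.

The same container holds real-world data (all-cause time / status) and, in
simulations, hypothetical-world data (disease time censored administratively).
Follow-up times are integer days; ages are stored in days; entry dates are
days since 1960-01-01.  The on-disk layout is delimited text with columns
``time,cens,age,sex,diag[,group,stratum]`` where ``age`` is in years and is
converted to days on ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._calendar import DAYS_PER_YEAR


@dataclass
class Cohort:
    """Arrays of equal length n; ``group``/``stratum`` are integer labels."""

    time: np.ndarray             # follow-up, integer days, > 0
    status: np.ndarray           # 1 = death, 0 = censored
    age_at_entry: np.ndarray     # days
    sex: np.ndarray              # 1 = male, 2 = female
    entry_date: np.ndarray       # days since 1960-01-01
    group: Optional[np.ndarray] = None
    stratum: Optional[np.ndarray] = None

    def __post_init__(self):
        self.time = np.asarray(np.round(self.time), dtype="int64")
        self.status = np.asarray(self.status, dtype="int64")
        self.age_at_entry = np.asarray(np.round(self.age_at_entry), dtype="int64")
        self.sex = np.asarray(self.sex, dtype="int64")
        self.entry_date = np.asarray(np.round(self.entry_date), dtype="int64")
        if self.group is not None:
            self.group = np.asarray(self.group, dtype="int64")
        if self.stratum is not None:
            self.stratum = np.asarray(self.stratum, dtype="int64")
        n = len(self.time)
        for name in ("status", "age_at_entry", "sex", "entry_date"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if (self.time <= 0).any():
            raise ValueError("all follow-up times must be > 0 days")
        if not np.isin(self.status, (0, 1)).all():
            raise ValueError("status must be 0 or 1")
        if not np.isin(self.sex, (1, 2)).all():
            raise ValueError("sex must be coded 1 (male) / 2 (female)")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n(self) -> int:
        return len(self.time)

    def group_labels(self) -> np.ndarray:
        if self.group is None:
            raise ValueError("cohort has no group variable")
        return np.unique(self.group)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time": self.time,
                "cens": self.status,
                "age": self.age_at_entry / DAYS_PER_YEAR,
                "sex": self.sex,
                "diag": self.entry_date,
            }
        )
        if self.group is not None:
            df["group"] = self.group
        if self.stratum is not None:
            df["stratum"] = self.stratum
        return df

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


def cohort_from_frame(
    df: pd.DataFrame,
    group: Optional[str] = None,
    stratum: Optional[str] = None,
) -> Cohort:
    """Build a :class:`Cohort` from a data frame in the standard layout.

    ``group``/``stratum`` name the columns holding the comparison and
    stratification variables; labels are recoded to 0..k-1 in sorted order.
    """
    for col in ("time", "cens", "age", "sex", "diag"):
        if col not in df.columns:
            raise ValueError(f"cohort data missing column {col!r}")

    def _codes(name):
        if name is None:
            return None
        if name not in df.columns:
            raise ValueError(f"column {name!r} not found in cohort data")
        return pd.factorize(df[name], sort=True)[0]

    return Cohort(
        time=df["time"].to_numpy(),
        status=df["cens"].to_numpy(),
        age_at_entry=np.round(df["age"].to_numpy(dtype=float) * DAYS_PER_YEAR),
        sex=df["sex"].to_numpy(),
        entry_date=df["diag"].to_numpy(),
        group=_codes(group),
        stratum=_codes(stratum),
    )


def load_cohort(path, group: Optional[str] = None, stratum: Optional[str] = None) -> Cohort:
    """Read a cohort from delimited text (``time,cens,age,sex,diag,...``)."""
    return cohort_from_frame(pd.read_csv(path), group=group, stratum=stratum)
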