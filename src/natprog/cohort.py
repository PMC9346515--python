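"""Tidy cohort container for longitudinal phenotyping + survival data.

A :class:`CohortDataset` bundles the three (optionally four) tidy tables of a
weekly phenotyping study:

* ``mice`` — one row per animal: ``mouse_id, genotype, arm,
  treatment_start_week`` (missing for untreated animals).
* ``observations`` — one row per mouse-week: body weight (g), the three
  hanging-trial times (s, capped at 60), and the four ordinal clinical signs
  (kyphosis, walking, ptosis, breathing; each in {0, 0.5, 1}).
* ``survival`` — one row per mouse: age (weeks) at death or censoring plus an
  event flag (1 = death observed, 0 = administratively censored).
* ``muscle`` — optional post-mortem endpoint panel: muscle masses (mg),
  minimum Feret diameter (µm) and % fibers with mispositioned nuclei.

All ages are on the absolute age scale in weeks (week 3 = weaning, the first
assessment). Validation enforces the structural invariants at construction
and at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CohortDataset",
    "CohortValidationError",
    "MICE_COLUMNS",
    "OBS_COLUMNS",
    "SURVIVAL_COLUMNS",
    "MUSCLE_COLUMNS",
    "HANG_COLUMNS",
    "ORDINAL_FACTORS",
    "read_cohort",
    "write_cohort",
]

HANG_COLUMNS = ["hang1", "hang2", "hang3"]
ORDINAL_FACTORS = ["kyphosis", "walking", "ptosis", "breathing"]
ORDINAL_LEVELS = (0.0, 0.5, 1.0)

MICE_COLUMNS = ["mouse_id", "genotype", "arm", "treatment_start_week"]
OBS_COLUMNS = ["mouse_id", "week", "body_weight", *HANG_COLUMNS, *ORDINAL_FACTORS]
SURVIVAL_COLUMNS = ["mouse_id", "time", "event"]
MUSCLE_COLUMNS = [
    "mouse_id",
    "ta_mass",
    "gas_mass",
    "quad_mass",
    "min_feret",
    "pct_mispositioned_nuclei",
]

HANG_MAX_SECONDS = 60.0


class CohortValidationError(ValueError):
    """A cohort table violates a structural invariant."""


def _require_columns(df: pd.DataFrame, columns: list[str], table: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{table}: missing columns {missing}")


def _rows(mask: pd.Series) -> list[int]:
    return [int(i) for i in np.flatnonzero(np.asarray(mask))]


@dataclass
class CohortDataset:
    """In-memory cohort: per-mouse metadata, weekly observations, outcomes."""

    mice: pd.DataFrame
    observations: pd.DataFrame
    survival: pd.DataFrame
    muscle: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> "CohortDataset":
        mice, obs, surv = self.mice, self.observations, self.survival
        _require_columns(mice, ["mouse_id", "genotype", "arm"], "mice")
        _require_columns(obs, OBS_COLUMNS, "observations")
        _require_columns(surv, SURVIVAL_COLUMNS, "survival")
        if "treatment_start_week" not in mice.columns:
            mice = mice.assign(treatment_start_week=np.nan)
            self.mice = mice

        if mice["mouse_id"].duplicated().any():
            dupes = mice.loc[mice["mouse_id"].duplicated(), "mouse_id"].tolist()
            raise CohortValidationError(f"mice: duplicated mouse_id {dupes}")
        known = set(mice["mouse_id"])

        for table_name, df in (("observations", obs), ("survival", surv)):
            bad = ~df["mouse_id"].isin(known)
            if bad.any():
                raise CohortValidationError(
                    f"{table_name}: unknown mouse_id at rows {_rows(bad)}"
                )

        dup = obs.duplicated(subset=["mouse_id", "week"])
        if dup.any():
            raise CohortValidationError(
                f"observations: duplicated (mouse_id, week) at rows {_rows(dup)}"
            )
        bad = ~(obs["body_weight"] > 0)
        if bad.any():
            raise CohortValidationError(
                f"observations: non-positive body_weight at rows {_rows(bad)}"
            )
        for col in HANG_COLUMNS:
            bad = (obs[col] < 0) | (obs[col] > HANG_MAX_SECONDS) | obs[col].isna()
            if bad.any():
                raise CohortValidationError(
                    f"observations: {col} outside [0, {HANG_MAX_SECONDS:g}] s "
                    f"at rows {_rows(bad)}"
                )
        for col in ORDINAL_FACTORS:
            bad = ~obs[col].isin(ORDINAL_LEVELS)
            if bad.any():
                raise CohortValidationError(
                    f"observations: {col} not in {{0, 0.5, 1}} at rows {_rows(bad)}"
                )

        counts = surv["mouse_id"].value_counts()
        if (counts != 1).any() or len(counts) != len(known):
            raise CohortValidationError(
                "survival: exactly one outcome per mouse required"
            )
        if not surv["event"].isin([0, 1]).all():
            raise CohortValidationError("survival: event flag must be 0 or 1")

        # no observation may post-date its mouse's survival time
        merged = obs.merge(surv[["mouse_id", "time"]], on="mouse_id", how="left")
        bad = merged["week"] > merged["time"]
        if bad.any():
            raise CohortValidationError(
                f"observations: week beyond survival time at rows {_rows(bad)}"
            )
        first_week = obs.groupby("mouse_id")["week"].min()
        merged = surv.merge(
            first_week.rename("first_week"), left_on="mouse_id", right_index=True
        )
        bad = merged["time"] < merged["first_week"]
        if bad.any():
            raise CohortValidationError(
                f"survival: time before first observed week at rows {_rows(bad)}"
            )

        if self.muscle is not None:
            _require_columns(self.muscle, MUSCLE_COLUMNS, "muscle")
            bad = ~self.muscle["mouse_id"].isin(known)
            if bad.any():
                raise CohortValidationError(
                    f"muscle: unknown mouse_id at rows {_rows(bad)}"
                )
            for col in ("ta_mass", "gas_mass", "quad_mass", "min_feret"):
                bad = ~(self.muscle[col] > 0)
                if bad.any():
                    raise CohortValidationError(
                        f"muscle: non-positive {col} at rows {_rows(bad)}"
                    )
            pct = self.muscle["pct_mispositioned_nuclei"]
            bad = (pct < 0) | (pct > 100)
            if bad.any():
                raise CohortValidationError(
                    f"muscle: pct_mispositioned_nuclei outside [0, 100] "
                    f"at rows {_rows(bad)}"
                )
        return self

    # -- convenience ----------------------------------------------------
    @property
    def n_mice(self) -> int:
        return len(self.mice)

    def mean_hang(self) -> pd.DataFrame:
        """Per mouse-week mean of the three hanging trials (s)."""
        out = self.observations[["mouse_id", "week"]].copy()
        out["mean_hang"] = self.observations[HANG_COLUMNS].mean(axis=1)
        return out

    def arm_subset(self, arm: str) -> "CohortDataset":
        """Restrict the cohort to a single dose arm."""
        keep = self.mice.loc[self.mice["arm"] == arm, "mouse_id"]
        ids = set(keep)
        muscle = None
        if self.muscle is not None:
            muscle = self.muscle[self.muscle["mouse_id"].isin(ids)].reset_index(
                drop=True
            )
        return CohortDataset(
            mice=self.mice[self.mice["mouse_id"].isin(ids)].reset_index(drop=True),
            observations=self.observations[
                self.observations["mouse_id"].isin(ids)
            ].reset_index(drop=True),
            survival=self.survival[self.survival["mouse_id"].isin(ids)].reset_index(
                drop=True
            ),
            muscle=muscle,
            provenance={**self.provenance, "subset_arm": arm},
        )

    def equals(self, other: "CohortDataset") -> bool:
        same = (
            self.mice.reset_index(drop=True).equals(other.mice.reset_index(drop=True))
            and self.observations.reset_index(drop=True).equals(
                other.observations.reset_index(drop=True)
            )
            and self.survival.reset_index(drop=True).equals(
                other.survival.reset_index(drop=True)
            )
        )
        if self.muscle is None or other.muscle is None:
            return same and (self.muscle is None) == (other.muscle is None)
        return same and self.muscle.reset_index(drop=True).equals(
            other.muscle.reset_index(drop=True)
        )

    # -- serialization --------------------------------------------------
    def write(self, directory: str | Path) -> Path:
        return write_cohort(self, directory)

    @classmethod
    def read(cls, directory: str | Path) -> "CohortDataset":
        return read_cohort(directory)


def write_cohort(dataset: CohortDataset, directory: str | Path) -> Path:
    """Write a cohort as CSV tables + a YAML provenance sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dataset.mice.to_csv(directory / "mice.csv", index=False)
    dataset.observations.to_csv(directory / "observations.csv", index=False)
    dataset.survival.to_csv(directory / "survival.csv", index=False)
    if dataset.muscle is not None:
        dataset.muscle.to_csv(directory / "muscle.csv", index=False)
    with open(directory / "provenance.yaml", "w") as fh:
        yaml.safe_dump(dataset.provenance or {"source": "imported"}, fh)
    return directory


def read_cohort(directory: str | Path) -> CohortDataset:
    """Load and validate a cohort written by :func:`write_cohort`.

    ``observations.csv`` and ``survival.csv`` are required; ``mice.csv``
    and ``muscle.csv`` are optional (mice metadata is reconstructed from the
    survival table when absent).
    """
    directory = Path(directory)
    obs_path = directory / "observations.csv"
    surv_path = directory / "survival.csv"
    for p in (obs_path, surv_path):
        if not p.exists():
            raise CohortValidationError(f"missing required file: {p}")
    observations = pd.read_csv(obs_path, float_precision="round_trip")
    survival = pd.read_csv(surv_path, float_precision="round_trip")
    mice_path = directory / "mice.csv"
    if mice_path.exists():
        mice = pd.read_csv(mice_path, float_precision="round_trip")
    else:
        mice = pd.DataFrame(
            {
                "mouse_id": survival["mouse_id"],
                "genotype": "unknown",
                "arm": "untreated",
                "treatment_start_week": np.nan,
            }
        )
    muscle_path = directory / "muscle.csv"
    muscle = (
        pd.read_csv(muscle_path, float_precision="round_trip")
        if muscle_path.exists()
        else None
    )
    prov_path = directory / "provenance.yaml"
    provenance = {}
    if prov_path.exists():
        with open(prov_path) as fh:
            provenance = yaml.safe_load(fh) or {}
    return CohortDataset(
        mice=mice,
        observations=observations,
        survival=survival,
        muscle=muscle,
        provenance=provenance,
    )
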