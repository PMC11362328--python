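"""Two-level data container shared by all estimators.

Long-format level-1 records (person id, occasion, repeated measures) plus a
person-level table with the level-2 outcome ``z``.  Optionally carries the
latent truth (person means, random slopes) retained by the simulator so that
oracle tests can compare estimates against the generating values; estimators
never read the truth block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

L1_COLUMNS = ("id", "t", "x", "u", "y", "v")
L2_COLUMNS = ("id", "z")


@dataclass
class TwoLevelData:
    """Repeated-measures data with a person-level outcome.

    Parameters
    ----------
    level1 : pandas.DataFrame
        Columns ``id``, ``t``, ``x``, ``y`` and, for designs with two
        within-person associations, ``u`` and ``v``.
    level2 : pandas.DataFrame
        Columns ``id`` and ``z`` (one row per person).
    truth : pandas.DataFrame, optional
        Per-person latent values (``beta_y``, ``x_b``, ``y_b`` and the
        u/v analogues) kept for oracle checks only.
    """

    level1: pd.DataFrame
    level2: pd.DataFrame
    truth: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        for col in ("id", "t", "x", "y"):
            if col not in self.level1.columns:
                raise ValueError(f"level1 is missing required column {col!r}")
        for col in L2_COLUMNS:
            if col not in self.level2.columns:
                raise ValueError(f"level2 is missing required column {col!r}")
        ids2 = self.level2["id"].to_numpy()
        if len(np.unique(ids2)) != len(ids2):
            raise ValueError("duplicate person ids in level2")
        ids1 = np.unique(self.level1["id"].to_numpy())
        if not np.isin(ids1, ids2).all():
            raise ValueError("level1 contains person ids absent from level2")
        counts = self.level1.groupby("id").size()
        if (counts < 2).any():
            raise ValueError("every person needs at least two occasions")

    @property
    def bivariate(self) -> bool:
        """Whether the data carry the second (u, v) variable pair."""
        return "u" in self.level1.columns and "v" in self.level1.columns

    @property
    def n_persons(self) -> int:
        return len(self.level2)

    def occasion_counts(self) -> pd.Series:
        return self.level1.groupby("id").size()

    # -- round trips -------------------------------------------------------

    def to_csv(self, directory: str | Path, prefix: str = "data") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.level1.to_csv(directory / f"{prefix}_level1.csv", index=False)
        self.level2.to_csv(directory / f"{prefix}_level2.csv", index=False)
        if self.truth is not None:
            self.truth.to_csv(directory / f"{prefix}_truth.csv", index=False)

    @classmethod
    def from_csv(cls, directory: str | Path, prefix: str = "data") -> "TwoLevelData":
        directory = Path(directory)
        level1 = pd.read_csv(directory / f"{prefix}_level1.csv")
        level2 = pd.read_csv(directory / f"{prefix}_level2.csv")
        truth_path = directory / f"{prefix}_truth.csv"
        truth = pd.read_csv(truth_path) if truth_path.exists() else None
        return cls(level1=level1, level2=level2, truth=truth)
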