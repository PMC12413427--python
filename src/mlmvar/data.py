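"""Long-format panel container for intensive-longitudinal data.

Observations live on an equidistant occasion grid per person.  Rows where
the preceding grid occasion is absent or belongs to a different day/wave
segment carry ``lag_valid = False``: the dynamic (lagged) part of the
model is skipped there, which is how overnight and between-wave gaps are
kept out of the AR/CR estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PanelFormatError
from .modelspec import ModelSpec

ID_COLS = ["person", "day", "occasion", "lag_valid"]


def y_column_names(spec: ModelSpec) -> list[str]:
    cols = []
    for c in spec.constructs:
        for p in range(c.n_indicators):
            cols.append(f"y_{c.name}_{p + 1}")
    return cols


@dataclass
class PanelData:
    """Validated long-format panel.

    ``df`` has columns ``person``, ``day``, ``occasion``, ``lag_valid`` and
    one ``y_<construct>_<indicator>`` column per observed variable, with
    ``NaN`` as the explicit missing marker.  ``latent_truth`` optionally
    stores the generating latent states/person parameters for recovery
    scoring.
    """

    df: pd.DataFrame
    y_columns: dict[str, list[str]]
    latent_truth: dict | None = None

    def __post_init__(self):
        self.validate()

    # ------------------------------------------------------------------
    @property
    def persons(self) -> np.ndarray:
        return self.df["person"].unique()

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    @property
    def all_y_columns(self) -> list[str]:
        return [c for cols in self.y_columns.values() for c in cols]

    def validate(self) -> None:
        for col in ("person", "occasion", "lag_valid"):
            if col not in self.df.columns:
                raise PanelFormatError(f"missing required column {col!r}")
        if "day" not in self.df.columns:
            self.df = self.df.assign(day=0)
        for cols in self.y_columns.values():
            for c in cols:
                if c not in self.df.columns:
                    raise PanelFormatError(f"missing indicator column {c!r}")
        dup = self.df.duplicated(subset=["person", "occasion"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            raise PanelFormatError(f"duplicate (person, occasion) at row {row}")
        occ = self.df.groupby("person", sort=False)["occasion"]
        bad = occ.apply(lambda s: bool((np.diff(s.to_numpy()) <= 0).any()))
        if bad.any():
            person = bad[bad].index[0]
            raise PanelFormatError(
                f"occasions not strictly increasing for person {person!r}"
            )

    # ------------------------------------------------------------------
    def to_arrays(self, spec: ModelSpec):
        """Dense (N, T_max, ...) arrays for vectorized computation.

        Returns a dict with ``y`` (N, T, P; NaN where missing or padded),
        ``present`` (row exists on the grid), ``lag_valid`` and
        ``person_index`` (person labels in array order).  Indicator columns
        are ordered construct-by-construct following ``spec``.
        """
        cols = y_column_names(spec)
        for c in cols:
            if c not in self.df.columns:
                raise PanelFormatError(
                    f"panel lacks column {c!r} required by the model spec"
                )
        persons = self.persons
        sizes = self.df.groupby("person", sort=False).size()
        T = int(sizes.max())
        N, P = len(persons), len(cols)
        y = np.full((N, T, P), np.nan)
        present = np.zeros((N, T), dtype=bool)
        lag_valid = np.zeros((N, T), dtype=bool)
        for i, pid in enumerate(persons):
            sub = self.df[self.df["person"] == pid]
            n = len(sub)
            y[i, :n] = sub[cols].to_numpy(dtype=float)
            present[i, :n] = True
            lag_valid[i, :n] = sub["lag_valid"].to_numpy(dtype=bool)
        lag_valid[:, 0] = False
        return {
            "y": y,
            "present": present,
            "lag_valid": lag_valid,
            "person_index": persons,
        }

    # ------------------------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        spec: ModelSpec,
        y: np.ndarray,
        lag_valid: np.ndarray,
        day: np.ndarray | None = None,
        latent_truth: dict | None = None,
    ) -> "PanelData":
        N, T, P = y.shape
        cols = y_column_names(spec)
        assert P == len(cols)
        person = np.repeat(np.arange(N), T)
        occasion = np.tile(np.arange(T), N)
        if day is None:
            day_arr = np.zeros(N * T, dtype=int)
        else:
            day_arr = np.tile(np.asarray(day, dtype=int), N)
        df = pd.DataFrame({"person": person, "day": day_arr, "occasion": occasion})
        df["lag_valid"] = lag_valid.reshape(-1)
        for j, c in enumerate(cols):
            df[c] = y[:, :, j].reshape(-1)
        y_columns = {
            c.name: [f"y_{c.name}_{p + 1}" for p in range(c.n_indicators)]
            for c in spec.constructs
        }
        return cls(df=df, y_columns=y_columns, latent_truth=latent_truth)
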