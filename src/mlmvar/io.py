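"""Reading/writing long-format panels and building occasion grids.

Ambulatory-assessment protocols sample several beeps per day, often over
several days and possibly several waves.  ``gridify`` maps raw rows onto
the full equidistant grid implied by such a template, inserting
fully-missing rows for skipped beeps and flagging the first beep of every
day/wave segment with ``lag_valid = False`` so that no lagged effect is
estimated across nights or waves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import PanelData
from .errors import PanelFormatError

__all__ = ["PanelSchema", "GridTemplate", "read_panel", "write_panel", "gridify"]


@dataclass
class PanelSchema:
    """Column mapping for raw CSV input.

    ``y_columns`` maps construct name -> list of indicator columns; when
    None, every column starting with ``y_`` is treated as an indicator of
    the construct named between the first and last underscore
    (``y_<construct>_<indicator>``).
    """

    person: str = "person"
    day: str = "day"
    occasion: str = "occasion"
    lag_valid: str | None = "lag_valid"
    y_columns: dict[str, list[str]] | None = None
    missing: str | float = ""


def _infer_y_columns(columns) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for c in columns:
        if not c.startswith("y_"):
            continue
        stem = c[2:]
        construct = stem.rsplit("_", 1)[0] if "_" in stem else stem
        out.setdefault(construct, []).append(c)
    if not out:
        raise PanelFormatError("no y_<construct>_<indicator> columns found")
    return out


def read_panel(path, schema: PanelSchema | None = None) -> PanelData:
    """Read a long-format CSV into a validated :class:`PanelData`.

    Values equal to the schema's missing marker (or empty cells) become
    NaN.  Duplicate (person, occasion) pairs and non-monotone occasion
    indices are rejected with the offending row/person named.
    """
    schema = schema or PanelSchema()
    df = pd.read_csv(path, na_values=[schema.missing] if schema.missing != "" else None)
    rename = {schema.person: "person", schema.occasion: "occasion"}
    if schema.day in df.columns:
        rename[schema.day] = "day"
    df = df.rename(columns=rename)
    if "day" not in df.columns:
        df["day"] = 0
    y_columns = schema.y_columns or _infer_y_columns(df.columns)
    for cols in y_columns.values():
        for c in cols:
            df[c] = pd.to_numeric(df[c], errors="coerce")
    if schema.lag_valid and schema.lag_valid in df.columns:
        df["lag_valid"] = df[schema.lag_valid].astype(bool)
    else:
        df = _default_lag_valid(df)
    return PanelData(df=df, y_columns=y_columns)


def _default_lag_valid(df: pd.DataFrame) -> pd.DataFrame:
    df = df.sort_values(["person", "occasion"], kind="stable").reset_index(drop=True)
    prev_occ = df.groupby("person")["occasion"].shift(1)
    prev_day = df.groupby("person")["day"].shift(1)
    df["lag_valid"] = (df["occasion"] - prev_occ == 1) & (df["day"] == prev_day)
    return df


def write_panel(panel: PanelData, path, truth_path=None) -> None:
    """Write the long CSV; optionally a truth sidecar (latent states)."""
    panel.df.to_csv(path, index=False)
    if truth_path is not None and panel.latent_truth is not None:
        truth = panel.latent_truth
        eta = truth["eta_w"]  # (N, T, Q)
        N, T, Q = eta.shape
        rec = {
            "person": np.repeat(np.arange(N), T),
            "occasion": np.tile(np.arange(T), N),
        }
        for q in range(Q):
            rec[f"eta_w_{q + 1}"] = eta[:, :, q].reshape(-1)
        pd.DataFrame(rec).to_csv(truth_path, index=False)


@dataclass
class GridTemplate:
    """Equidistant occasion grid: waves x days x beeps per day.

    Lags are always broken at day starts and (hence) across waves.
    """

    beeps_per_day: int
    days: int = 1
    waves: int = 1

    @property
    def n_occasions(self) -> int:
        return self.beeps_per_day * self.days * self.waves

    def day_of_occasion(self) -> np.ndarray:
        """Global day index (0 .. waves*days-1) of each grid occasion."""
        return np.repeat(np.arange(self.days * self.waves), self.beeps_per_day)

    def lag_valid_template(self) -> np.ndarray:
        day = self.day_of_occasion()
        lv = np.ones(self.n_occasions, dtype=bool)
        lv[0] = False
        lv[1:] = day[1:] == day[:-1]
        return lv


def gridify(panel: PanelData, template: GridTemplate) -> PanelData:
    """Expand a panel onto the full template grid.

    Every person ends up with exactly ``template.n_occasions`` rows;
    occasions absent from the input become fully missing rows.  The
    ``lag_valid`` flag is recomputed from the template (False at the first
    beep of each day segment).  Observations whose occasion index falls
    outside the template raise an error.
    """
    n_occ = template.n_occasions
    occ_max = panel.df["occasion"].max()
    if occ_max >= n_occ:
        raise PanelFormatError(
            f"occasion {occ_max} outside template grid of {n_occ} occasions"
        )
    day = template.day_of_occasion()
    lv = template.lag_valid_template()
    ycols = panel.all_y_columns
    frames = []
    for pid, sub in panel.df.groupby("person", sort=False):
        full = pd.DataFrame(
            {"person": pid, "day": day, "occasion": np.arange(n_occ), "lag_valid": lv}
        )
        full = full.merge(
            sub[["occasion"] + ycols], on="occasion", how="left", validate="1:1"
        )
        frames.append(full)
    df = pd.concat(frames, ignore_index=True)
    return PanelData(df=df, y_columns=panel.y_columns, latent_truth=panel.latent_truth)
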