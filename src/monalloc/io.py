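"""Long-format observation tables: validation, reading and writing.

The one wire format of the toolkit is a tidy delimited-text table with the
five columns ``station_id, day, depth_m, variable, value`` — one row per
sensor reading.  Vertical casts, surface-band means and fitted extinction
coefficients all fit this schema, so a single reader covers the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ObservationError
from .profiles import Cast, LightProfile

__all__ = ["ObservationSet", "read_observations", "write_observations", "REQUIRED_COLUMNS"]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("station_id", "day", "depth_m", "variable", "value")
_KEY = ["station_id", "day", "depth_m", "variable"]


@dataclass
class ObservationSet:
    """Validated long-format observations plus provenance metadata.

    ``data`` holds one row per (station, day, depth, variable) key;
    ``vocabulary`` is the declared set of variable names; ``provenance``
    records the source file or generator seed.
    """

    data: pd.DataFrame
    vocabulary: tuple[str, ...] = ()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ObservationError(f"missing required columns: {missing}")
        df = df[list(REQUIRED_COLUMNS)].copy()
        for col in ("day", "depth_m", "value"):
            if not pd.api.types.is_numeric_dtype(df[col]):
                raise ObservationError(f"column {col!r} must be numeric")
        if ((df["day"] < 1) | (df["day"] > 366)).any():
            bad = df.loc[(df["day"] < 1) | (df["day"] > 366), "day"].unique()
            raise ObservationError(f"day-of-year values outside [1, 366]: {sorted(bad)[:5]}")
        dup = df.duplicated(subset=_KEY)
        if dup.any():
            rows = df.index[dup][:5].tolist()
            raise ObservationError(
                f"duplicate (station, day, depth, variable) keys at rows {rows}"
            )
        if (df["depth_m"] < 0).any():
            logger.warning("negative depths present; check depth units/sign")
        if not self.vocabulary:
            self.vocabulary = tuple(sorted(df["variable"].unique()))
        else:
            unknown = set(df["variable"].unique()) - set(self.vocabulary)
            if unknown:
                raise ObservationError(f"variables outside declared vocabulary: {sorted(unknown)}")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def variables(self) -> tuple[str, ...]:
        return self.vocabulary

    @property
    def stations(self) -> list[str]:
        return sorted(self.data["station_id"].astype(str).unique())

    @property
    def days(self) -> list[float]:
        return sorted(self.data["day"].unique())

    def casts(self, variable: str):
        """Yield one :class:`Cast` per (station, day) holding that variable."""
        sub = self.data[self.data["variable"] == variable]
        for (station, day), grp in sub.groupby(["station_id", "day"], sort=True):
            samples = tuple(
                (float(r.depth_m), variable, float(r.value)) for r in grp.itertuples()
            )
            yield Cast(station_id=str(station), day=float(day), samples=samples)

    def light_profiles(self, variable: str = "par"):
        """Yield one :class:`LightProfile` per (station, day) for the PAR variable."""
        sub = self.data[self.data["variable"] == variable]
        for (station, day), grp in sub.groupby(["station_id", "day"], sort=True):
            grp = grp.sort_values("depth_m")
            yield LightProfile(
                station_id=str(station),
                day=float(day),
                depths=grp["depth_m"].to_numpy(),
                irradiance=grp["value"].to_numpy(),
            )


def read_observations(path, delimiter: str = ",") -> ObservationSet:
    """Read and validate a long-format observation file.

    Hard errors (missing columns, unparseable numerics, duplicate keys) carry
    the file location; soft unit oddities are logged as warnings.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, delimiter=delimiter)
    except ValueError as exc:
        raise ObservationError(f"{path}: cannot parse: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ObservationError(f"{path}: missing columns {missing}")
    for col in ("day", "depth_m", "value"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            # +2: header line plus 1-based numbering
            lines = (df.index[bad][:5] + 2).tolist()
            raise ObservationError(f"{path}: unparseable numeric in {col!r} at lines {lines}")
        df[col] = converted
    dup = df.duplicated(subset=_KEY)
    if dup.any():
        lines = (df.index[dup][:5] + 2).tolist()
        raise ObservationError(f"{path}: duplicate observation keys at lines {lines}")
    return ObservationSet(data=df, provenance={"source": str(path)})


def write_observations(obs: ObservationSet, path, delimiter: str = ",") -> None:
    """Write the observation table as delimited text (round-trips with the reader)."""
    obs.data.to_csv(path, sep=delimiter, index=False)
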