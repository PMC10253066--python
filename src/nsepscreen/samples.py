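"""Per-cell fluorescence records and per-sample containers.

A *sample* is one electroporation cuvette (or its sham-exposed twin) imaged
in one well: a set of cells, each with a nuclear-marker (Hoechst) intensity
and an integrated Yo-Pro-1 (YP) fluorescence. Samples are keyed by
experiment (day), plate (the group of variants processed together),
variant (KO gene or scrambled control) and condition (exposed | sham).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("exposed", "sham")

#: Column order of the long-format per-cell table used on disk.
CELL_TABLE_COLUMNS = [
    "experiment",
    "plate",
    "variant",
    "condition",
    "cell_id",
    "hoechst",
    "yp",
]


class CellRecord(NamedTuple):
    """One identified cell: nuclear-marker intensity and integrated YP."""

    cell_id: int
    hoechst: float
    yp: float


@dataclass
class SampleMeasurement:
    """All cells measured in one cuvette/well.

    Parameters
    ----------
    experiment, plate, variant : str
        Identifiers; ``(variant, condition, experiment)`` is unique within
        a screen.
    condition : str
        ``"exposed"`` (pulsed) or ``"sham"`` (handled identically, no pulses).
    yp : ndarray
        Integrated YP fluorescence per cell (arbitrary units).
    hoechst : ndarray, optional
        Nuclear-marker intensity per cell; used only for bookkeeping.
    """

    experiment: str
    plate: str
    variant: str
    condition: str
    yp: np.ndarray
    hoechst: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        self.yp = np.asarray(self.yp, dtype=float)
        if self.yp.ndim != 1 or self.yp.size < 1:
            raise ValueError("a sample needs at least one cell")
        if self.hoechst is not None:
            self.hoechst = np.asarray(self.hoechst, dtype=float)
            if self.hoechst.shape != self.yp.shape:
                raise ValueError("hoechst and yp must have the same length")

    @property
    def n_cells(self) -> int:
        return int(self.yp.size)

    def cells(self) -> list[CellRecord]:
        hoechst = (
            self.hoechst
            if self.hoechst is not None
            else np.full_like(self.yp, np.nan)
        )
        return [
            CellRecord(i, float(h), float(y))
            for i, (h, y) in enumerate(zip(hoechst, self.yp))
        ]

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.variant, self.condition, self.experiment)


def samples_to_frame(samples: Iterable[SampleMeasurement]) -> pd.DataFrame:
    """Flatten samples into the long-format per-cell table."""
    chunks = []
    for s in samples:
        hoechst = s.hoechst if s.hoechst is not None else np.full(s.n_cells, np.nan)
        chunks.append(
            pd.DataFrame(
                {
                    "experiment": s.experiment,
                    "plate": s.plate,
                    "variant": s.variant,
                    "condition": s.condition,
                    "cell_id": np.arange(s.n_cells),
                    "hoechst": hoechst,
                    "yp": s.yp,
                }
            )
        )
    if not chunks:
        return pd.DataFrame(columns=CELL_TABLE_COLUMNS)
    return pd.concat(chunks, ignore_index=True)[CELL_TABLE_COLUMNS]


def frame_to_samples(df: pd.DataFrame) -> list[SampleMeasurement]:
    """Group a long-format per-cell table back into samples."""
    missing = set(CELL_TABLE_COLUMNS[:4] + ["yp"]) - set(df.columns)
    if missing:
        raise ValueError(f"cell table is missing columns: {sorted(missing)}")
    out = []
    keys = ["experiment", "plate", "variant", "condition"]
    for (exp, plate, variant, cond), grp in df.groupby(keys, sort=True):
        out.append(
            SampleMeasurement(
                experiment=str(exp),
                plate=str(plate),
                variant=str(variant),
                condition=str(cond),
                yp=grp["yp"].to_numpy(),
                hoechst=grp["hoechst"].to_numpy() if "hoechst" in grp else None,
            )
        )
    return out


def write_cell_table(samples: Sequence[SampleMeasurement] | pd.DataFrame, path) -> None:
    df = samples if isinstance(samples, pd.DataFrame) else samples_to_frame(samples)
    df.to_csv(path, sep="\t", index=False)


def read_cell_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
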