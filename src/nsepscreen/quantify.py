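"""Per-sample summaries, sham-corrected ΔF, plate normalization, pooling.

The quantification chain is:

1. summarize each sample's per-cell YP values (mean or median);
2. ΔF = exposed summary − matched sham summary, per variant and experiment,
   removing "spontaneous" dye uptake;
3. normalize all ΔF within a (plate, experiment) group to the mean ΔF of
   the scrambled-control (SCR) samples, taken as 100% — this cancels
   day-to-day plate gain;
4. pool normalized ΔF across experiments per variant into a mean ΔF̄ and
   its squared standard error S².

Both the mean and the median per-cell metric run through the identical
chain; the median is robust to the rare very bright (dead) cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .samples import SampleMeasurement

METRICS = ("mean", "median")

DEFAULT_SCR_PREFIX = "SCR"


class PlateNormalizationError(ValueError):
    """SCR mean ΔF non-positive: percent-of-control is undefined."""


@dataclass(frozen=True)
class DeltaF:
    """Sham-corrected fluorescence change for one variant in one experiment."""

    variant: str
    experiment: str
    plate: str
    metric: str
    value: float
    normalized: float | None = None
    #: distinguishes multiple SCR samples of one variant id, if any
    replicate: int = 0


@dataclass(frozen=True)
class VariantPooled:
    """Normalized ΔF pooled across experiments for one variant.

    ``sem2`` is the squared standard error of the pooled mean: the sample
    variance of the per-replicate normalized values divided by their
    number. It is the S² entering the SSMD.
    """

    variant: str
    metric: str
    mean: float
    sem2: float
    n: int
    values: tuple[float, ...] = ()

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("pooling requires >= 2 replicates")


def summarize_sample(
    sample: SampleMeasurement | np.ndarray | Sequence[float], metric: str
) -> float:
    """Mean or median of per-cell YP fluorescence for one sample."""
    values = sample.yp if isinstance(sample, SampleMeasurement) else np.asarray(
        sample, dtype=float
    )
    if values.size == 0:
        raise ValueError("cannot summarize an empty cell list")
    if metric == "mean":
        return float(np.mean(values))
    if metric == "median":
        return float(np.median(values))
    raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")


def delta_f(
    exposed: SampleMeasurement, sham: SampleMeasurement, metric: str
) -> DeltaF:
    """ΔF = summary(exposed) − summary(sham) for one matched cuvette pair."""
    if exposed.condition != "exposed" or sham.condition != "sham":
        raise ValueError("arguments must be (exposed, sham) in that order")
    if (exposed.variant, exposed.experiment) != (sham.variant, sham.experiment):
        raise ValueError(
            "exposed and sham samples must share variant and experiment"
        )
    value = summarize_sample(exposed, metric) - summarize_sample(sham, metric)
    return DeltaF(
        variant=exposed.variant,
        experiment=exposed.experiment,
        plate=exposed.plate,
        metric=metric,
        value=value,
    )


def normalize_plate(
    deltas: Sequence[DeltaF], scr_ids: Iterable[str]
) -> list[DeltaF]:
    """Express each ΔF as percent of the SCR mean ΔF of its group.

    ``deltas`` must all belong to one (plate, experiment, metric) group.
    By construction the mean of the normalized SCR values is exactly 100.
    """
    scr_ids = set(scr_ids)
    if not deltas:
        return []
    groups = {(d.plate, d.experiment, d.metric) for d in deltas}
    if len(groups) > 1:
        raise ValueError(
            "normalize_plate expects a single (plate, experiment, metric) "
            f"group, got {sorted(groups)}"
        )
    scr_values = [d.value for d in deltas if d.variant in scr_ids]
    if not scr_values:
        raise PlateNormalizationError("no SCR ΔF values in this group")
    scr_mean = float(np.mean(scr_values))
    if scr_mean <= 0:
        raise PlateNormalizationError(
            f"SCR mean ΔF is {scr_mean:.3g} <= 0; percent-of-control undefined"
        )
    return [replace(d, normalized=100.0 * d.value / scr_mean) for d in deltas]


def pool_variant(norm_deltas: Sequence[DeltaF], metric: str) -> VariantPooled:
    """Pool one variant's normalized ΔF values across experiments."""
    ds = [d for d in norm_deltas if d.metric == metric]
    if not ds:
        raise ValueError(f"no ΔF values with metric {metric!r}")
    variants = {d.variant for d in ds}
    if len(variants) > 1:
        raise ValueError(f"mixed variants in pool: {sorted(variants)}")
    values = np.array([d.normalized for d in ds], dtype=float)
    if np.any(np.isnan(values)):
        raise ValueError("pool_variant requires normalized ΔF values")
    if values.size < 2:
        raise ValueError("pooling requires >= 2 experiments")
    mean = float(np.mean(values))
    sem2 = float(np.var(values, ddof=1) / values.size)
    return VariantPooled(
        variant=variants.pop(),
        metric=metric,
        mean=mean,
        sem2=sem2,
        n=int(values.size),
        values=tuple(values),
    )


# ---------------------------------------------------------------------------
# screen-level (table) pipeline


def _pair_samples(
    samples: Sequence[SampleMeasurement],
) -> list[tuple[SampleMeasurement, SampleMeasurement]]:
    exposed: dict[tuple, list[SampleMeasurement]] = {}
    sham: dict[tuple, list[SampleMeasurement]] = {}
    for s in samples:
        key = (s.experiment, s.plate, s.variant)
        (exposed if s.condition == "exposed" else sham).setdefault(key, []).append(s)
    pairs = []
    for key, exp_list in sorted(exposed.items()):
        sham_list = sham.get(key)
        if not sham_list:
            raise ValueError(f"exposed sample without sham twin: {key}")
        if len(exp_list) != len(sham_list):
            raise ValueError(f"unpaired exposed/sham counts for {key}")
        pairs.extend(zip(exp_list, sham_list))
    return pairs


def compute_normalized_deltas(
    samples: Sequence[SampleMeasurement] | pd.DataFrame,
    scr_ids: Iterable[str] | None = None,
    metrics: Sequence[str] = METRICS,
) -> pd.DataFrame:
    """Full ΔF + per-(plate, experiment) normalization over a screen.

    Accepts either a list of samples or the long-format per-cell table.
    Variants whose id starts with ``"SCR"`` are treated as controls when
    ``scr_ids`` is not given. Groups whose SCR mean ΔF is non-positive are
    dropped with a warning.

    Returns a tidy frame with columns
    ``experiment, plate, variant, metric, replicate, delta_f, normalized, is_scr``.
    """
    if isinstance(samples, pd.DataFrame):
        from .samples import frame_to_samples

        samples = frame_to_samples(samples)
    if scr_ids is None:
        scr_ids = {
            s.variant
            for s in samples
            if s.variant.startswith(DEFAULT_SCR_PREFIX)
        }
    scr_ids = set(scr_ids)

    deltas: list[DeltaF] = []
    pair_index: dict[tuple, int] = {}
    for exp_s, sham_s in _pair_samples(samples):
        key = (exp_s.experiment, exp_s.plate, exp_s.variant)
        rep = pair_index.get(key, 0)
        pair_index[key] = rep + 1
        for metric in metrics:
            deltas.append(replace(delta_f(exp_s, sham_s, metric), replicate=rep))

    rows = []
    by_group: dict[tuple, list[DeltaF]] = {}
    for d in deltas:
        by_group.setdefault((d.plate, d.experiment, d.metric), []).append(d)
    for key in sorted(by_group):
        try:
            normalized = normalize_plate(by_group[key], scr_ids)
        except PlateNormalizationError as err:
            warnings.warn(
                f"plate group {key} excluded from analysis: {err}",
                stacklevel=2,
            )
            continue
        rows.extend(normalized)

    return pd.DataFrame(
        {
            "experiment": [d.experiment for d in rows],
            "plate": [d.plate for d in rows],
            "variant": [d.variant for d in rows],
            "metric": [d.metric for d in rows],
            "replicate": [d.replicate for d in rows],
            "delta_f": [d.value for d in rows],
            "normalized": [d.normalized for d in rows],
            "is_scr": [d.variant in scr_ids for d in rows],
        }
    )


def pool_screen(norm_df: pd.DataFrame) -> pd.DataFrame:
    """Pool normalized ΔF per (variant, metric) across experiments."""
    out = []
    for (variant, metric), grp in norm_df.groupby(["variant", "metric"]):
        values = grp["normalized"].to_numpy(dtype=float)
        if values.size < 2:
            continue
        out.append(
            {
                "variant": variant,
                "metric": metric,
                "plate": grp["plate"].iloc[0],
                "is_scr": bool(grp["is_scr"].iloc[0]),
                "delta_f_mean": float(np.mean(values)),
                "sem2": float(np.var(values, ddof=1) / values.size),
                "n": int(values.size),
            }
        )
    return pd.DataFrame(out)


def scr_control_group(norm_df: pd.DataFrame, plate: str, metric: str) -> np.ndarray:
    """Normalized ΔF of every individual SCR sample in one plate group.

    All SCR samples across experiments form the shared control group for
    SSMD and Dunnett statistics; their mean is 100 by construction.
    """
    mask = (
        (norm_df["plate"] == plate)
        & (norm_df["metric"] == metric)
        & norm_df["is_scr"]
    )
    return norm_df.loc[mask, "normalized"].to_numpy(dtype=float)
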