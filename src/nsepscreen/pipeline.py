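"""End-to-end screen analysis: cells → normalized ΔF → SSMD/Dunnett → hits.

One plate group (the 15–20 KO variants processed together with their 2–4
SCR controls) forms one Dunnett family per metric; the control group pools
the normalized ΔF of every individual SCR sample on the plate across
experiments (its mean is 100 by construction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .quantify import (
    METRICS,
    VariantPooled,
    compute_normalized_deltas,
    pool_screen,
    scr_control_group,
)
from .samples import SampleMeasurement
from .stats import (
    ScreenSummary,
    VariantStats,
    classify_hits,
    combine_metric_calls,
    dunnett_test,
    screen_summary,
    ssmd,
)

STATS_COLUMNS = [
    "variant",
    "plate",
    "metric",
    "n",
    "delta_f_mean",
    "sem",
    "ssmd",
    "dunnett_t",
    "dunnett_p_adj",
    "hit_class",
]


@dataclass
class ScreenResult:
    """All per-variant outputs of one analyzed screen."""

    norm: pd.DataFrame  # per-experiment normalized ΔF
    pooled: pd.DataFrame  # per (variant, metric) pooled values
    stats: pd.DataFrame  # per (variant, metric) SSMD/Dunnett/hit class
    calls: pd.DataFrame  # per variant, combined over metrics
    summary: ScreenSummary
    variant_stats: list[VariantStats]

    def hits(self) -> pd.DataFrame:
        return self.calls[self.calls["hit_class"] != "none"]


def analyze_screen(
    samples: Sequence[SampleMeasurement] | pd.DataFrame,
    scr_ids: Iterable[str] | None = None,
    alpha: float = 0.05,
    ssmd_thresh: float = 1.0,
    metrics: Sequence[str] = METRICS,
) -> ScreenResult:
    """Run the full quantification + hit-calling chain on one screen.

    ``samples`` is either a list of :class:`SampleMeasurement` or the
    long-format per-cell table. Variants whose id starts with ``"SCR"``
    are controls unless ``scr_ids`` is given explicitly.
    """
    norm = compute_normalized_deltas(samples, scr_ids=scr_ids, metrics=metrics)
    if norm.empty:
        raise ValueError("no analyzable plate groups in this screen")
    pooled_df = pool_screen(norm)

    all_stats: list[VariantStats] = []
    ko_pooled: list[VariantPooled] = []
    for (plate, metric), grp in pooled_df.groupby(["plate", "metric"]):
        kos = grp[~grp["is_scr"]]
        if kos.empty:
            continue
        control = scr_control_group(norm, plate, metric)
        scr_mean = float(np.mean(control))
        scr_sem2 = float(np.var(control, ddof=1) / control.size)
        ko_values = []
        for _, row in kos.iterrows():
            mask = (
                (norm["variant"] == row["variant"])
                & (norm["metric"] == metric)
            )
            ko_values.append(norm.loc[mask, "normalized"].to_numpy(dtype=float))
        dres = dunnett_test(ko_values, control)
        for (_, row), t, p in zip(kos.iterrows(), dres.statistic, dres.pvalue):
            vp = VariantPooled(
                variant=row["variant"],
                metric=metric,
                mean=row["delta_f_mean"],
                sem2=row["sem2"],
                n=int(row["n"]),
            )
            ko_pooled.append(vp)
            all_stats.append(
                VariantStats(
                    variant=row["variant"],
                    metric=metric,
                    delta_f_mean=row["delta_f_mean"],
                    sem2=row["sem2"],
                    n=int(row["n"]),
                    ssmd=ssmd(vp, scr_mean, scr_sem2=scr_sem2),
                    dunnett_t=float(t),
                    dunnett_p_adj=float(p),
                )
            )

    all_stats = classify_hits(all_stats, alpha=alpha, ssmd_thresh=ssmd_thresh)
    summary = screen_summary(
        ko_pooled, all_stats, alpha=alpha, ssmd_thresh=ssmd_thresh
    )
    calls = combine_metric_calls(all_stats)

    plate_of = dict(zip(pooled_df["variant"], pooled_df["plate"]))
    stats_df = pd.DataFrame(
        {
            "variant": [s.variant for s in all_stats],
            "plate": [plate_of[s.variant] for s in all_stats],
            "metric": [s.metric for s in all_stats],
            "n": [s.n for s in all_stats],
            "delta_f_mean": [s.delta_f_mean for s in all_stats],
            "sem": [float(np.sqrt(s.sem2)) for s in all_stats],
            "ssmd": [s.ssmd for s in all_stats],
            "dunnett_t": [s.dunnett_t for s in all_stats],
            "dunnett_p_adj": [s.dunnett_p_adj for s in all_stats],
            "hit_class": [s.hit_class for s in all_stats],
        }
    )[STATS_COLUMNS]
    calls_df = pd.DataFrame(
        {"variant": list(calls), "hit_class": list(calls.values())}
    ).sort_values("variant", ignore_index=True)
    return ScreenResult(
        norm=norm,
        pooled=pooled_df,
        stats=stats_df,
        calls=calls_df,
        summary=summary,
        variant_stats=all_stats,
    )
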