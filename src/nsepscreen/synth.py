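"""Synthetic arrayed-screen generator with known ground truth.

Emulates the statistical structure of an arrayed CRISPR-KO
electropermeabilization screen read out by Yo-Pro-1 (YP) uptake:

* per-cell baseline ("spontaneous") YP fluorescence drawn from a
  right-skewed, unimodal log-normal law;
* an exposure increment whose population mean grows linearly with pulse
  number up to ``linear_limit`` pulses and degrades into a broad
  high-variance mixture component above it (a proxy for cell swelling and
  membrane rupture at heavy doses);
* knockout effects acting multiplicatively on the increment, applied only
  to the edited fraction of cells (CRISPR mosaicism) — unedited cells
  respond like scrambled-control (SCR) cells;
* per-(experiment, plate) multiplicative scale factors (day-to-day gain);
* rare bright outlier cells (dead cells take up the dye regardless of
  exposure), present in both exposed and sham samples.

Every sample is drawn from its own seed substream, so individual samples
are reproducible independently of generation order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .samples import SampleMeasurement

_HOECHST_MEAN = 1000.0
_HOECHST_CV = 0.25

# Substream tags keeping sample, plate-scale and derived-seed draws disjoint.
_STREAM_SAMPLE = 1
_STREAM_SCALE = 2
_STREAM_SERIES = 3


def _lognormal(rng: np.random.Generator, mean, cv, size=None) -> np.ndarray:
    """Log-normal draws parametrized by arithmetic mean and CV.

    ``mean`` and ``cv`` may be arrays broadcastable to ``size``; entries with
    non-positive mean yield zeros (no increment).
    """
    mean = np.asarray(mean, dtype=float)
    cv = np.asarray(cv, dtype=float)
    if size is None:
        size = np.broadcast_shapes(mean.shape, cv.shape)
    positive = mean > 0
    sigma2 = np.log1p(np.square(cv))
    mu = np.log(np.where(positive, mean, 1.0)) - sigma2 / 2.0
    draws = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)
    return np.where(positive, draws, 0.0)


@dataclass
class GeneratorConfig:
    """Study-design and noise parameters of the simulated screen.

    Defaults mirror a typical screening group: ~20 KO variants plus 3 SCR
    controls per plate, exposed/sham cuvette pairs, 3 independent
    experiments, 20 pulses, several hundred cells quantified per sample.

    Parameters
    ----------
    n_variants : int
        Number of KO variants (ignored when ``effect_map`` is given).
    n_scr_per_plate : int
        Scrambled-gRNA control variants added to every plate (2-4 typical).
    plate_size : int
        KO variants processed concurrently as one plate/group (15-20).
    n_experiments : int
        Independent repeats on different days (3-8).
    pulses : int
        Number of 300-ns pulses in the exposed condition.
    cells_per_sample : int
        Cells quantified per cuvette (400-2000 typical).
    sham_mean, sham_cv : float
        Mean and coefficient of variation of the baseline per-cell YP law.
    slope_per_pulse : float
        Mean uptake increment per pulse (a.u.) for a null variant at unit
        plate scale.
    increment_cv : float
        CV of the per-cell exposure increment.
    linear_limit : int
        Pulse count above which the dose response leaves the linear regime.
    divergence_fraction, divergence_scatter, divergence_mean_shift : float
        Above ``linear_limit``, this fraction of cells is reassigned to a
        broad component whose increment CV is multiplied by
        ``divergence_scatter`` and mean by ``divergence_mean_shift``.
    effect_map : mapping
        Variant id -> multiplicative effect on the exposure increment
        (1.0 = null). Built as all-null ``KO###`` ids when omitted.
    editing_fraction : mapping
        Variant id -> fraction of cells carrying the functional knockout;
        unlisted variants default to 1.0.
    plate_scale_sd : float
        CV of the per-(experiment, plate) multiplicative scale factor.
    outlier_rate, outlier_mean, outlier_cv : float
        Rare bright dead-cell outliers: per-cell probability and the
        (condition-independent) fluorescence law they are drawn from.
    seed : int
        Root seed; all samples derive reproducible substreams from it.
    """

    n_variants: int = 20
    n_scr_per_plate: int = 3
    plate_size: int = 20
    n_experiments: int = 3
    pulses: int = 20
    cells_per_sample: int = 800
    sham_mean: float = 100.0
    sham_cv: float = 0.5
    slope_per_pulse: float = 10.0
    increment_cv: float = 1.2
    linear_limit: int = 50
    divergence_fraction: float = 0.4
    divergence_scatter: float = 3.0
    divergence_mean_shift: float = 2.0
    effect_map: dict[str, float] | None = None
    editing_fraction: dict[str, float] = field(default_factory=dict)
    plate_scale_sd: float = 0.1
    outlier_rate: float = 0.005
    outlier_mean: float = 5000.0
    outlier_cv: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_map is None:
            self.effect_map = {
                f"KO{i + 1:03d}": 1.0 for i in range(self.n_variants)
            }
        else:
            self.effect_map = dict(self.effect_map)
            self.n_variants = len(self.effect_map)
        self.editing_fraction = dict(self.editing_fraction)
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_variants": self.n_variants,
            "n_scr_per_plate": self.n_scr_per_plate,
            "plate_size": self.plate_size,
            "n_experiments": self.n_experiments,
            "cells_per_sample": self.cells_per_sample,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ValueError(f"{name} must be a count >= 1, got {value}")
        if self.pulses < 0:
            raise ValueError("pulses must be >= 0")
        if self.linear_limit < 0:
            raise ValueError("linear_limit must be >= 0")
        for name in (
            "sham_cv",
            "increment_cv",
            "divergence_scatter",
            "divergence_mean_shift",
            "plate_scale_sd",
            "outlier_cv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sham_mean <= 0 or self.outlier_mean <= 0:
            raise ValueError("fluorescence means must be positive")
        if self.slope_per_pulse < 0:
            raise ValueError("slope_per_pulse must be >= 0")
        for name, frac in (
            ("divergence_fraction", self.divergence_fraction),
            ("outlier_rate", self.outlier_rate),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {frac}")
        for variant, eff in self.effect_map.items():
            if eff < 0:
                raise ValueError(f"effect for {variant} must be >= 0")
            if variant.startswith("SCR") and eff != 1.0:
                raise ValueError("SCR variants must carry effect 1.0")
        for variant, ef in self.editing_fraction.items():
            if not 0.0 <= ef <= 1.0:
                raise ValueError(
                    f"editing_fraction for {variant} must lie in [0, 1]"
                )

    @property
    def ko_variants(self) -> list[str]:
        return sorted(self.effect_map)

    def editing_of(self, variant: str) -> float:
        return self.editing_fraction.get(variant, 1.0)


@dataclass
class GroundTruth:
    """What the generator actually planted, for pipeline validation."""

    effects: dict[str, float]
    editing: dict[str, float]
    plate_of: dict[str, str]
    plate_scales: dict[tuple[str, str], float]
    scr_ids: set[str]

    def expected_delta_f(self, cfg: GeneratorConfig, variant: str) -> float:
        """Closed-form E[exposed mean - sham mean] at unit plate scale."""
        eff = self.effects[variant]
        ef = self.editing[variant]
        base = cfg.slope_per_pulse * cfg.pulses
        return (1.0 - cfg.outlier_rate) * base * (1.0 + ef * (eff - 1.0))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variant": v,
                "plate": self.plate_of[v],
                "effect": self.effects[v],
                "editing_fraction": self.editing[v],
                "is_scr": v in self.scr_ids,
            }
            for v in sorted(self.effects)
        ]
        return pd.DataFrame(rows)

    def scales_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"experiment": e, "plate": p, "scale": s}
                for (e, p), s in sorted(self.plate_scales.items())
            ]
        )


def _sample_rng(cfg: GeneratorConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, *key)))


def _draw_cells(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    condition: str,
    effect: float,
    editing: float,
    plate_scale: float,
) -> tuple[np.ndarray, np.ndarray]:
    n = cfg.cells_per_sample
    yp = _lognormal(rng, cfg.sham_mean, cfg.sham_cv, size=n)
    hoechst = _lognormal(rng, _HOECHST_MEAN, _HOECHST_CV, size=n)

    base_inc = cfg.slope_per_pulse * cfg.pulses * plate_scale
    if condition == "exposed" and base_inc > 0:
        mean_vec = np.full(n, base_inc)
        if effect != 1.0 and editing > 0:
            edited = rng.random(n) < editing
            mean_vec[edited] *= effect
        cv_vec = np.full(n, cfg.increment_cv)
        if cfg.pulses > cfg.linear_limit and cfg.divergence_fraction > 0:
            diverged = rng.random(n) < cfg.divergence_fraction
            mean_vec[diverged] *= cfg.divergence_mean_shift
            cv_vec[diverged] *= cfg.divergence_scatter
        yp = yp + _lognormal(rng, mean_vec, cv_vec)

    if cfg.outlier_rate > 0:
        dead = rng.random(n) < cfg.outlier_rate
        if dead.any():
            yp[dead] = _lognormal(
                rng, cfg.outlier_mean, cfg.outlier_cv, size=int(dead.sum())
            )
    return yp, hoechst


def generate_cell_sample(
    cfg: GeneratorConfig,
    variant: str,
    condition: str,
    experiment: str = "E1",
    rng: np.random.Generator | int | None = None,
    *,
    plate: str = "P1",
    plate_scale: float = 1.0,
) -> SampleMeasurement:
    """Draw one sample (cuvette) of per-cell fluorescence.

    ``variant`` must be present in ``cfg.effect_map``; sham samples ignore
    the exposure model entirely, so at zero pulses exposed and sham samples
    are draws from the same law.
    """
    if condition not in ("exposed", "sham"):
        raise ValueError(f"invalid condition {condition!r}")
    if variant not in cfg.effect_map:
        raise KeyError(f"unknown variant {variant!r}")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = _sample_rng(cfg, _STREAM_SAMPLE, 0 if rng is None else int(rng))
    yp, hoechst = _draw_cells(
        cfg,
        rng,
        condition,
        cfg.effect_map[variant],
        cfg.editing_of(variant),
        plate_scale,
    )
    return SampleMeasurement(
        experiment=experiment,
        plate=plate,
        variant=variant,
        condition=condition,
        yp=yp,
        hoechst=hoechst,
    )


def _plate_layout(cfg: GeneratorConfig) -> dict[str, list[str]]:
    """Partition KO variants into plates and add SCR controls to each."""
    kos = cfg.ko_variants
    plates: dict[str, list[str]] = {}
    n_plates = max(1, -(-len(kos) // cfg.plate_size))
    for p in range(n_plates):
        plate_id = f"P{p + 1}"
        members = [f"SCR-{plate_id}-{j + 1}" for j in range(cfg.n_scr_per_plate)]
        members += kos[p * cfg.plate_size : (p + 1) * cfg.plate_size]
        plates[plate_id] = members
    return plates


def generate_screen(
    cfg: GeneratorConfig,
) -> tuple[list[SampleMeasurement], GroundTruth]:
    """Generate a full screen: every variant as an exposed+sham pair in
    every experiment, with per-(experiment, plate) scale factors.

    Fully reproducible from ``cfg.seed``; each sample uses its own seed
    substream keyed by (experiment, plate, variant, condition).
    """
    plates = _plate_layout(cfg)
    effects = dict(cfg.effect_map)
    editing = {v: cfg.editing_of(v) for v in cfg.effect_map}
    plate_of: dict[str, str] = {}
    scr_ids: set[str] = set()
    for plate_id, members in plates.items():
        for v in members:
            plate_of[v] = plate_id
            if v.startswith("SCR-"):
                effects[v] = 1.0
                editing[v] = 1.0
                scr_ids.add(v)

    experiments = [f"E{e + 1}" for e in range(cfg.n_experiments)]
    plate_scales: dict[tuple[str, str], float] = {}
    for ei, exp in enumerate(experiments):
        for pi, plate_id in enumerate(plates):
            rng = _sample_rng(cfg, _STREAM_SCALE, ei, pi)
            plate_scales[(exp, plate_id)] = float(
                _lognormal(rng, 1.0, cfg.plate_scale_sd, size=())
            )

    samples: list[SampleMeasurement] = []
    for ei, exp in enumerate(experiments):
        for pi, (plate_id, members) in enumerate(plates.items()):
            scale = plate_scales[(exp, plate_id)]
            for vi, variant in enumerate(members):
                for ci, condition in enumerate(("exposed", "sham")):
                    rng = _sample_rng(cfg, _STREAM_SAMPLE, ei, pi, vi, ci)
                    yp, hoechst = _draw_cells(
                        cfg,
                        rng,
                        condition,
                        effects[variant],
                        editing[variant],
                        scale,
                    )
                    samples.append(
                        SampleMeasurement(
                            experiment=exp,
                            plate=plate_id,
                            variant=variant,
                            condition=condition,
                            yp=yp,
                            hoechst=hoechst,
                        )
                    )
    truth = GroundTruth(
        effects=effects,
        editing=editing,
        plate_of=plate_of,
        plate_scales=plate_scales,
        scr_ids=scr_ids,
    )
    return samples, truth


def generate_replication_series(
    cfg: GeneratorConfig,
    attenuation: float,
    seed: int | None = None,
) -> tuple[list[SampleMeasurement], GroundTruth]:
    """Re-generate the screen as an independent replication series.

    Models the fade of knockout effects between series (unedited cells
    outgrowing edited ones): every editing fraction is multiplied by
    ``1 - attenuation``. A fresh seed is derived from the root seed unless
    one is given explicitly.
    """
    if not 0.0 <= attenuation <= 1.0:
        raise ValueError("attenuation must lie in [0, 1]")
    if seed is None:
        seed = int(
            np.random.SeedSequence((cfg.seed, _STREAM_SERIES)).generate_state(1)[0]
            % (2**31)
        )
    editing = {
        v: cfg.editing_of(v) * (1.0 - attenuation) for v in cfg.effect_map
    }
    new_cfg = dataclasses.replace(
        cfg,
        effect_map=dict(cfg.effect_map),
        editing_fraction=editing,
        seed=seed,
    )
    return generate_screen(new_cfg)
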