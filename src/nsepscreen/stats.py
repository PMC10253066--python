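"""Hit-selection statistics: SSMD, Dunnett many-to-one test, hit classes.

Effect size and significance are judged separately and a variant is a hit
only when both criteria agree:

* SSMD (strictly standardized mean difference), in the unpaired
  unequal-variance form for screens::

      SSMD = (ΔF̄_KO − ΔF̄_SCR) / sqrt(S²_KO + S²_SCR)

  where ΔF̄ is the mean normalized ΔF pooled across experiments and S² the
  squared standard error of that mean. |SSMD| > 1 is the conventional
  "strong effect" band.

* Dunnett's test comparing every knockout on a plate against the shared
  scrambled-control group, controlling the family-wise error rate. The
  family-wise adjusted two-sided p-value is computed by deterministic
  numerical integration of the equicorrelated multivariate-t null
  (Gauss–Hermite over the shared control deviate × Gauss–Legendre over the
  pooled-scale distribution).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
from scipy.special import ndtr

from .quantify import VariantPooled

HIT_CLASSES = ("up_hit", "down_hit", "possible_up", "possible_down", "none")

_RANK = {"up_hit": 2, "down_hit": 2, "possible_up": 1, "possible_down": 1, "none": 0}
_DIRECTION = {
    "up_hit": 1,
    "possible_up": 1,
    "down_hit": -1,
    "possible_down": -1,
    "none": 0,
}


# ---------------------------------------------------------------------------
# SSMD


def ssmd(ko: VariantPooled | float, scr: VariantPooled | float, *,
         ko_sem2: float | None = None, scr_sem2: float | None = None) -> float:
    """Strictly standardized mean difference between a KO and the control.

    Accepts two :class:`~nsepscreen.quantify.VariantPooled` objects, or raw
    ``(mean, sem2)`` pairs via the keyword arguments. The sign carries the
    direction of the effect. With both dispersions zero the result is 0 for
    equal means and signed infinity otherwise (flagged downstream).
    """
    if isinstance(ko, VariantPooled):
        ko_mean, ko_sem2 = ko.mean, ko.sem2
    else:
        ko_mean = float(ko)
    if isinstance(scr, VariantPooled):
        scr_mean, scr_sem2 = scr.mean, scr.sem2
    else:
        scr_mean = float(scr)
    if ko_sem2 is None or scr_sem2 is None:
        raise ValueError("dispersions are required")
    if ko_sem2 < 0 or scr_sem2 < 0:
        raise ValueError("dispersions must be >= 0")
    diff = ko_mean - scr_mean
    denom = np.sqrt(ko_sem2 + scr_sem2)
    if denom == 0:
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / denom)


# ---------------------------------------------------------------------------
# Dunnett's many-to-one comparison


def _quadrature_nodes(ns: Sequence[int], n0: int, nu: int,
                      n_s: int, n_z: int):
    """Nodes/weights for the Dunnett null integral.

    The null distribution of the comparison statistics conditions on the
    shared control deviate Z₀ (standard normal) and the pooled scale
    S ~ χ_ν/√ν; both integrals are smooth and handled by fixed Gaussian
    quadrature.
    """
    lo = sps.chi.ppf(1e-14, nu) / np.sqrt(nu)
    hi = sps.chi.isf(1e-14, nu) / np.sqrt(nu)
    xs, ws = np.polynomial.legendre.leggauss(n_s)
    s = (hi + lo) / 2 + (hi - lo) / 2 * xs
    w_s = ws * (hi - lo) / 2 * sps.chi.pdf(s * np.sqrt(nu), nu) * np.sqrt(nu)
    xz, wz = np.polynomial.hermite.hermgauss(n_z)
    z = np.sqrt(2.0) * xz
    w_z = wz / np.sqrt(np.pi)
    return s, w_s, z, w_z


def _max_abs_t_cdf(c, ns: Sequence[int], n0: int, nu: int,
                   n_s: int = 96, n_z: int = 96) -> np.ndarray:
    """P(max_j |T_j| <= c) under the Dunnett null, for an array of c.

    T_j = (X̄_j − X̄_0)/(S·sqrt(1/n_j + 1/n_0)) with a shared control mean
    X̄_0 and pooled scale S on ``nu`` degrees of freedom.
    """
    c = np.atleast_1d(np.asarray(c, dtype=float))
    s, w_s, z, w_z = _quadrature_nodes(ns, n0, nu, n_s, n_z)
    z0 = z / np.sqrt(n0)  # conditional mean of X̄_j-window centre
    prod = np.ones((c.size, s.size, z.size))
    for nj in ns:
        g = np.sqrt(1.0 / nj + 1.0 / n0)
        half = c[:, None, None] * s[None, :, None] * g
        centre = z0[None, None, :]
        sqrt_nj = np.sqrt(nj)
        prod *= ndtr((centre + half) * sqrt_nj) - ndtr((centre - half) * sqrt_nj)
    inner = prod @ w_z  # integrate over the control deviate
    out = inner @ w_s  # integrate over the pooled scale
    return np.clip(out, 0.0, 1.0)


@dataclass
class DunnettResult:
    """Comparison statistics of every group against the shared control."""

    statistic: np.ndarray
    pvalue: np.ndarray
    df: int
    group_sizes: tuple[int, ...]
    control_size: int

    def critical_value(self, alpha: float = 0.05) -> float:
        """Two-sided family-wise critical |t| at level ``alpha``."""
        target = 1.0 - alpha

        def f(c):
            return float(
                _max_abs_t_cdf(c, self.group_sizes, self.control_size, self.df)[0]
            ) - target

        return float(optimize.brentq(f, 1e-3, 50.0, xtol=1e-10))


def dunnett_test(
    groups: Sequence[Sequence[float]], control: Sequence[float]
) -> DunnettResult:
    """Dunnett's two-sided many-to-one test from raw replicate values.

    Classical pooled-variance form: the error variance is pooled across all
    groups and the control; family-wise adjusted p-values come from the
    joint null of max |T_j|. With a single comparison the test reduces to
    Student's two-sample t-test.
    """
    control = np.asarray(control, dtype=float)
    groups = [np.asarray(g, dtype=float) for g in groups]
    if control.size < 2:
        raise ValueError("control needs >= 2 replicates")
    if not groups:
        raise ValueError("at least one comparison group is required")
    for g in groups:
        if g.size < 2:
            raise ValueError("every group needs >= 2 replicates")
    n0 = control.size
    ns = tuple(int(g.size) for g in groups)
    nu = int(sum(n - 1 for n in ns) + (n0 - 1))
    ss = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    ss += float(np.sum((control - control.mean()) ** 2))
    s2p = ss / nu
    m0 = control.mean()
    diffs = np.array([g.mean() - m0 for g in groups])
    if s2p == 0:
        t = np.where(diffs == 0, 0.0, np.sign(diffs) * np.inf)
        p = np.where(diffs == 0, 1.0, 0.0)
        return DunnettResult(t, p, nu, ns, n0)
    se = np.sqrt(s2p * (1.0 / np.array(ns) + 1.0 / n0))
    t = diffs / se
    p = 1.0 - _max_abs_t_cdf(np.abs(t), ns, n0, nu)
    return DunnettResult(t, p, nu, ns, n0)


def dunnett(
    kos: Sequence[VariantPooled], scr_values: Sequence[float]
) -> list[tuple[float, float]]:
    """Per-KO (t, adjusted p) against the pooled SCR control values.

    Thin wrapper over :func:`dunnett_test` taking pooled variant objects
    (which carry their per-experiment normalized ΔF replicates).
    """
    res = dunnett_test([ko.values for ko in kos], scr_values)
    return list(zip(res.statistic.tolist(), res.pvalue.tolist()))


def dunnett_critical_value(
    k: int, n_per_group: int, n_control: int, alpha: float = 0.05
) -> float:
    """Two-sided Dunnett critical |t| for a balanced design."""
    ns = (n_per_group,) * k
    nu = k * (n_per_group - 1) + (n_control - 1)
    res = DunnettResult(np.zeros(k), np.ones(k), nu, ns, n_control)
    return res.critical_value(alpha)


# ---------------------------------------------------------------------------
# hit classification


@dataclass(frozen=True)
class VariantStats:
    """Per-variant, per-metric screen statistics and hit class."""

    variant: str
    metric: str
    delta_f_mean: float
    sem2: float
    n: int
    ssmd: float
    dunnett_t: float
    dunnett_p_adj: float
    hit_class: str = "none"

    @property
    def ssmd_infinite(self) -> bool:
        return bool(np.isinf(self.ssmd))


def _classify_one(
    ssmd_value: float, p_adj: float, alpha: float, ssmd_thresh: float
) -> str:
    if ssmd_value > ssmd_thresh:
        return "up_hit" if p_adj < alpha else "possible_up"
    if ssmd_value < -ssmd_thresh:
        return "down_hit" if p_adj < alpha else "possible_down"
    return "none"


def classify_hits(
    stats: Sequence[VariantStats],
    alpha: float = 0.05,
    ssmd_thresh: float = 1.0,
) -> list[VariantStats]:
    """Apply the dual hit criterion per metric record.

    A record is an ``up_hit``/``down_hit`` only when the family-wise
    adjusted p-value is below ``alpha`` *and* the SSMD is beyond the
    threshold in the same direction; an SSMD excursion without significance
    is a ``possible_up``/``possible_down``.
    """
    return [
        replace(
            s,
            hit_class=_classify_one(s.ssmd, s.dunnett_p_adj, alpha, ssmd_thresh),
        )
        for s in stats
    ]


def combine_metric_calls(stats: Sequence[VariantStats]) -> dict[str, str]:
    """One call per variant across metrics: a variant qualifies if either
    the mean or the median metric qualifies; the stronger class wins."""
    best: dict[str, VariantStats] = {}
    for s in stats:
        cur = best.get(s.variant)
        if cur is None:
            best[s.variant] = s
            continue
        key_new = (_RANK[s.hit_class], abs(s.ssmd) if np.isfinite(s.ssmd) else 0.0)
        key_cur = (
            _RANK[cur.hit_class],
            abs(cur.ssmd) if np.isfinite(cur.ssmd) else 0.0,
        )
        if key_new > key_cur:
            best[s.variant] = s
    return {v: s.hit_class for v, s in best.items()}


# ---------------------------------------------------------------------------
# replication concordance


def _series_view(stats: Sequence[VariantStats]) -> dict[str, list[VariantStats]]:
    view: dict[str, list[VariantStats]] = {}
    for s in stats:
        view.setdefault(s.variant, []).append(s)
    return view


def replication_concordance(
    series1: Sequence[VariantStats],
    series2: Sequence[VariantStats],
    ssmd_thresh: float = 1.0,
    margin_up: float = 120.0,
    margin_down: float = 80.0,
) -> pd.DataFrame:
    """Final hit calls from two independent replication series.

    A variant is a final hit when it is a significant hit (dual criterion)
    in at least one series and the other series supports the same
    direction — either an SSMD beyond the threshold, or a mean normalized
    ΔF beyond the consistency margin (``>= margin_up`` % for up,
    ``<= margin_down`` % for down). Opposite-direction evidence in the
    other series demotes the variant to ``none``; variants missing from
    one series are reported as ``untested``.
    """
    v1, v2 = _series_view(series1), _series_view(series2)
    rows = []
    for variant in sorted(set(v1) | set(v2)):
        s1, s2 = v1.get(variant), v2.get(variant)
        if s1 is None or s2 is None:
            rows.append({"variant": variant, "final": "untested",
                         "series1": _best_class(s1), "series2": _best_class(s2)})
            continue
        final = _concord(s1, s2, ssmd_thresh, margin_up, margin_down)
        rows.append({"variant": variant, "final": final,
                     "series1": _best_class(s1), "series2": _best_class(s2)})
    return pd.DataFrame(rows)


def _best_class(stats: Sequence[VariantStats] | None) -> str:
    if not stats:
        return "absent"
    return max(
        stats,
        key=lambda s: (_RANK[s.hit_class], abs(s.ssmd) if np.isfinite(s.ssmd) else 0),
    ).hit_class


def _sig_direction(stats: Sequence[VariantStats]) -> int:
    dirs = {
        _DIRECTION[s.hit_class]
        for s in stats
        if s.hit_class in ("up_hit", "down_hit")
    }
    if not dirs:
        return 0
    if len(dirs) > 1:
        return 0  # internally contradictory series
    return dirs.pop()


def _supports(stats: Sequence[VariantStats], direction: int,
              ssmd_thresh: float, margin_up: float, margin_down: float) -> bool:
    for s in stats:
        if np.isfinite(s.ssmd) and np.sign(s.ssmd) == direction and abs(s.ssmd) > ssmd_thresh:
            return True
        if direction > 0 and s.delta_f_mean >= margin_up:
            return True
        if direction < 0 and s.delta_f_mean <= margin_down:
            return True
    return False


def _contradicts(stats: Sequence[VariantStats], direction: int,
                 ssmd_thresh: float) -> bool:
    for s in stats:
        s_dir = _DIRECTION[s.hit_class]
        if s_dir and s_dir != direction and (
            s.hit_class in ("up_hit", "down_hit")
            or (np.isfinite(s.ssmd) and abs(s.ssmd) > ssmd_thresh)
        ):
            return True
    return False


def _concord(s1, s2, ssmd_thresh, margin_up, margin_down) -> str:
    d1, d2 = _sig_direction(s1), _sig_direction(s2)
    if d1 and d2:
        if d1 != d2:
            return "none"
        return "up_hit" if d1 > 0 else "down_hit"
    for sig, other, direction in ((s1, s2, d1), (s2, s1, d2)):
        if direction == 0:
            continue
        if _contradicts(other, direction, ssmd_thresh):
            return "none"
        if _supports(other, direction, ssmd_thresh, margin_up, margin_down):
            return "up_hit" if direction > 0 else "down_hit"
    return "none"


# ---------------------------------------------------------------------------
# screen summary


@dataclass
class ScreenSummary:
    """Threshold counts describing the asymmetry of a screen."""

    n_variants: int
    counts: dict[str, dict[str, int]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts).T.rename_axis("metric")


def screen_summary(
    pooled: Sequence[VariantPooled],
    stats: Sequence[VariantStats],
    alpha: float = 0.05,
    ssmd_thresh: float = 1.0,
) -> ScreenSummary:
    """Count variants beyond the ±10/±20% bands, the SSMD threshold, and
    the significance level, split by direction and metric.

    Infinite SSMD values (zero-dispersion degenerate pools) are excluded
    from the SSMD threshold counts.
    """
    metrics = sorted({p.metric for p in pooled} | {s.metric for s in stats})
    counts: dict[str, dict[str, int]] = {}
    for metric in metrics:
        pm = [p for p in pooled if p.metric == metric]
        sm = [s for s in stats if s.metric == metric]
        finite = [s for s in sm if np.isfinite(s.ssmd)]
        counts[metric] = {
            "above_110": sum(p.mean > 110.0 for p in pm),
            "above_120": sum(p.mean > 120.0 for p in pm),
            "below_90": sum(p.mean < 90.0 for p in pm),
            "below_80": sum(p.mean < 80.0 for p in pm),
            "ssmd_gt_1": sum(s.ssmd > ssmd_thresh for s in finite),
            "ssmd_lt_minus1": sum(s.ssmd < -ssmd_thresh for s in finite),
            "sig_up": sum(
                s.dunnett_p_adj < alpha and s.ssmd > 0 for s in finite
            ),
            "sig_down": sum(
                s.dunnett_p_adj < alpha and s.ssmd < 0 for s in finite
            ),
        }
    n_variants = len({p.variant for p in pooled} | {s.variant for s in stats})
    return ScreenSummary(n_variants=n_variants, counts=counts)
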