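"""T7EI genomic-cleavage assay model.

After PCR amplification of the targeted locus, strands are denatured and
re-annealed at random. Duplexes pairing two different allele classes
(wild-type × indel, or two distinct indels) carry a mismatch and are cut
by the T7 endonuclease I into two fragments; gel densitometry then gives
the cleaved fraction

    CF = (B + C) / (A + B + C)

from the parental band A and the cleaved bands B and C. Under random
re-annealing the expected mismatched fraction is 1 − Σ pᵢ², so a pool of
wild-type plus one indel class can never exceed 50% — the assay's
detection ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CleavageLanes:
    """Band intensities for one gel lane (arbitrary densitometry units)."""

    a: float  # parental band
    b: float  # cleaved fragment band
    c: float  # cleaved fragment band
    lane: str = ""
    t7ei_treated: bool = True

    def __post_init__(self):
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("band intensities must be >= 0")


@dataclass(frozen=True)
class AllelePool:
    """Allele-class frequencies (wild type plus distinct indel classes)."""

    frequencies: tuple[float, ...]

    def __post_init__(self):
        p = np.asarray(self.frequencies, dtype=float)
        if p.size == 0 or np.any(p < 0):
            raise ValueError("frequencies must be non-negative and non-empty")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies must sum to 1, got {p.sum()!r}")
        object.__setattr__(self, "frequencies", tuple(float(x) for x in p))


def cleaved_fraction(lanes: CleavageLanes) -> float:
    """CF = (B + C)/(A + B + C) for a T7EI-treated lane."""
    if not lanes.t7ei_treated:
        raise ValueError("cleaved fraction is defined for T7EI-treated lanes")
    total = lanes.a + lanes.b + lanes.c
    if total <= 0:
        raise ValueError("all band intensities are zero")
    return (lanes.b + lanes.c) / total


def expected_mismatch_fraction(pool: AllelePool | Sequence[float]) -> float:
    """Probability that a randomly re-annealed duplex is mismatched.

    Two strands drawn independently from the pool pair into a heteroduplex
    whenever their allele classes differ: 1 − Σ pᵢ². For a two-class pool
    this is maximized at p = 0.5 with value exactly 0.5, which is the
    assay's detection ceiling in the common wild-type + single-indel case.
    """
    if not isinstance(pool, AllelePool):
        pool = AllelePool(tuple(pool))
    p = np.asarray(pool.frequencies)
    return float(1.0 - np.sum(p**2))


def simulate_reannealing(
    pool: AllelePool | Sequence[float],
    n_duplexes: int,
    rng: np.random.Generator | int | None = None,
) -> CleavageLanes:
    """Monte-Carlo re-annealing of ``n_duplexes`` strand pairs.

    Each duplex contributes unit DNA mass: mismatched duplexes are cut into
    two equal-mass fragments (B and C each gain 0.5), matched duplexes stay
    in the parental band A — so ``cleaved_fraction`` of the resulting lane
    estimates the mismatched fraction directly.
    """
    if not isinstance(pool, AllelePool):
        pool = AllelePool(tuple(pool))
    if n_duplexes < 1:
        raise ValueError("n_duplexes must be >= 1")
    rng = np.random.default_rng(rng)
    p = np.asarray(pool.frequencies)
    first = rng.choice(p.size, size=n_duplexes, p=p)
    second = rng.choice(p.size, size=n_duplexes, p=p)
    mismatched = int(np.sum(first != second))
    matched = n_duplexes - mismatched
    return CleavageLanes(
        a=float(matched),
        b=mismatched / 2.0,
        c=mismatched / 2.0,
        lane="simulated",
        t7ei_treated=True,
    )


def read_lane_table(path) -> list[CleavageLanes]:
    """Read a delimited lane table with columns lane, a, b, c, treated."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    required = {"lane", "a", "b", "c"}
    if not required <= set(cols):
        raise ValueError(f"lane table must have columns {sorted(required)}")
    lanes = []
    for _, row in df.iterrows():
        treated = bool(row[cols["treated"]]) if "treated" in cols else True
        lanes.append(
            CleavageLanes(
                a=float(row[cols["a"]]),
                b=float(row[cols["b"]]),
                c=float(row[cols["c"]]),
                lane=str(row[cols["lane"]]),
                t7ei_treated=treated,
            )
        )
    return lanes
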