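"""Gene expression vs nsEP lethality (LD50) correlation stage.

Candidate genes from the screen are checked for a linear relationship
between their basal expression level across cell lines and each line's
LD50 for lethal pulsed-field treatments. Genes with a strong
(R ≥ ``r_min``) and significant (p ≤ ``p_max``) Pearson correlation are
selected, and their baseline-shifted expression values are pooled into a
single cross-gene correlation with LD50. The baseline is the most
sensitive line (lowest LD50), whose expression is taken as zero; Pearson
correlation is translation-invariant, so the shift changes pooling but not
per-gene R.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Default synthetic panel geometry: 60 candidate genes over 6 cell lines
#: whose LD50 spans an ~80-fold range (arbitrary dose units), the most
#: sensitive line first.
DEFAULT_LINES = ("IMR-32", "HPAF-II", "Hep-G2", "HT-1080", "MRC-5", "BJ")


@dataclass
class ExpressionPanel:
    """Gene × cell-line expression with per-line LD50.

    ``expression`` is a genes-by-lines DataFrame (arbitrary expression
    units); ``ld50`` a Series indexed by the same lines (dose units, > 0).
    """

    expression: pd.DataFrame
    ld50: pd.Series

    def __post_init__(self):
        self.expression = self.expression.astype(float)
        self.ld50 = self.ld50.astype(float)
        if list(self.expression.columns) != list(self.ld50.index):
            self.ld50 = self.ld50.reindex(self.expression.columns)
        if self.ld50.isna().any():
            raise ValueError("every cell line needs an LD50 value")
        if (self.ld50 <= 0).any():
            raise ValueError("LD50 values must be positive")
        if self.expression.isna().any().any():
            raise ValueError("expression matrix must be complete")
        if self.expression.shape[1] < 3:
            raise ValueError("need >= 3 cell lines for correlation")

    @property
    def genes(self) -> list[str]:
        return list(self.expression.index)

    @property
    def lines(self) -> list[str]:
        return list(self.expression.columns)

    def most_sensitive_line(self) -> str:
        return str(self.ld50.idxmin())


def baseline_shift(panel: ExpressionPanel, baseline_line: str | None = None) -> ExpressionPanel:
    """Subtract the baseline line's expression per gene (its column -> 0).

    The most sensitive line (lowest LD50) is the default baseline.
    Idempotent: re-shifting to the same baseline is a no-op.
    """
    if baseline_line is None:
        baseline_line = panel.most_sensitive_line()
    if baseline_line not in panel.lines:
        raise KeyError(f"unknown baseline line {baseline_line!r}")
    shifted = panel.expression.sub(panel.expression[baseline_line], axis=0)
    return ExpressionPanel(expression=shifted, ld50=panel.ld50.copy())


def gene_ld50_correlation(panel: ExpressionPanel, gene: str) -> tuple[float, float]:
    """Pearson R and two-sided p of one gene's expression vs LD50.

    The p-value comes from the t transform on n − 2 degrees of freedom.
    """
    if gene not in panel.expression.index:
        raise KeyError(f"unknown gene {gene!r}")
    x = panel.expression.loc[gene].to_numpy(dtype=float)
    y = panel.ld50.to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in expression or LD50")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class SelectionResult:
    """Outcome of threshold selection + pooling over a panel."""

    per_gene: pd.DataFrame  # gene, r, p, selected
    selected: list[str]
    pooled_r: float
    pooled_p: float
    baseline_line: str


def select_and_pool(
    panel: ExpressionPanel,
    r_min: float = 0.9,
    p_max: float = 0.02,
    baseline_line: str | None = None,
) -> SelectionResult:
    """Select genes with R ≥ ``r_min`` and p ≤ ``p_max``; pool their
    baseline-shifted (expression, LD50) pairs into one correlation.

    An empty selection is a valid outcome (pooled values are NaN).
    """
    if baseline_line is None:
        baseline_line = panel.most_sensitive_line()
    shifted = baseline_shift(panel, baseline_line)
    rows = []
    for gene in panel.genes:
        try:
            r, p = gene_ld50_correlation(shifted, gene)
        except ValueError:
            r, p = np.nan, np.nan
        rows.append(
            {
                "gene": gene,
                "r": r,
                "p": p,
                "selected": bool(r >= r_min and p <= p_max),
            }
        )
    per_gene = pd.DataFrame(rows)
    selected = per_gene.loc[per_gene["selected"], "gene"].tolist()
    if selected:
        expr = shifted.expression.loc[selected].to_numpy(dtype=float).ravel()
        ld50 = np.tile(shifted.ld50.to_numpy(dtype=float), len(selected))
        pooled_r, pooled_p = sps.pearsonr(expr, ld50)
    else:
        pooled_r, pooled_p = np.nan, np.nan
    return SelectionResult(
        per_gene=per_gene,
        selected=selected,
        pooled_r=float(pooled_r),
        pooled_p=float(pooled_p),
        baseline_line=baseline_line,
    )


def simulate_expression_panel(
    n_genes: int = 60,
    n_planted: int = 8,
    lines: tuple[str, ...] = DEFAULT_LINES,
    ld50: np.ndarray | None = None,
    noise_frac: float = 0.15,
    null_sd: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[ExpressionPanel, list[str]]:
    """Synthetic candidate-gene panel with planted LD50-linear genes.

    The first ``n_planted`` genes follow expression = a + b·LD50 + noise
    with noise SD equal to ``noise_frac`` of the signal spread b·SD(LD50);
    the remaining genes are LD50-independent noise. The default LD50
    ladder is log-spaced over an 80-fold range across six lines, the most
    sensitive line first. Returns the panel and the planted gene ids.
    """
    if not 0 <= n_planted <= n_genes:
        raise ValueError("n_planted must lie in [0, n_genes]")
    rng = np.random.default_rng(rng)
    if ld50 is None:
        ld50 = np.geomspace(1.0, 80.0, len(lines))
    ld50 = np.asarray(ld50, dtype=float)
    if ld50.size != len(lines):
        raise ValueError("ld50 must have one value per line")
    genes = [f"G{i + 1:03d}" for i in range(n_genes)]
    planted = genes[:n_planted]
    expr = np.empty((n_genes, len(lines)))
    sd_ld50 = float(np.std(ld50))
    for i in range(n_genes):
        if i < n_planted:
            slope = rng.uniform(0.5, 2.0)
            intercept = rng.uniform(-2.0, 2.0)
            noise = rng.normal(0.0, noise_frac * slope * sd_ld50, size=ld50.size)
            expr[i] = intercept + slope * ld50 + noise
        else:
            expr[i] = rng.normal(0.0, null_sd, size=ld50.size)
    panel = ExpressionPanel(
        expression=pd.DataFrame(expr, index=genes, columns=list(lines)),
        ld50=pd.Series(ld50, index=list(lines)),
    )
    return panel, planted


def read_expression_tables(expression_path, ld50_path) -> ExpressionPanel:
    """Read a gene × line expression table and a line → LD50 table."""
    expr = pd.read_csv(expression_path, sep=None, engine="python", index_col=0)
    ld = pd.read_csv(ld50_path, sep=None, engine="python")
    cols = {c.lower(): c for c in ld.columns}
    if "line" not in cols or "ld50" not in cols:
        raise ValueError("LD50 table must have columns 'line' and 'ld50'")
    ld50 = ld.set_index(cols["line"])[cols["ld50"]]
    return ExpressionPanel(expression=expr, ld50=ld50)
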