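"""Genotype x modifier interaction matrix.

Each cell of the matrix is one double-heterozygote combination (row gene x
column modifier, with "wild type" rows/columns giving the single mutants and
the wild-type cell itself). Per cell we summarise recordings with and
without PhTx (:func:`homeoscreen.quantal.php_summary`), test the +/-PhTx
quantal-content difference within the cell (Student's t, two-tailed), and
compare every cell's +PhTx quantal content against the wild-type cell with
Dunnett's many-to-one procedure. Classification into blocked / suppressed /
intact uses the percent-QC-change bins; the within-cell test is the
authoritative statistic for presence of PHP, the Dunnett column is reported
alongside as the secondary, family-wise-controlled comparison.

Dunnett adjustment is computed by seeded Monte Carlo: under the null the
vector of many-to-one t statistics is a correlated multivariate t, and the
adjusted p-value of a cell is the probability that the maximum |t| over the
family exceeds the observed |t|.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .quantal import PHPSummary, classify_php, php_summary

WILD_TYPE = "wild type"


def pair_label(row: str, col: str, sep: str = ";") -> str:
    """Measurement-table genotype label for a (row, column) combination."""
    return f"{row}{sep}{col}"


@dataclass(frozen=True)
class InteractionCell:
    row_label: str
    col_label: str
    summary: PHPSummary
    p_vs_wt: float | None = None  # Dunnett-adjusted, filled by dunnett_vs_wt

    @property
    def php_class(self) -> str:
        return self.summary.php_class


class InteractionMatrix:
    """Complete genotype x modifier matrix of :class:`InteractionCell`."""

    def __init__(
        self,
        row_labels: Sequence[str],
        col_labels: Sequence[str],
        cells: Mapping[tuple[str, str], InteractionCell],
        qc_samples: Mapping[tuple[str, str], tuple[np.ndarray, np.ndarray]],
    ):
        self.row_labels = list(row_labels)
        self.col_labels = list(col_labels)
        self.cells = dict(cells)
        self._qc_samples = dict(qc_samples)  # (minus, plus) per-NMJ QC arrays
        if len(self.cells) != len(self.row_labels) * len(self.col_labels):
            raise DomainError("matrix incomplete: cell count != rows x columns")
        for (r, c), cell in self.cells.items():
            if (cell.row_label, cell.col_label) != (r, c):
                raise DomainError(f"cell labels {cell.row_label, cell.col_label} "
                                  f"do not match position {(r, c)}")

    def __getitem__(self, key: tuple[str, str]) -> InteractionCell:
        return self.cells[key]

    def qc_plus(self, key: tuple[str, str]) -> np.ndarray:
        return self._qc_samples[key][1]


def build_matrix(
    measurements: pd.DataFrame,
    row_labels: Sequence[str],
    col_labels: Sequence[str],
    label_sep: str = ";",
) -> InteractionMatrix:
    """Assemble the matrix from a measurement table.

    The genotype label of the (row, col) cell is ``f"{row}{sep}{col}"``;
    every cell needs >= 2 recordings per PhTx state.
    """
    if len(set(row_labels)) != len(row_labels) or len(set(col_labels)) != len(
        col_labels
    ):
        raise DomainError("duplicate row or column labels")
    cells = {}
    qc_samples = {}
    for r in row_labels:
        for c in col_labels:
            label = pair_label(r, c, label_sep)
            rows = measurements[measurements["genotype"] == label]
            if rows.empty:
                raise DomainError(f"no recordings for matrix cell {label!r}")
            s = php_summary(rows, genotype=label)
            cells[(r, c)] = InteractionCell(row_label=r, col_label=c, summary=s)
            qc = rows["epsp_mV"] / rows["mepsp_mV"]
            qc_samples[(r, c)] = (
                qc[rows["phtx"] == 0].to_numpy(dtype=float),
                qc[rows["phtx"] == 1].to_numpy(dtype=float),
            )
    return InteractionMatrix(row_labels, col_labels, cells, qc_samples)


def within_cell_test(
    qc_minus: np.ndarray, qc_plus: np.ndarray, welch: bool = False
) -> float:
    """Two-tailed two-sample Student's t on per-NMJ QC, -PhTx vs +PhTx."""
    if len(qc_minus) < 2 or len(qc_plus) < 2:
        raise DomainError("within_cell_test needs >= 2 recordings per state")
    if np.ptp(qc_minus) == 0 and np.ptp(qc_plus) == 0:
        if qc_minus.mean() == qc_plus.mean():
            return 1.0
        warnings.warn("degenerate variance; p-value undefined", stacklevel=2)
        return float("nan")
    p = stats.ttest_ind(qc_minus, qc_plus, equal_var=not welch).pvalue
    return float(p) if math.isfinite(p) else float("nan")


def dunnett_max_t_sample(
    group_sizes: Sequence[int],
    rng: np.random.Generator,
    n_draws: int = 100_000,
) -> np.ndarray:
    """Monte-Carlo sample of max_i |t_i| for Dunnett many-to-one comparisons.

    ``group_sizes[0]`` is the control group. Under the global null with a
    pooled variance estimate on ``N - k`` degrees of freedom,
    ``t_i = (Zbar_i - Zbar_0) / (s * sqrt(1/n_i + 1/n_0))``; the draws share
    the control mean and the variance estimate, reproducing the Dunnett
    correlation structure exactly.
    """
    sizes = np.asarray(group_sizes, dtype=float)
    k = len(sizes) - 1
    if k < 1:
        raise DomainError("need at least one comparison group")
    df = int(sizes.sum()) - len(sizes)
    z = rng.standard_normal((n_draws, len(sizes))) / np.sqrt(sizes)
    s = np.sqrt(rng.chisquare(df, size=n_draws) / df)
    scale = np.sqrt(1.0 / sizes[1:] + 1.0 / sizes[0])
    t = (z[:, 1:] - z[:, :1]) / (s[:, None] * scale)
    return np.abs(t).max(axis=1)


def dunnett_adjusted_p(
    groups: Sequence[np.ndarray],
    rng: np.random.Generator,
    n_draws: int = 100_000,
) -> np.ndarray:
    """Dunnett-adjusted two-sided p-values of each group vs ``groups[0]``.

    Returns one adjusted p per comparison group, computed as the Monte-Carlo
    probability that the family's max |t| exceeds that group's observed |t|.
    """
    sizes = [len(g) for g in groups]
    if len(groups) < 2:
        raise DomainError("need a control and at least one comparison group")
    df = sum(sizes) - len(groups)
    if df < 1:
        raise DomainError("no residual degrees of freedom for the pooled variance")
    pooled = math.sqrt(
        sum((len(g) - 1) * np.var(g, ddof=1) for g in groups) / df
    )
    control = np.mean(groups[0])
    maxt = dunnett_max_t_sample(sizes, rng, n_draws)
    out = []
    for g, n in zip(groups[1:], sizes[1:]):
        if pooled == 0:
            out.append(1.0 if np.mean(g) == control else 0.0)
            continue
        t_obs = (np.mean(g) - control) / (pooled * math.sqrt(1 / n + 1 / sizes[0]))
        out.append(float(np.mean(maxt >= abs(t_obs))))
    return np.asarray(out)


def dunnett_vs_wt(
    matrix: InteractionMatrix,
    rng: np.random.Generator,
    wt_key: tuple[str, str] = (WILD_TYPE, WILD_TYPE),
    n_draws: int = 100_000,
) -> dict[tuple[str, str], float]:
    """Adjusted p of each cell's +PhTx QC against the wild-type cell."""
    if wt_key not in matrix.cells:
        raise DomainError(f"wild-type cell {wt_key} missing from matrix")
    keys = [k for k in matrix.cells if k != wt_key]
    groups = [matrix.qc_plus(wt_key)] + [matrix.qc_plus(k) for k in keys]
    adj = dunnett_adjusted_p(groups, rng, n_draws)
    return dict(zip(keys, adj))


def export_heatmap_tables(matrix: InteractionMatrix) -> dict[str, pd.DataFrame]:
    """Heat-map-ready tables in matrix order.

    Keys: ``mepsp_minus``, ``mepsp_plus``, ``epsp_minus``, ``epsp_plus``
    (mean amplitudes, mV), ``pct_qc_change`` (%), ``php_class``.
    """
    if not matrix.cells:
        raise DomainError("empty matrix")

    def grid(getter):
        return pd.DataFrame(
            [[getter(matrix[(r, c)]) for c in matrix.col_labels]
             for r in matrix.row_labels],
            index=matrix.row_labels,
            columns=matrix.col_labels,
        )

    return {
        "mepsp_minus": grid(lambda c: c.summary.mean_mepsp_minus),
        "mepsp_plus": grid(lambda c: c.summary.mean_mepsp_plus),
        "epsp_minus": grid(lambda c: c.summary.mean_epsp_minus),
        "epsp_plus": grid(lambda c: c.summary.mean_epsp_plus),
        "pct_qc_change": grid(lambda c: c.summary.pct_qc_change),
        "php_class": grid(lambda c: classify_php(c.summary.pct_qc_change)),
    }


class InteractionModel:
    """Statsmodels-style wrapper over matrix construction and testing."""

    def __init__(
        self,
        measurements: pd.DataFrame,
        row_labels: Sequence[str],
        col_labels: Sequence[str],
        label_sep: str = ";",
    ):
        self.measurements = measurements
        self.row_labels = list(row_labels)
        self.col_labels = list(col_labels)
        self.label_sep = label_sep

    def fit(
        self,
        rng: np.random.Generator | int | None = 0,
        n_draws: int = 100_000,
        wt_key: tuple[str, str] | None = None,
    ) -> "InteractionResults":
        rng = np.random.default_rng(rng) if not isinstance(
            rng, np.random.Generator
        ) else rng
        matrix = build_matrix(
            self.measurements, self.row_labels, self.col_labels, self.label_sep
        )
        if wt_key is None:
            wt_key = (WILD_TYPE, WILD_TYPE)
        p_wt = (
            dunnett_vs_wt(matrix, rng, wt_key, n_draws)
            if wt_key in matrix.cells
            else {}
        )
        matrix.cells = {
            k: InteractionCell(
                row_label=c.row_label,
                col_label=c.col_label,
                summary=c.summary,
                p_vs_wt=p_wt.get(k),
            )
            for k, c in matrix.cells.items()
        }
        return InteractionResults(self, matrix)


class InteractionResults:
    def __init__(self, model: InteractionModel, matrix: InteractionMatrix):
        self.model = model
        self.matrix = matrix

    def frame(self) -> pd.DataFrame:
        rows = []
        for (r, c), cell in self.matrix.cells.items():
            d = {"row": r, "col": c, **cell.summary.__dict__,
                 "p_vs_wt": cell.p_vs_wt}
            rows.append(d)
        return pd.DataFrame(rows)

    def tables(self) -> dict[str, pd.DataFrame]:
        return export_heatmap_tables(self.matrix)

    def summary(self) -> str:
        cls = self.tables()["php_class"]
        n_blocked = int((cls == "blocked").to_numpy().sum())
        lines = [
            "Genetic interaction matrix",
            f"  {len(self.matrix.row_labels)} rows x "
            f"{len(self.matrix.col_labels)} columns = "
            f"{len(self.matrix.cells)} combinations",
            f"  blocked cells (<15% QC change): {n_blocked}",
            "",
            "Percent QC change (+PhTx vs -PhTx):",
            self.tables()["pct_qc_change"].round(1).to_string(),
            "",
            "PHP class:",
            cls.to_string(),
        ]
        return "\n".join(lines)


__all__ = [
    "WILD_TYPE",
    "pair_label",
    "InteractionCell",
    "InteractionMatrix",
    "build_matrix",
    "within_cell_test",
    "dunnett_max_t_sample",
    "dunnett_adjusted_p",
    "dunnett_vs_wt",
    "export_heatmap_tables",
    "InteractionModel",
    "InteractionResults",
]
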