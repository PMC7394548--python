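"""Core quantal-analysis statistics.

Quantal content (QC) — the number of vesicles released per nerve stimulus —
is estimated per recording as mean EPSP divided by mean mEPSP. Presynaptic
homeostatic plasticity (PHP) is quantified as the percent change in quantal
content with versus without PhTx, and classified into the standard bins:
below 15% change PHP is blocked, 15-30% suppressed, 30% and above intact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError

PHP_BLOCKED_BOUND = 15.0  # % QC change below this: PHP blocked
PHP_SUPPRESSED_BOUND = 30.0  # % QC change in [15, 30): suppressed; >= 30: intact


def quantal_content(epsp_mean: float, mepsp_mean: float) -> float:
    """Quantal content = mean EPSP / mean mEPSP (no nonlinear-summation correction)."""
    if mepsp_mean <= 0:
        raise DomainError(f"mepsp_mean must be > 0 (got {mepsp_mean})")
    return epsp_mean / mepsp_mean


def percent_change(reference: float, treated: float) -> float:
    """Signed percent change of ``treated`` relative to ``reference``."""
    if reference == 0:
        raise DomainError("percent_change undefined for zero reference")
    return 100.0 * (treated - reference) / reference


def classify_php(pct_qc_change: float) -> str:
    """Three-way PHP classification from the percent QC change under PhTx.

    Bin boundaries: values below 15 (including negatives) are ``blocked``,
    exactly 15 up to but excluding 30 are ``suppressed``, 30 and above are
    ``intact``.
    """
    if not math.isfinite(pct_qc_change):
        raise DomainError("pct_qc_change must be finite")
    if pct_qc_change < PHP_BLOCKED_BOUND:
        return "blocked"
    if pct_qc_change < PHP_SUPPRESSED_BOUND:
        return "suppressed"
    return "intact"


@dataclass(frozen=True)
class ScatterFit:
    """OLS line through per-recording (mEPSP, QC) points."""

    slope: float
    intercept: float
    r2: float
    n: int

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass(frozen=True)
class PHPSummary:
    """Per-genotype +/-PhTx summary with percent changes and the PHP class."""

    genotype: str
    n_minus: int
    n_plus: int
    mean_mepsp_minus: float
    mean_mepsp_plus: float
    mean_epsp_minus: float
    mean_epsp_plus: float
    mean_qc_minus: float
    mean_qc_plus: float
    pct_mepsp_change: float
    pct_qc_change: float
    p_qc: float
    php_class: str


def _qc_column(rows: pd.DataFrame) -> pd.Series:
    if "qc" in rows.columns:
        return rows["qc"]
    return rows["epsp_mV"] / rows["mepsp_mV"]


def php_summary(
    rows: pd.DataFrame,
    genotype: str | None = None,
    change_method: str = "ratio_of_means",
    welch: bool = False,
) -> PHPSummary:
    """Summarise one genotype's recordings across PhTx states.

    ``rows`` is a standard measurement table restricted to one genotype with
    both PhTx states present (``phtx`` in {0, 1}). Percent changes are
    computed on genotype means by default (``ratio_of_means``): the ratio of
    the mean QC with PhTx to the mean QC without, minus one, times 100.
    ``mean_of_ratios`` instead averages all pairwise per-recording ratios
    (+PhTx over -PhTx); the two differ when baseline QC is variable.
    ``p_qc`` is a two-tailed two-sample Student's t-test on per-NMJ QC
    across the states (Welch's variant behind the flag).
    """
    if genotype is None:
        labels = rows["genotype"].unique()
        if len(labels) != 1:
            raise DomainError(
                f"php_summary needs a single genotype, got {sorted(labels)}"
            )
        genotype = labels[0]
    else:
        rows = rows[rows["genotype"] == genotype]

    minus = rows[rows["phtx"] == 0]
    plus = rows[rows["phtx"] == 1]
    for state, part in (("-PhTx", minus), ("+PhTx", plus)):
        if len(part) < 2:
            raise DomainError(
                f"genotype {genotype!r} has {len(part)} {state} recordings; "
                "need >= 2 per state"
            )

    qc_minus = _qc_column(minus).to_numpy(dtype=float)
    qc_plus = _qc_column(plus).to_numpy(dtype=float)

    if change_method == "ratio_of_means":
        pct_qc = percent_change(qc_minus.mean(), qc_plus.mean())
    elif change_method == "mean_of_ratios":
        ratios = qc_plus[:, None] / qc_minus[None, :]
        pct_qc = (ratios.mean() - 1.0) * 100.0
    else:
        raise DomainError(f"unknown change_method {change_method!r}")

    pct_mepsp = percent_change(
        minus["mepsp_mV"].mean(), plus["mepsp_mV"].mean()
    )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t = stats.ttest_ind(qc_minus, qc_plus, equal_var=not welch)
    p_qc = float(t.pvalue) if math.isfinite(t.pvalue) else float("nan")

    return PHPSummary(
        genotype=genotype,
        n_minus=len(minus),
        n_plus=len(plus),
        mean_mepsp_minus=float(minus["mepsp_mV"].mean()),
        mean_mepsp_plus=float(plus["mepsp_mV"].mean()),
        mean_epsp_minus=float(minus["epsp_mV"].mean()),
        mean_epsp_plus=float(plus["epsp_mV"].mean()),
        mean_qc_minus=float(qc_minus.mean()),
        mean_qc_plus=float(qc_plus.mean()),
        pct_mepsp_change=float(pct_mepsp),
        pct_qc_change=float(pct_qc),
        p_qc=p_qc,
        php_class=classify_php(float(pct_qc)),
    )


def fit_mepsp_qc(mepsp, qc) -> ScatterFit:
    """OLS fit of quantal content on mEPSP amplitude; r2 = squared Pearson r.

    Homeostatic genotypes show a negative relation (smaller quanta, more of
    them); a blocked genotype abolishes the correlation.
    """
    x = np.asarray(mepsp, dtype=float)
    y = np.asarray(qc, dtype=float)
    if len(x) < 3:
        raise DomainError("fit_mepsp_qc needs at least 3 recordings")
    if np.ptp(x) == 0:
        raise DomainError("fit_mepsp_qc: zero variance in mEPSP values")
    if np.ptp(y) == 0:
        return ScatterFit(slope=0.0, intercept=float(y[0]), r2=0.0, n=len(x))
    res = stats.linregress(x, y)
    return ScatterFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n=len(x),
    )


def summaries_frame(summaries) -> pd.DataFrame:
    """Stack PHPSummary records into the per-genotype summary table."""
    return pd.DataFrame([s.__dict__ for s in summaries])


__all__ = [
    "PHP_BLOCKED_BOUND",
    "PHP_SUPPRESSED_BOUND",
    "ScatterFit",
    "PHPSummary",
    "quantal_content",
    "percent_change",
    "classify_php",
    "php_summary",
    "fit_mepsp_qc",
    "summaries_frame",
]
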