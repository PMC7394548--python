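"""Forward-genetic-screen decision procedure.

A screen measures quantal content under PhTx for a panel of heterozygous
deficiencies combined with a sensitising reference mutation. A genotype is
flagged as disrupting presynaptic homeostatic plasticity by two criteria:

1. *SD criterion* — its mean +PhTx quantal content lies more than one
   standard deviation below the population mean of all genotype means.
2. *Envelope criterion* — its mean (mEPSP, QC) point falls below a reference
   boundary: an OLS centre line fitted to the reference genotype's
   individual +PhTx recordings, offset by empirical residual quantiles so
   the band encompasses (by default) 95% of those recordings.

The criteria are combined with OR by default ("either"), AND behind the
``rule`` flag; both flags are reported per genotype so the call is
auditable. Candidate hits are then triaged with -PhTx data: a baseline
transmission defect (EPSP differs from wild type without PhTx) versus a
selective PHP defect.

``ScreenModel`` wraps the procedure statsmodels-style: construct from a
measurement table, ``fit()`` returns :class:`ScreenResults` with the hit
table, the fitted envelope and a ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .quantal import ScatterFit, fit_mepsp_qc


@dataclass(frozen=True)
class Envelope:
    """Reference boundary in (mEPSP, QC) space.

    ``lower_offset`` / ``upper_offset`` are residual offsets around the OLS
    centre line chosen by order statistics so that at least
    ``coverage_target`` of the fitting points satisfy
    ``lower_offset <= qc - predicted <= upper_offset``.
    """

    center_fit: ScatterFit
    lower_offset: float
    upper_offset: float
    coverage_target: float

    def residual(self, mepsp, qc):
        return np.asarray(qc, dtype=float) - self.center_fit.predict(mepsp)

    def contains(self, mepsp, qc):
        r = self.residual(mepsp, qc)
        return (r >= self.lower_offset) & (r <= self.upper_offset)

    def below(self, mepsp, qc):
        """True where a point lies below the lower boundary (the hit side)."""
        return self.residual(mepsp, qc) < self.lower_offset


@dataclass(frozen=True)
class HitCall:
    genotype: str
    mean_qc_phtx: float
    mean_mepsp_phtx: float
    crit_sd: bool
    crit_envelope: bool
    is_hit: bool
    triage: str  # untested | baseline_defect | php_defect | normal


def criterion_sd(genotype_mean_qc: float, all_genotype_means) -> bool:
    """One-SD population criterion.

    True iff the genotype mean is *more than* one sample SD below the mean
    of all genotype means (the tested genotype included in the population;
    the boundary value itself does not flag).
    """
    means = np.asarray(all_genotype_means, dtype=float)
    if len(means) < 3:
        raise DomainError("criterion_sd needs >= 3 genotype means")
    return bool(genotype_mean_qc < means.mean() - means.std(ddof=1))


def fit_envelope(mepsp, qc, coverage: float = 0.95) -> Envelope:
    """Fit the reference envelope on individual reference recordings.

    The centre line is OLS of QC on mEPSP; the offsets are the residual
    order statistics that leave at most ``floor(n * (1 - coverage))`` points
    outside, split evenly between the two tails, so the band's empirical
    coverage on the fitting data is always >= ``coverage``.
    """
    x = np.asarray(mepsp, dtype=float)
    y = np.asarray(qc, dtype=float)
    if len(x) < 10:
        raise DomainError("fit_envelope needs >= 10 reference recordings")
    if not 0 < coverage <= 1:
        raise DomainError("coverage must be in (0, 1]")
    fit = fit_mepsp_qc(x, y)
    res = np.sort(y - fit.predict(x))
    n = len(res)
    n_out = int(np.floor(n * (1.0 - coverage)))
    n_lo = n_out // 2
    n_hi = n_out - n_lo
    return Envelope(
        center_fit=fit,
        lower_offset=float(res[n_lo]),
        upper_offset=float(res[n - 1 - n_hi]),
        coverage_target=coverage,
    )


def call_hits(
    screen_table: pd.DataFrame,
    reference_label: str,
    rule: str = "either",
    coverage: float = 0.95,
    envelope: Envelope | None = None,
) -> list[HitCall]:
    """Evaluate both screen criteria on every non-reference genotype.

    ``screen_table`` is the standard measurement table; only +PhTx rows are
    used. The envelope is fitted on the reference genotype's individual
    +PhTx recordings unless one is supplied; the SD criterion population is
    the mean +PhTx QC of every genotype in the table (reference included).
    """
    if rule not in ("either", "both"):
        raise DomainError(f"rule must be 'either' or 'both', got {rule!r}")
    plus = screen_table[screen_table["phtx"] == 1].copy()
    if reference_label not in set(plus["genotype"]):
        raise DomainError(
            f"reference genotype {reference_label!r} has no +PhTx recordings"
        )
    plus["qc"] = plus["epsp_mV"] / plus["mepsp_mV"]

    counts = plus.groupby("genotype").size()
    thin = counts[counts < 3]
    if len(thin):
        raise DomainError(
            "genotypes with fewer than 3 +PhTx recordings: "
            + ", ".join(sorted(thin.index))
        )

    if envelope is None:
        ref = plus[plus["genotype"] == reference_label]
        envelope = fit_envelope(ref["mepsp_mV"], ref["qc"], coverage)

    means = plus.groupby("genotype").agg(
        qc=("qc", "mean"), mepsp=("mepsp_mV", "mean")
    )
    all_means = means["qc"].to_numpy()

    calls = []
    for geno, row in means.iterrows():
        if geno == reference_label:
            continue
        c_sd = criterion_sd(row["qc"], all_means)
        c_env = bool(envelope.below(row["mepsp"], row["qc"]))
        is_hit = (c_sd or c_env) if rule == "either" else (c_sd and c_env)
        calls.append(
            HitCall(
                genotype=str(geno),
                mean_qc_phtx=float(row["qc"]),
                mean_mepsp_phtx=float(row["mepsp"]),
                crit_sd=c_sd,
                crit_envelope=c_env,
                is_hit=is_hit,
                triage="untested" if is_hit else "normal",
            )
        )
    return calls


def triage(
    candidate: str,
    minus_phtx_rows: pd.DataFrame,
    wild_type_rows: pd.DataFrame,
    alpha: float = 0.05,
) -> str:
    """Classify a candidate hit as a baseline defect or a selective PHP defect.

    Compares the candidate's -PhTx EPSP amplitudes against wild type with a
    two-tailed Student's t-test: a significant difference means the genotype
    impairs baseline transmission; otherwise baseline is normal and the PHP
    failure is selective.
    """
    cand = minus_phtx_rows[minus_phtx_rows["genotype"] == candidate]
    if len(cand) < 2:
        warnings.warn(
            f"candidate {candidate!r} lacks -PhTx recordings; triage untested",
            stacklevel=2,
        )
        return "untested"
    wt = wild_type_rows[wild_type_rows["phtx"] == 0]
    t = stats.ttest_ind(
        cand["epsp_mV"].to_numpy(), wt["epsp_mV"].to_numpy(), equal_var=True
    )
    return "baseline_defect" if t.pvalue < alpha else "php_defect"


def gene_count_correlation(deficiency_table: pd.DataFrame) -> ScatterFit:
    """OLS of +PhTx quantal content on the number of genes each deficiency deletes.

    The screen's design check: hit probability should not scale with
    deficiency size, so r2 is expected to be near zero.
    """
    n_def = deficiency_table["n_genes_deleted"].nunique()
    if deficiency_table["genotype"].nunique() < 3:
        raise DomainError("gene_count_correlation needs >= 3 deficiencies")
    if n_def < 2:
        raise DomainError("gene counts are constant; correlation undefined")
    return fit_mepsp_qc(
        deficiency_table["n_genes_deleted"], deficiency_table["qc_phtx"]
    )


def hit_calls_frame(calls) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])


class ScreenModel:
    """Hit-calling model over a screen measurement table.

    Parameters
    ----------
    measurements : DataFrame
        Standard measurement table (both PhTx states).
    reference : str
        Reference genotype label whose recordings define the envelope.
    """

    def __init__(self, measurements: pd.DataFrame, reference: str):
        self.measurements = measurements
        self.reference = reference

    def fit(
        self, coverage: float = 0.95, rule: str = "either", triage_alpha: float = 0.05
    ) -> "ScreenResults":
        plus = self.measurements[self.measurements["phtx"] == 1]
        ref = plus[plus["genotype"] == self.reference]
        envelope = fit_envelope(
            ref["mepsp_mV"], ref["epsp_mV"] / ref["mepsp_mV"], coverage
        )
        calls = call_hits(
            self.measurements, self.reference, rule=rule, envelope=envelope
        )
        minus = self.measurements[self.measurements["phtx"] == 0]
        wt_rows = self.measurements[
            self.measurements["genotype"] == self.reference
        ]
        triaged = []
        for c in calls:
            if c.is_hit:
                verdict = triage(c.genotype, minus, wt_rows, alpha=triage_alpha)
                c = HitCall(**{**c.__dict__, "triage": verdict})
            triaged.append(c)
        return ScreenResults(self, envelope, triaged, rule=rule, coverage=coverage)


class ScreenResults:
    """Fitted screen: envelope, per-genotype hit calls, summary table."""

    def __init__(self, model, envelope, calls, rule, coverage):
        self.model = model
        self.envelope = envelope
        self.calls = calls
        self.rule = rule
        self.coverage = coverage

    @property
    def hits(self) -> list[HitCall]:
        return [c for c in self.calls if c.is_hit]

    def frame(self) -> pd.DataFrame:
        return hit_calls_frame(self.calls)

    def summary(self) -> str:
        df = self.frame()
        lines = [
            "Forward genetic screen",
            f"  reference genotype: {self.model.reference}",
            f"  envelope coverage:  {self.coverage:.2f}"
            f"  (offsets {self.envelope.lower_offset:+.2f} /"
            f" {self.envelope.upper_offset:+.2f})",
            f"  combination rule:   {self.rule}",
            f"  genotypes tested:   {len(df)}    hits: {len(self.hits)}",
            "",
            df.to_string(index=False, float_format=lambda v: f"{v:.2f}"),
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Screen scatter: genotype mean (mEPSP, QC) points over the
        reference envelope; hits drawn in red."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.frame()
        xs = np.linspace(df["mean_mepsp_phtx"].min(), df["mean_mepsp_phtx"].max(), 50)
        center = self.envelope.center_fit.predict(xs)
        ax.plot(xs, center, "b-", lw=1, label="reference fit")
        for off in (self.envelope.lower_offset, self.envelope.upper_offset):
            ax.plot(xs, center + off, "b:", lw=1)
        normal = df[~df["is_hit"]]
        hits = df[df["is_hit"]]
        ax.scatter(normal["mean_mepsp_phtx"], normal["mean_qc_phtx"],
                   c="gold", edgecolors="k", label="tested")
        ax.scatter(hits["mean_mepsp_phtx"], hits["mean_qc_phtx"],
                   c="red", edgecolors="k", label="hit")
        ax.set_xlabel("mEPSP (mV), +PhTx")
        ax.set_ylabel("quantal content, +PhTx")
        ax.legend(frameon=False)
        return ax


__all__ = [
    "Envelope",
    "HitCall",
    "criterion_sd",
    "fit_envelope",
    "call_hits",
    "triage",
    "gene_count_correlation",
    "hit_calls_frame",
    "ScreenModel",
    "ScreenResults",
]
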