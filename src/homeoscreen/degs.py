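"""Count-data filtering, differential expression, and synergy selection.

The differential-expression test is a deliberately simple negative-binomial
Wald test — median-of-ratios size-factor normalisation, per-gene
method-of-moments dispersion with a floor, and a log-linear model with batch
as covariate, fitted by vectorised IRLS across all genes at once. It is not
a re-implementation of DESeq2/limma; it exists so the selection logic built
on top of it (CPM filtering, the FDR < 0.05 and +/-50% fold-change call,
exclusive intersections, and the double-mutant synergy selection) runs on
honestly calibrated p-values.

Synergy selection: a gene is "synergistically differentially expressed" in
a double heterozygote when it is called DE — same direction — against all
three controls (wild type and each single heterozygote).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, SchemaError

DISPERSION_FLOOR = 0.01
DISPERSION_CAP = 10.0
_PSEUDOCOUNT = 0.5


# ---------------------------------------------------------------------------
# filtering and normalisation


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million, per sample (columns)."""
    lib = counts.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise SchemaError(f"zero library size for sample(s): {list(zero.index)}")
    return counts / lib * 1e6


def cpm_filter(counts: pd.DataFrame, threshold: float = 5.0) -> pd.DataFrame:
    """Drop genes whose CPM is below ``threshold`` in *every* sample.

    A gene at exactly the threshold in at least one sample is kept; all-zero
    genes are always dropped.
    """
    keep = ((cpm(counts) >= threshold) & (counts > 0)).any(axis=1)
    out = counts.loc[keep]
    if out.empty:
        warnings.warn("no gene passes the CPM filter", stacklevel=2)
    return out


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference)."""
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if positive.sum() < 1:
        lib = counts.sum(axis=0).astype(float)
        return lib / np.exp(np.mean(np.log(lib)))
    loggeo = np.mean(np.log(arr[positive]), axis=1)
    sf = np.exp(np.median(np.log(arr[positive]) - loggeo[:, None], axis=0))
    return pd.Series(sf, index=counts.columns)


# ---------------------------------------------------------------------------
# the NB Wald test


def _design_matrix(design: pd.DataFrame, test: str, ref: str):
    """[intercept, genotype, batch dummies] for the two-genotype subset."""
    sub = design[design["genotype"].isin([test, ref])].reset_index(drop=True)
    for side in (test, ref):
        if (sub["genotype"] == side).sum() < 2:
            raise DomainError(f"contrast side {side!r} has fewer than 2 samples")
    geno = (sub["genotype"] == test).to_numpy(dtype=float)
    batches = pd.get_dummies(sub["batch"], drop_first=True, dtype=float)
    X = np.column_stack([np.ones(len(sub)), geno, batches.to_numpy()])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DomainError(
            "design is confounded: genotype and batch are not separable"
        )
    return sub, X


def _mom_dispersion(norm: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Pooled within-group method-of-moments NB dispersion per gene."""
    G = norm.shape[0]
    num = np.zeros(G)
    den = 0.0
    mean_all = np.zeros(G)
    wsum = 0.0
    for g in np.unique(groups):
        cols = norm[:, groups == g]
        n = cols.shape[1]
        if n < 2:
            continue
        num += (n - 1) * cols.var(axis=1, ddof=1)
        den += n - 1
        mean_all += n * cols.mean(axis=1)
        wsum += n
    if den == 0:
        return np.full(G, DISPERSION_FLOOR)
    pooled_var = num / den
    mean = np.where(wsum > 0, mean_all / max(wsum, 1), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mean) / mean**2
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    return np.clip(alpha, DISPERSION_FLOOR, DISPERSION_CAP)


def _trended_dispersion(
    alpha: np.ndarray, mean_norm: np.ndarray, n_bins: int = 20
) -> np.ndarray:
    """Median dispersion within log-mean bins — the cross-gene trend.

    Gene-wise moment estimates on few replicates are noisy; the final
    dispersion is the gene-wise estimate floored at this trend, so a gene
    never borrows a *smaller* dispersion than its expression stratum
    supports (guarding the Wald test against anti-conservative per-gene
    underestimates).
    """
    lm = np.log1p(mean_norm)
    edges = np.quantile(lm, np.linspace(0, 1, n_bins + 1))
    idx = np.clip(np.digitize(lm, edges[1:-1]), 0, n_bins - 1)
    out = np.empty_like(alpha)
    overall = np.median(alpha)
    for b in range(n_bins):
        mask = idx == b
        out[mask] = np.median(alpha[mask]) if mask.any() else overall
    return out


def _irls_nb(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: np.ndarray,
    max_iter: int = 50, tol: float = 1e-8,
):
    """Vectorised per-gene NB log-linear IRLS; returns (beta, cov)."""
    G, n = y.shape
    p = X.shape[1]
    beta = np.linalg.lstsq(
        X, (np.log(y + _PSEUDOCOUNT) - offset).T, rcond=None
    )[0].T  # G x p
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T + offset, -30, 30)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha[:, None] * mu)
        z = eta - offset + (y - mu) / mu
        A = np.einsum("gn,np,nq->gpq", W, X, X)
        b = np.einsum("gn,np->gp", W * z, X)
        new = np.linalg.solve(A, b[..., None])[..., 0]
        delta = np.abs(new - beta).max()
        beta = new
        if delta < tol:
            break
    eta = np.clip(beta @ X.T + offset, -30, 30)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha[:, None] * mu)
    A = np.einsum("gn,np,nq->gpq", W, X, X)
    cov = np.linalg.inv(A)
    return beta, cov


def per_gene_test(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    contrast: tuple[str, str],
    dispersion_floor: float = DISPERSION_FLOOR,
) -> pd.DataFrame:
    """Per-gene NB Wald test of ``contrast = (test, reference)``.

    Returns a DataFrame indexed by gene with ``log2fc`` (on size-factor
    normalised group means) and ``p`` (two-sided Wald, normal reference;
    the trend-floored dispersion keeps it calibrated at small n). Batch
    enters the model as a covariate.
    """
    test, ref = contrast
    sub, X = _design_matrix(design, test, ref)
    cols = sub["sample"].tolist()
    missing = [s for s in cols if s not in counts.columns]
    if missing:
        raise SchemaError(f"samples missing from count matrix: {missing}")
    y = counts[cols].to_numpy(dtype=float)
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise SchemaError("count matrix must hold non-negative integers")

    sf = size_factors(counts[cols]).to_numpy()
    norm = y / sf
    group_codes = (
        sub["genotype"].astype(str) + "//" + sub["batch"].astype(str)
    ).to_numpy()
    alpha = _mom_dispersion(norm, group_codes)
    alpha = np.maximum(alpha, _trended_dispersion(alpha, norm.mean(axis=1)))
    alpha = np.maximum(alpha, dispersion_floor)

    beta, cov = _irls_nb(y, X, np.log(sf), alpha)
    se = np.sqrt(np.maximum(cov[:, 1, 1], 1e-300))
    wald = beta[:, 1] / se
    p = 2.0 * stats.norm.sf(np.abs(wald))

    is_test = (sub["genotype"] == test).to_numpy()
    m_test = norm[:, is_test].mean(axis=1)
    m_ref = norm[:, ~is_test].mean(axis=1)
    log2fc = np.log2((m_test + _PSEUDOCOUNT) / (m_ref + _PSEUDOCOUNT))

    zero_change = np.isclose(m_test, m_ref) & np.isclose(beta[:, 1], 0, atol=1e-6)
    p = np.where(zero_change, 1.0, p)
    return pd.DataFrame(
        {"log2fc": log2fc, "p": np.clip(p, 0, 1)},
        index=counts.index.copy(),
    )


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR values, in input order."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def deg_call(
    results: pd.DataFrame, fdr_cut: float = 0.05, fc_cut: float = 1.5
) -> pd.DataFrame:
    """Flag DEGs at FDR < ``fdr_cut`` and fold change >= ``fc_cut`` (or <= 1/fc).

    The fold-change boundary passes (>= 1.5x counts as a 50% change); the
    FDR boundary fails (strictly below 0.05).
    """
    out = results.copy()
    if "fdr" not in out.columns:
        out["fdr"] = bh_adjust(out["p"].to_numpy())
    fold = 2.0 ** out["log2fc"].to_numpy()
    big = (fold >= fc_cut) | (fold <= 1.0 / fc_cut)
    out["is_deg"] = (out["fdr"].to_numpy() < fdr_cut) & big
    return out


# ---------------------------------------------------------------------------
# intersections and synergy


@dataclass(frozen=True)
class IntersectionSet:
    """One exclusive intersection: genes DE in exactly this set of contrasts."""

    signature: tuple[str, ...]
    genes: tuple[str, ...]
    n_up: int | None = None
    n_down: int | None = None

    @property
    def size(self) -> int:
        return len(self.genes)


def upset_intersections(
    deg_sets: Mapping[str, set],
    directions: Mapping[str, Mapping[str, float]] | None = None,
) -> list[IntersectionSet]:
    """Exclusive intersections of DEG sets (UpSet-style).

    Every gene in the union is assigned to exactly one signature — the set
    of contrasts that call it — so the sizes sum to the union size. When
    per-contrast ``directions`` (gene -> signed log2fc) are supplied, each
    intersection is split into consistently-up / consistently-down counts.
    """
    if not deg_sets:
        raise DomainError("upset_intersections needs at least one set")
    names = list(deg_sets)
    by_sig: dict[tuple[str, ...], list[str]] = {}
    for gene in set().union(*deg_sets.values()):
        sig = tuple(n for n in names if gene in deg_sets[n])
        by_sig.setdefault(sig, []).append(gene)
    out = []
    for sig, genes in by_sig.items():
        n_up = n_down = None
        if directions is not None:
            signs = [
                [np.sign(directions[n].get(g, 0.0)) for n in sig] for g in genes
            ]
            n_up = sum(all(s > 0 for s in ss) for ss in signs)
            n_down = sum(all(s < 0 for s in ss) for ss in signs)
        out.append(
            IntersectionSet(
                signature=sig, genes=tuple(sorted(genes)), n_up=n_up, n_down=n_down
            )
        )
    return sorted(out, key=lambda s: (-s.size, s.signature))


def synergy_select(
    deg_vs_wt: pd.DataFrame,
    deg_vs_single_a: pd.DataFrame,
    deg_vs_single_b: pd.DataFrame,
) -> pd.DataFrame:
    """Genes DE in the double mutant against *all three* controls, same sign.

    Each input is a called DEG table (``log2fc``, ``is_deg``) for the double
    mutant versus one control, over a shared gene universe. Selected genes
    are DE in every contrast with a consistent direction; the returned table
    carries the direction and the log2fc of the vs-wild-type contrast.
    """
    frames = [deg_vs_wt, deg_vs_single_a, deg_vs_single_b]
    universe = frames[0].index
    for f in frames[1:]:
        if not universe.equals(f.index):
            raise DomainError("synergy_select: contrasts differ in gene universe")
    all_deg = np.logical_and.reduce([f["is_deg"].to_numpy() for f in frames])
    signs = np.sign(np.column_stack([f["log2fc"].to_numpy() for f in frames]))
    consistent = (signs == signs[:, :1]).all(axis=1) & (signs[:, 0] != 0)
    sel = all_deg & consistent
    return pd.DataFrame(
        {
            "log2fc_vs_wt": deg_vs_wt["log2fc"].to_numpy()[sel],
            "direction": np.where(signs[sel, 0] > 0, "up", "down"),
        },
        index=universe[sel],
    )


def ddct(records: pd.DataFrame, control_group: str = "control") -> pd.DataFrame:
    """Comparative-Ct qPCR fold changes per test group.

    ``records`` columns: ``sample``, ``group``, ``ct_target``,
    ``ct_reference``. Per sample dCt = Ct(target) - Ct(reference); per group
    ddCt = mean dCt(test) - mean dCt(control); fold change = 2^(-ddCt).
    """
    req = {"sample", "group", "ct_target", "ct_reference"}
    if not req <= set(records.columns):
        raise SchemaError(f"qPCR table must have columns {sorted(req)}")
    if records[["ct_target", "ct_reference"]].isna().any().any():
        raise SchemaError("missing Ct value in qPCR table")
    df = records.copy()
    df["dct"] = df["ct_target"] - df["ct_reference"]
    if control_group not in set(df["group"]):
        raise DomainError(f"no records for control group {control_group!r}")
    ctrl = df.loc[df["group"] == control_group, "dct"].mean()
    rows = []
    for group, part in df[df["group"] != control_group].groupby("group"):
        ddct_val = part["dct"].mean() - ctrl
        rows.append(
            {"group": group, "ddct": ddct_val, "fold_change": 2.0 ** (-ddct_val)}
        )
    return pd.DataFrame(rows, columns=["group", "ddct", "fold_change"])


# ---------------------------------------------------------------------------
# model facade


class NBExpressionModel:
    """Count matrix + design, fitted per contrast into :class:`DEResults`."""

    def __init__(
        self,
        counts: pd.DataFrame,
        design: pd.DataFrame,
        cpm_threshold: float | None = None,
    ):
        missing = set(counts.columns) - set(design["sample"])
        if missing:
            raise SchemaError(f"design missing samples: {sorted(missing)}")
        self.counts = (
            cpm_filter(counts, cpm_threshold) if cpm_threshold is not None else counts
        )
        self.design = design

    def fit(
        self,
        contrast: tuple[str, str],
        fdr_cut: float = 0.05,
        fc_cut: float = 1.5,
    ) -> "DEResults":
        table = per_gene_test(self.counts, self.design, contrast)
        table = deg_call(table, fdr_cut=fdr_cut, fc_cut=fc_cut)
        return DEResults(self, contrast, table, fdr_cut, fc_cut)


class DEResults:
    def __init__(self, model, contrast, table, fdr_cut, fc_cut):
        self.model = model
        self.contrast = contrast
        self.table = table
        self.fdr_cut = fdr_cut
        self.fc_cut = fc_cut

    @property
    def degs(self) -> pd.Index:
        return self.table.index[self.table["is_deg"]]

    def summary(self) -> str:
        t = self.table
        up = int(((t["is_deg"]) & (t["log2fc"] > 0)).sum())
        down = int(((t["is_deg"]) & (t["log2fc"] < 0)).sum())
        return "\n".join(
            [
                f"Differential expression: {self.contrast[0]} vs {self.contrast[1]}",
                f"  genes tested: {len(t)}",
                f"  DEGs (FDR < {self.fdr_cut}, fold >= {self.fc_cut}x): "
                f"{up + down}  ({up} up, {down} down)",
            ]
        )


__all__ = [
    "cpm",
    "cpm_filter",
    "size_factors",
    "per_gene_test",
    "bh_adjust",
    "deg_call",
    "IntersectionSet",
    "upset_intersections",
    "synergy_select",
    "ddct",
    "NBExpressionModel",
    "DEResults",
]
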