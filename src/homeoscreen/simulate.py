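"""Synthetic data generators for the whole pipeline.

Every input the analysis stages consume can be generated here from a seeded
`numpy.random.Generator`: per-NMJ quantal summaries, raw voltage traces with
planted miniature and evoked events, multi-deficiency screen collections with
known hits, and negative-binomial count matrices with planted (including
double-mutant-specific) differential expression.

Quantal model
-------------
Per NMJ, quantal size q and quantal content QC are drawn from gamma
distributions parameterised by (mean, CV) — strictly positive and
right-skewed, like miniature amplitude histograms. PhTx scales q by
``phtx_scale`` (the receptor antagonist shrinks the postsynaptic response to
one vesicle) and scales QC by ``1 + compensation * (1/phtx_scale - 1)``:
with compensation 1 the expected EPSP is identical with and without PhTx
(full homeostatic compensation), with 0 it scales by ``phtx_scale``.
The noise-free identities hold exactly: EPSP = QC x q, and the percent
change in QC under PhTx is ``(1/phtx_scale - 1) * compensation * 100``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .params import CountSimSpec, GenotypeParams, TraceSpec

MEASUREMENT_COLUMNS = [
    "genotype",
    "nmj_id",
    "phtx",
    "mepsp_mV",
    "epsp_mV",
    "vm_mV",
    "rin_MOhm",
]

# Plausible larval muscle passive properties; cosmetic columns only.
_VM_MEAN, _VM_SD = -70.0, 2.0
_RIN_MEAN, _RIN_SD = 8.0, 1.0


@dataclass(frozen=True)
class SimulatedNMJ:
    """One simulated muscle recording with its ground truth."""

    genotype: str
    nmj_id: str
    phtx: bool
    true_q: float
    true_qc: float
    mepsp_mean: float
    epsp_mean: float


def _gamma_draw(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Positive draw with the given mean and CV; degenerate when cv == 0."""
    if cv == 0:
        return mean
    shape = 1.0 / cv**2
    return float(rng.gamma(shape, mean / shape))


def sample_nmj(
    params: GenotypeParams,
    phtx: bool,
    rng: np.random.Generator,
    nmj_id: str = "nmj1",
) -> SimulatedNMJ:
    """Draw one NMJ recording summary from a genotype's ground truth.

    With PhTx the true quantal size is scaled by ``phtx_scale`` and the true
    quantal content by ``1 + compensation * (1/phtx_scale - 1)``. The
    reported EPSP mean carries multiplicative measurement noise with CV
    ``meas_cv``; the reported mEPSP mean equals the true quantal size.
    """
    true_q = _gamma_draw(rng, params.q_mean, params.q_cv)
    true_qc = _gamma_draw(rng, params.qc_mean, params.qc_cv)
    if phtx:
        true_q *= params.phtx_scale
        true_qc *= 1.0 + params.compensation * (1.0 / params.phtx_scale - 1.0)
    noise = 1.0 + params.meas_cv * rng.standard_normal() if params.meas_cv else 1.0
    epsp = true_qc * true_q * max(noise, 1e-6)
    return SimulatedNMJ(
        genotype=params.name,
        nmj_id=nmj_id,
        phtx=bool(phtx),
        true_q=true_q,
        true_qc=true_qc,
        mepsp_mean=true_q,
        epsp_mean=epsp,
    )


def simulate_genotype(
    params: GenotypeParams,
    n_per_state: int,
    rng: np.random.Generator,
    states: Sequence[bool] = (False, True),
) -> pd.DataFrame:
    """Measurement table for one genotype, ``n_per_state`` NMJs per PhTx state."""
    rows = []
    for phtx in states:
        for i in range(n_per_state):
            tag = "p" if phtx else "b"
            nmj = sample_nmj(params, phtx, rng, nmj_id=f"{params.name}_{tag}{i + 1}")
            rows.append(_nmj_row(nmj, rng))
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def _nmj_row(nmj: SimulatedNMJ, rng: np.random.Generator) -> dict:
    return {
        "genotype": nmj.genotype,
        "nmj_id": nmj.nmj_id,
        "phtx": int(nmj.phtx),
        "mepsp_mV": nmj.mepsp_mean,
        "epsp_mV": nmj.epsp_mean,
        "vm_mV": _VM_MEAN + _VM_SD * rng.standard_normal(),
        "rin_MOhm": max(_RIN_MEAN + _RIN_SD * rng.standard_normal(), 0.5),
    }


# ---------------------------------------------------------------------------
# voltage traces


def event_kernel(spec: TraceSpec) -> np.ndarray:
    """Unit-peak difference-of-exponentials kernel sampled at the trace rate."""
    dt_ms = 1000.0 / spec.sampling_rate
    length = int(round(8 * spec.decay_tau / dt_ms)) + 1
    t = np.arange(length) * dt_ms
    k = np.exp(-t / spec.decay_tau) - np.exp(-t / spec.rise_tau)
    return k / k.max()


def synth_trace(
    nmj: SimulatedNMJ,
    spec: TraceSpec,
    rng: np.random.Generator,
    mini_rate: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Voltage trace with planted miniature and evoked events.

    Returns ``(trace, events)``: the trace as a two-column DataFrame
    (``time_s``, ``voltage_mV``) of Gaussian baseline noise plus planted
    events, and the ground-truth event table (``time_s``, ``amplitude_mV``,
    ``kind``). Miniature times are Poisson with rate ``mini_rate`` and
    amplitudes gamma-distributed around the NMJ's true quantal size; one
    evoked event of amplitude ``true_qc * true_q`` is planted at each
    stimulus time.
    """
    n = int(round(spec.duration * spec.sampling_rate))
    if spec.stimulus_times:
        guard = 10 * spec.decay_tau / 1000.0
        if max(spec.stimulus_times) > spec.duration - guard:
            raise DomainError(
                "stimulus within 10 decay constants of the trace end; "
                "evoked response would be truncated"
            )
    kernel = event_kernel(spec)
    v = (
        rng.standard_normal(n) * spec.baseline_noise_sd
        if spec.baseline_noise_sd
        else np.zeros(n)
    )

    events: list[tuple[float, float, str]] = []
    n_minis = rng.poisson(mini_rate * spec.duration) if mini_rate > 0 else 0
    margin = len(kernel) / spec.sampling_rate
    mini_times = np.sort(rng.uniform(0, spec.duration - margin, size=n_minis))
    for t0 in mini_times:
        amp = _gamma_draw(rng, nmj.true_q, 0.15)
        _add_event(v, kernel, t0, amp, spec.sampling_rate)
        events.append((float(t0), amp, "mini"))
    evoked_amp = nmj.true_qc * nmj.true_q
    for t0 in spec.stimulus_times:
        _add_event(v, kernel, t0, evoked_amp, spec.sampling_rate)
        events.append((float(t0), evoked_amp, "evoked"))

    trace = pd.DataFrame(
        {"time_s": np.arange(n) / spec.sampling_rate, "voltage_mV": v}
    )
    truth = pd.DataFrame(events, columns=["time_s", "amplitude_mV", "kind"])
    return trace, truth.sort_values("time_s", ignore_index=True)


def _add_event(
    v: np.ndarray, kernel: np.ndarray, t0: float, amplitude: float, fs: float
) -> None:
    i0 = int(round(t0 * fs))
    seg = kernel[: len(v) - i0]
    v[i0 : i0 + len(seg)] += amplitude * seg


def write_trace(path_prefix, trace: pd.DataFrame, truth: pd.DataFrame, spec: TraceSpec) -> None:
    """Write ``<prefix>.csv`` (time_s, voltage_mV) and a ``.json`` sidecar."""
    trace.to_csv(f"{path_prefix}.csv", index=False)
    sidecar = {
        "sampling_rate": spec.sampling_rate,
        "stimulus_times": list(spec.stimulus_times),
        "events": truth.to_dict(orient="records"),
    }
    with open(f"{path_prefix}.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


# ---------------------------------------------------------------------------
# genetic screen

HIT_COMPENSATION_THRESHOLD = 0.5  # ground-truth convention: h below this is a hit


def simulate_screen(
    reference: GenotypeParams,
    deficiencies: Sequence[tuple[str, int, GenotypeParams]],
    n_per_genotype: int,
    rng: np.random.Generator,
    n_reference: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a deficiency screen: measurement table plus truth table.

    Each deficiency is a ``(label, n_genes_deleted, params)`` triple; the
    measurement table holds reference and deficiency recordings in both PhTx
    states. The truth table marks a deficiency a hit iff its compensation is
    below ``HIT_COMPENSATION_THRESHOLD`` — the planted convention for "PHP
    disrupted". ``n_reference`` lets the reference genotype be recorded more
    densely than the candidates (screens typically do), default
    ``max(n_per_genotype, 20)``.
    """
    if n_per_genotype < 3:
        raise ConfigurationError("n_per_genotype must be >= 3")
    labels = [lab for lab, _, _ in deficiencies]
    if len(set(labels)) != len(labels) or reference.name in labels:
        raise ConfigurationError("duplicate genotype labels in screen")
    if n_reference is None:
        n_reference = max(n_per_genotype, 20)

    tables = [simulate_genotype(reference, n_reference, rng)]
    truth_rows = []
    for label, n_genes, params in deficiencies:
        if params.name != label:
            params = GenotypeParams(**{**params.__dict__, "name": label})
        tables.append(simulate_genotype(params, n_per_genotype, rng))
        truth_rows.append(
            {
                "genotype": label,
                "n_genes_deleted": int(n_genes),
                "compensation": params.compensation,
                "is_hit": params.compensation < HIT_COMPENSATION_THRESHOLD,
            }
        )
    table = pd.concat(tables, ignore_index=True)
    truth = pd.DataFrame(
        truth_rows, columns=["genotype", "n_genes_deleted", "compensation", "is_hit"]
    )
    return table, truth


# ---------------------------------------------------------------------------
# count matrices


def simulate_counts(
    spec: CountSimSpec, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix with planted differential expression.

    Returns ``(counts, design, truth)``. Counts are genes x samples with
    mean ``baseline * 2^(batch effect + genotype log2FC [+ synergy log2FC in
    the double mutant])`` and NB dispersion ``nb_dispersion``. The truth
    table lists every gene with a nonzero planted log2FC per
    genotype-vs-control contrast.
    """
    genotype_of = {s: g for s, g, _ in spec.samples}
    counts_per_geno = pd.Series(genotype_of).value_counts()
    if (counts_per_geno < 2).any():
        raise ConfigurationError("every genotype needs >= 2 samples")
    if spec.control in spec.de_spec:
        raise ConfigurationError(
            "de_spec may not plant fold changes in the control genotype"
        )

    genes = spec.gene_ids
    n_genes, n_samples = len(genes), len(spec.samples)
    base = spec.baseline_mean * 2.0 ** (
        rng.standard_normal(n_genes) * spec.baseline_log2_sd
    )

    batches = sorted({b for _, _, b in spec.samples})
    batch_fx = {
        b: (rng.standard_normal(n_genes) * spec.batch_log2_sd if i else np.zeros(n_genes))
        for i, b in enumerate(batches)
    }

    lfc = {g: np.zeros(n_genes) for g in {g for _, g, _ in spec.samples}}
    gene_index = {g: i for i, g in enumerate(genes)}
    truth_rows = []
    for geno, (gene_set, fold) in spec.de_spec.items():
        for g in gene_set:
            lfc[geno][gene_index[g]] += fold
    if spec.synergy_spec is not None:
        gene_set, fold = spec.synergy_spec
        for g in gene_set:
            lfc[spec.double_genotype][gene_index[g]] += fold

    control = spec.control
    for geno, arr in lfc.items():
        if geno == control:
            continue
        planted = np.nonzero(arr)[0]
        for i in planted:
            truth_rows.append(
                {"contrast": f"{geno}_vs_{control}", "gene": genes[i], "log2fc": arr[i]}
            )

    mat = np.empty((n_genes, n_samples), dtype=np.int64)
    size = 1.0 / spec.nb_dispersion
    for j, (sample, geno, batch) in enumerate(spec.samples):
        mu = base * 2.0 ** (batch_fx[batch] + lfc[geno])
        p = size / (size + mu)
        mat[:, j] = rng.negative_binomial(size, p)

    counts = pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"),
                          columns=[s for s, _, _ in spec.samples])
    design = pd.DataFrame(
        [{"sample": s, "genotype": g, "batch": b} for s, g, b in spec.samples]
    )
    truth = pd.DataFrame(truth_rows, columns=["contrast", "gene", "log2fc"])
    return counts, design, truth


def expected_pct_qc_change(params: GenotypeParams) -> float:
    """Closed-form percent change in quantal content under PhTx."""
    return (1.0 / params.phtx_scale - 1.0) * params.compensation * 100.0


__all__ = [
    "MEASUREMENT_COLUMNS",
    "HIT_COMPENSATION_THRESHOLD",
    "SimulatedNMJ",
    "sample_nmj",
    "simulate_genotype",
    "event_kernel",
    "synth_trace",
    "write_trace",
    "simulate_screen",
    "simulate_counts",
    "expected_pct_qc_change",
]
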