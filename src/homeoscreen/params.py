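"""Parameter containers for the quantal-release and count-data simulators.

``GenotypeParams`` is the ground truth one simulated genotype is drawn from:
the quantal size ``q_mean`` (mean miniature amplitude, mV), the quantal
content ``qc_mean`` (vesicles per stimulus), the PhTx effect ``phtx_scale``
(multiplicative scaling of quantal size under the glutamate-receptor
antagonist), and the homeostatic ``compensation`` level. Compensation 1 means
quantal content rises exactly enough to restore the expected EPSP under PhTx
(full presynaptic homeostatic plasticity); 0 means no compensation at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ConfigurationError


@dataclass(frozen=True)
class GenotypeParams:
    """Simulator ground truth for one genotype.

    Parameters
    ----------
    name : str
        Genotype label.
    q_mean : float
        Mean miniature amplitude (quantal size), mV. Must be positive.
    q_cv : float
        Coefficient of variation of quantal size across NMJs.
    qc_mean : float
        Mean quantal content (vesicles released per stimulus).
    qc_cv : float
        Coefficient of variation of quantal content across NMJs.
    phtx_scale : float
        Multiplicative effect of PhTx on quantal size, in (0, 1].
    compensation : float
        Homeostatic compensation level h >= 0. Under PhTx the quantal
        content is scaled by ``1 + h * (1/phtx_scale - 1)``, so h = 1
        restores the expected EPSP exactly and h = 0 leaves release
        unchanged.
    mini_rate : float
        Spontaneous miniature event rate, events/s (trace synthesis).
    meas_cv : float
        Multiplicative measurement noise CV on the evoked EPSP.
    """

    name: str
    q_mean: float = 0.5
    q_cv: float = 0.2
    qc_mean: float = 40.0
    qc_cv: float = 0.2
    phtx_scale: float = 0.5
    compensation: float = 1.0
    mini_rate: float = 2.0
    meas_cv: float = 0.05

    def __post_init__(self) -> None:
        checks = [
            ("q_mean", self.q_mean > 0, "must be > 0"),
            ("qc_mean", self.qc_mean > 0, "must be > 0"),
            ("phtx_scale", 0 < self.phtx_scale <= 1, "must be in (0, 1]"),
            ("compensation", self.compensation >= 0, "must be >= 0"),
            ("q_cv", self.q_cv >= 0, "must be >= 0"),
            ("qc_cv", self.qc_cv >= 0, "must be >= 0"),
            ("meas_cv", self.meas_cv >= 0, "must be >= 0"),
            ("mini_rate", self.mini_rate >= 0, "must be >= 0"),
        ]
        for fname, ok, msg in checks:
            if not ok:
                raise ConfigurationError(
                    f"GenotypeParams.{fname} {msg} (got {getattr(self, fname)!r})"
                )


@dataclass(frozen=True)
class TraceSpec:
    """Shape of a synthetic voltage trace.

    ``rise_tau`` / ``decay_tau`` parameterise the difference-of-exponentials
    event kernel; the kernel is normalised to unit peak so planted amplitudes
    are baseline-to-peak amplitudes.
    """

    sampling_rate: float = 10_000.0  # Hz
    duration: float = 60.0  # s
    rise_tau: float = 1.0  # ms
    decay_tau: float = 8.0  # ms
    baseline_noise_sd: float = 0.05  # mV
    stimulus_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigurationError("TraceSpec.sampling_rate must be > 0")
        if not 0 < self.rise_tau < self.decay_tau:
            raise ConfigurationError(
                "TraceSpec requires 0 < rise_tau < decay_tau "
                f"(got rise_tau={self.rise_tau}, decay_tau={self.decay_tau})"
            )
        if self.baseline_noise_sd < 0:
            raise ConfigurationError("TraceSpec.baseline_noise_sd must be >= 0")
        if self.stimulus_times and max(self.stimulus_times) >= self.duration:
            raise ConfigurationError(
                "TraceSpec.stimulus_times must all fall before duration"
            )
        object.__setattr__(self, "stimulus_times", tuple(self.stimulus_times))


@dataclass(frozen=True)
class CountSimSpec:
    """Design of a synthetic RNA-seq count matrix.

    Counts are negative binomial with per-gene baseline means, per-batch
    log2 shifts, and planted per-genotype log2 fold changes relative to the
    control genotype. ``synergy_spec`` plants additional fold changes only in
    ``double_genotype`` — the double-heterozygote-specific ("synergistic")
    expression changes the selection logic downstream is meant to recover.
    """

    n_genes: int
    samples: tuple[tuple[str, str, str], ...]  # (sample, genotype, batch)
    nb_dispersion: float = 0.05
    baseline_mean: float = 500.0
    baseline_log2_sd: float = 1.0
    batch_log2_sd: float = 0.25
    de_spec: Mapping[str, tuple[Sequence[str], float]] = field(default_factory=dict)
    synergy_spec: tuple[Sequence[str], float] | None = None
    double_genotype: str | None = None
    control_genotype: str | None = None

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("CountSimSpec.n_genes must be > 0")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("CountSimSpec.nb_dispersion must be > 0")
        if self.baseline_mean <= 0:
            raise ConfigurationError("CountSimSpec.baseline_mean must be > 0")
        object.__setattr__(self, "samples", tuple(tuple(s) for s in self.samples))
        genotypes = {g for _, g, _ in self.samples}
        for g in self.de_spec:
            if g not in genotypes:
                raise ConfigurationError(
                    f"CountSimSpec.de_spec genotype {g!r} absent from samples"
                )
        universe = set(self.gene_ids)
        for g, (genes, lfc) in self.de_spec.items():
            if not set(genes) <= universe:
                raise ConfigurationError(
                    f"CountSimSpec.de_spec[{g!r}] gene set outside gene universe"
                )
            _require_finite(lfc, f"de_spec[{g!r}] log2 fold change")
        if self.synergy_spec is not None:
            if self.double_genotype is None:
                raise ConfigurationError(
                    "CountSimSpec.double_genotype required when synergy_spec is set"
                )
            if self.double_genotype not in genotypes:
                raise ConfigurationError(
                    f"CountSimSpec.double_genotype {self.double_genotype!r} "
                    "absent from samples"
                )
            genes, lfc = self.synergy_spec
            if not set(genes) <= universe:
                raise ConfigurationError(
                    "CountSimSpec.synergy_spec gene set outside gene universe"
                )
            _require_finite(lfc, "synergy_spec log2 fold change")

    @property
    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"g{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    @property
    def control(self) -> str:
        if self.control_genotype is not None:
            return self.control_genotype
        return self.samples[0][1]


def _require_finite(x: float, what: str) -> None:
    import math

    if not math.isfinite(x):
        raise ConfigurationError(f"CountSimSpec {what} must be finite (got {x!r})")
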