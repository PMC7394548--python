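"""End-to-end pipeline: simulate -> metrics -> screen -> matrix -> DE report.

``run_pipeline`` composes the stages on synthetic data from one master
seed, writing every table, a plain-text log with ISO timestamps, and an
echo of the fully resolved configuration into the output directory.
Identical configuration (same seed) produces byte-identical outputs.
"""

from __future__ import annotations

import datetime
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .degs import NBExpressionModel, synergy_select
from .errors import HomeoscreenError
from .interaction import InteractionModel, pair_label
from .io import echo_config, write_counts, write_measurements
from .params import CountSimSpec, GenotypeParams
from .quantal import php_summary, summaries_frame
from .screen import ScreenModel, hit_calls_frame
from .simulate import simulate_counts, simulate_genotype, simulate_screen


class _Log:
    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []

    def __call__(self, msg: str) -> None:
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        self.lines.append(f"{stamp}  {msg}")

    def flush(self) -> None:
        self.path.write_text("\n".join(self.lines) + "\n")


def _screen_panel(cfg: Mapping, rng: np.random.Generator):
    """Reference genotype plus a deficiency panel with planted blocked hits."""
    sc = cfg["screen"]
    reference = GenotypeParams(name=sc["reference"], compensation=1.0)
    n_def = int(sc["n_deficiencies"])
    n_blocked = int(sc["n_blocked"])
    deficiencies = []
    for i in range(n_def):
        h = 0.0 if i < n_blocked else 1.0
        label = f"Df{i + 1:02d}"
        deficiencies.append(
            (
                label,
                int(rng.integers(5, 51)),
                GenotypeParams(name=label, compensation=h),
            )
        )
    return reference, deficiencies


def run_pipeline(cfg: Mapping, out_dir=None) -> Path:
    """Run the full synthetic study; returns the output directory."""
    out = Path(out_dir if out_dir is not None else cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "run.log")
    log(f"homeoscreen {__version__} seed={cfg['seed']}")
    echo_config(cfg, out)

    master = np.random.SeedSequence(int(cfg["seed"]))
    rng_screen, rng_matrix, rng_counts, rng_dunnett = (
        np.random.default_rng(s) for s in master.spawn(4)
    )

    try:
        # --- screen ------------------------------------------------------
        sc = cfg["screen"]
        if int(sc["n_deficiencies"]) == 0:
            log("screen: no deficiencies configured; stage skipped")
            hits = pd.DataFrame()
        else:
            reference, deficiencies = _screen_panel(cfg, rng_screen)
            table, truth = simulate_screen(
                reference, deficiencies, int(sc["n_per_genotype"]), rng_screen
            )
            write_measurements(table, out / "screen_measurements.csv")
            truth.to_csv(out / "screen_truth.csv", index=False)
            res = ScreenModel(table, sc["reference"]).fit(
                coverage=float(sc["coverage"]), rule=sc["rule"]
            )
            hits = hit_calls_frame(res.calls)
            hits.to_csv(out / "hits.tsv", sep="\t", index=False)
            summaries = [
                php_summary(table[table["genotype"] == g])
                for g in table["genotype"].unique()
            ]
            summaries_frame(summaries).to_csv(
                out / "php_summaries.tsv", sep="\t", index=False
            )
            log(
                f"screen: {len(hits)} genotypes tested, "
                f"{int(hits['is_hit'].sum())} hits"
            )

        # --- interaction matrix -------------------------------------------
        rows = ["wild type", "geneA", "geneB"]
        cols = ["wild type", "Df1", "Df2"]
        parts = []
        for r in rows:
            for c in cols:
                blocked = r != "wild type" and c != "wild type"
                params = GenotypeParams(
                    name=pair_label(r, c), compensation=0.0 if blocked else 1.0
                )
                parts.append(simulate_genotype(params, 10, rng_matrix))
        matrix_table = pd.concat(parts, ignore_index=True)
        write_measurements(matrix_table, out / "matrix_measurements.csv")
        ires = InteractionModel(matrix_table, rows, cols).fit(rng=rng_dunnett)
        for name, tab in ires.tables().items():
            tab.to_csv(out / f"matrix_{name}.tsv", sep="\t")
        ires.frame().to_csv(out / "matrix_cells.tsv", sep="\t", index=False)
        log(f"matrix: {len(rows)}x{len(cols)} cells written")

        # --- differential expression --------------------------------------
        genes_all = CountSimSpec(n_genes=2000, samples=(("s", "wt", "b1"),) * 2).gene_ids
        de_genes = genes_all[:40]
        syn_genes = genes_all[40:54]
        samples = tuple(
            (f"{g}_{i}", g, f"b{i % 2 + 1}")
            for g in ("wt", "hetA", "hetB", "double")
            for i in range(1, 5)
        )
        spec = CountSimSpec(
            n_genes=2000,
            samples=samples,
            de_spec={"hetA": (de_genes[:20], 1.5), "hetB": (de_genes[20:], -1.5)},
            synergy_spec=(syn_genes, 2.0),
            double_genotype="double",
            control_genotype="wt",
        )
        counts, design, truth_de = simulate_counts(spec, rng_counts)
        write_counts(counts, out / "counts.tsv")
        design.to_csv(out / "design.csv", index=False)
        model = NBExpressionModel(counts, design, cpm_threshold=float(
            cfg["deg"]["cpm_threshold"]))
        fits = {
            ctrl: model.fit(("double", ctrl), fdr_cut=float(cfg["deg"]["fdr_cut"]),
                            fc_cut=float(cfg["deg"]["fc_cut"]))
            for ctrl in ("wt", "hetA", "hetB")
        }
        for ctrl, fit in fits.items():
            fit.table.to_csv(out / f"deg_double_vs_{ctrl}.tsv", sep="\t")
        synergy = synergy_select(
            fits["wt"].table, fits["hetA"].table, fits["hetB"].table
        )
        synergy.to_csv(out / "synergy_genes.tsv", sep="\t")
        log(
            f"deg: {int(fits['wt'].table['is_deg'].sum())} DEGs vs wt, "
            f"{len(synergy)} synergy genes"
        )
    except HomeoscreenError:
        log("pipeline aborted on stage error")
        log.flush()
        raise

    log("pipeline complete")
    log.flush()
    return out


__all__ = ["run_pipeline"]
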