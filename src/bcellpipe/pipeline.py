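"""End-to-end driver: simulate -> demux -> repertoire -> transcriptome -> kinetics.

Every stage writes its artifacts under the configured output directory and
contributes to a machine-readable ``summary.json``.  All randomness flows
from the config seed; running twice with the same config is byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

from . import io as pio
from .config import PipelineConfig
from .datatypes import UNASSIGNED
from .demux import STATE_SINGLET, demultiplex
from .kinetics import elisa_auc, fit_langmuir, preprocess_sensorgram
from .repertoire import assign_germline_many, build_clonotype_table
from .repertoire.clonotypes import position_composition
from .synthetic import (
    default_atlas,
    default_reference,
    simulate_elisa,
    simulate_expression,
    simulate_hashtags,
    simulate_repertoire,
    simulate_sensorgram,
)
from .transcriptome import cluster_cells, find_markers, normalize_counts, project_to_atlas

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained on disk."""


def run_pipeline(config: PipelineConfig) -> dict:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    stage = "simulate"
    try:
        reference = default_reference(config.repertoire.strain)
        contigs, truth = simulate_repertoire(config.repertoire, config.seed, reference)
        pio.write_contig_table(contigs, outdir / "contig_annotations.csv",
                               outdir / "contigs.fasta")
        truth.to_csv(outdir / "truth_clonotypes.csv", index=False)
        pio.write_germline_fasta(reference, outdir / "germline.fasta")
        summary["n_cells"] = len(truth)

        assignments: dict[str, int] | None = None
        if config.stages.demux:
            stage = "demux"
            barcodes = truth["barcode"].tolist()
            matrix, ht_truth = simulate_hashtags(
                config.hashtags, truth["donor"].to_numpy(), config.seed + 1,
                cell_ids=barcodes,
            )
            pio.write_matrix(matrix, outdir / "hashtag_counts.mtx")
            ht_truth.to_csv(outdir / "truth_hashtags.csv", index=False)
            assignment = demultiplex(matrix, config.demux_params)
            assignment.table.to_csv(outdir / "assignments.csv", index=False)
            singlets = assignment.table[assignment.table["state"] == STATE_SINGLET]
            assignments = dict(zip(singlets["cell"], singlets["donor"]))
            summary["demux"] = {
                "n_singlet": int(len(singlets)),
                "n_multiplet": int((assignment.table["state"] == "multiplet").sum()),
                "n_unassigned": int((assignment.table["state"] == "unassigned").sum()),
                "per_donor": {str(k): int(v)
                              for k, v in assignment.counts_by_donor().items()},
            }

        if config.stages.repertoire:
            stage = "repertoire"
            kappa = contigs.chain("IGK")
            seqs = {cid: contigs.sequences[cid] for cid in kappa["contig_id"]}
            calls = assign_germline_many(seqs, reference)
            if assignments is None:
                assignments = {
                    bc: (d if d != UNASSIGNED else UNASSIGNED)
                    for bc, d in zip(truth["barcode"], truth["donor"])
                }
            table = build_clonotype_table(contigs, calls, assignments)
            table.cells.to_csv(outdir / "clonotype_cells.csv", index=False)
            table.v_freq.to_csv(outdir / "v_frequencies.csv", index_label="v_gene")
            table.j_freq.to_csv(outdir / "j_frequencies.csv", index_label="j_gene")
            table.pair_freq.to_csv(outdir / "pair_frequencies.csv", index_label="pair")
            joint = position_composition(table, position=97,
                                         v_gene=table.top_pair.split("/")[0],
                                         j_gene=table.top_pair.split("/")[1])
            summary["repertoire"] = {
                "kappa_fraction": table.kappa_fraction,
                "n_excluded": table.n_excluded,
                "top_pair": table.top_pair,
                "top_pair_frequency": table.mean_frequency("pair", table.top_pair),
                "top_v": str(table.v_freq["mean"].idxmax()),
                "top_v_frequency": float(table.v_freq["mean"].max()),
                "top_j": str(table.j_freq["mean"].idxmax()),
                "top_j_frequency": float(table.j_freq["mean"].max()),
                "joint_position_composition": {k: float(v) for k, v in joint.items()},
            }

        if config.stages.transcriptome:
            stage = "transcriptome"
            counts, labels_truth = simulate_expression(config.expression, config.seed + 2)
            pio.write_matrix(counts, outdir / "expression_counts.mtx")
            normalized = normalize_counts(counts)
            result = cluster_cells(normalized, config.cluster_params, seed=config.seed + 2)
            import pandas as pd

            pd.DataFrame({
                "cell": list(counts.index),
                "cluster": result.labels,
                "truth": labels_truth,
            }).to_csv(outdir / "cluster_labels.csv", index=False)
            summary["transcriptome"] = {"n_clusters": result.n_clusters}
            if result.n_clusters >= 2:
                markers = find_markers(normalized, result.labels)
                markers.significant.to_csv(outdir / "markers.csv", index=False)
                atlas = default_atlas(seed=0)
                pio.write_atlas(atlas, outdir / "atlas.csv")
                sig = project_to_atlas(markers, atlas)
                sig.z.to_csv(outdir / "signature_matrix.csv", index_label="gene")
                summary["transcriptome"]["cluster_populations"] = {
                    str(k): v for k, v in sig.assignment.items()
                }

        if config.stages.kinetics:
            stage = "kinetics"
            raw = simulate_sensorgram(config.spr, config.seed + 3)
            pio.write_sensorgrams(raw, outdir / "sensorgrams.csv")
            clean = preprocess_sensorgram(raw, config.preprocess)
            fit = fit_langmuir(clean, config.fit_options)
            pio.write_json(fit.as_dict(), outdir / "kinetic_fit.json")
            curve = simulate_elisa(params=config.elisa, seed=config.seed + 4,
                                   group="default")
            pio.write_elisa([curve], outdir / "elisa.csv")
            summary["kinetics"] = {
                "ka": fit.ka, "kd": fit.kd, "KD": fit.kD, "rmax": fit.rmax,
                "residual_rms": fit.residual_rms,
                "elisa_auc": elisa_auc(curve),
            }
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    pio.write_json(summary, outdir / "summary.json")
    return summary
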