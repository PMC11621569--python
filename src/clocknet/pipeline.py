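"""End-to-end orchestration: synth → roster → connectivity → transmitters →
paracrine → merge, with a consolidated, recomputable run report.

Stages communicate only through files under the output directory, so any
stage can be re-run in isolation; the report stores paths relative to the
output directory and is byte-identical across runs with the same seed.
Conservation checks (census sums, laterality sums, strict ⊂ loose subset
relations) run on every report and abort the run if violated.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import connectivity as conn_mod
from . import neurotransmitter as nt_mod
from . import paracrine as para_mod
from . import roster as roster_mod
from . import synthetic_data as synth_mod
from .connectivity import Thresholds, DEFAULT_THRESHOLDS
from .io import write_roster_table
from .paracrine import ParacrineParams, DEFAULT_PARAMS


class PipelineError(RuntimeError):
    """A stage failed or a conservation check did not hold."""


@dataclass
class RunReport:
    """Per-stage parameters, output paths and headline counts; every number
    is recomputable from the written outputs."""

    seed: int
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "stages": self.stages, "warnings": self.warnings},
            indent=1,
            sort_keys=True,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def run_all(
    out_dir: str | Path,
    seed: int = 0,
    config: synth_mod.SynthConfig | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    params: ParacrineParams = DEFAULT_PARAMS,
) -> RunReport:
    """Run the full pipeline on a synthetic connectome and write all outputs.

    ``config`` defaults to the standard study conditions with the given seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = synth_mod.default_config(seed=seed)
    report = RunReport(seed=seed)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # --- synth ----------------------------------------------------------
        conn = synth_mod.build_synthetic_connectome(config)
        expression, _ = synth_mod.build_synthetic_expression(config)
        catalog = synth_mod.build_ligand_receptor_catalog(config)
        paths = synth_mod.write_synthetic_dataset(conn, expression, catalog, out)
        report.stages["synth"] = {
            "outputs": paths,
            "n_neurons": int(len(conn.neurons)),
            "n_synapse_edges": int(len(conn.synapses)),
            "total_synapses": conn.ground_truth.total_synapses,
        }

        # --- roster ----------------------------------------------------------
        roster, log = roster_mod.identify_clock_neurons(
            conn.seed_roster, conn.morphology_clusters, conn.neurons
        )
        write_roster_table(roster.to_frame(), out / "roster.tsv")
        cens = roster_mod.census(roster)
        (out / "census.json").write_text(json.dumps(cens.to_dict(), indent=1, sort_keys=True) + "\n")
        if sum(cens.by_cell_type.values()) != cens.total or sum(
            cens.by_class.values()
        ) != cens.total or sum(cens.by_super_class.values()) != cens.total:
            raise PipelineError("census totals not conserved across grouping levels")
        report.stages["roster"] = {
            "outputs": {"roster": "roster.tsv", "census": "census.json"},
            "iterations": len(log),
            "census": cens.to_dict(),
        }

        # --- connectivity -----------------------------------------------------
        grouping = roster.cluster_map()
        edge_counts = {}
        for name, threshold in (
            ("relaxed", thresholds.relaxed),
            ("significant", thresholds.significant),
            ("strong", thresholds.strong),
        ):
            edges = conn_mod.aggregate_edges(
                conn.synapses, grouping, threshold=threshold, annotations=conn.neurons
            )
            bad = edges[
                edges["ipsi_synapses"] + edges["contra_synapses"] + edges["unassigned_synapses"]
                != edges["total_synapses"]
            ]
            if len(bad):
                raise PipelineError("laterality buckets do not sum to edge totals")
            edges.to_csv(out / f"cluster_edges_{name}.tsv", sep="\t", index=False)
            edge_counts[name] = int(len(edges))
        if not (edge_counts["strong"] <= edge_counts["significant"] <= edge_counts["relaxed"]):
            raise PipelineError("edge sets not monotone in the synapse threshold")
        clock_ids = sorted(roster.ids())
        profiles = conn_mod.build_profiles(conn.synapses, clock_ids)
        nonzero = profiles[(profiles.sum(axis=1) > 0)]
        clustering = conn_mod.cluster_profiles(nonzero) if len(nonzero) >= 2 else None
        if clustering is not None:
            (out / "profile_dendrogram.nwk").write_text(clustering.to_newick() + "\n")
        lat = conn_mod.laterality_split(
            conn.synapses, conn.neurons, threshold=thresholds.significant
        )
        report.stages["connectivity"] = {
            "outputs": {
                name: f"cluster_edges_{name}.tsv" for name in edge_counts
            },
            "edge_counts": edge_counts,
            "laterality_synapses": lat,
            "n_profiled": int(len(nonzero)),
        }

        # --- neurotransmitters -------------------------------------------------
        assignments, conflicts = nt_mod.consolidate(
            conn.nt_predictions, conn.neurons, conn.nt_overrides
        )
        assignments.to_csv(out / "nt_assignments.tsv", sep="\t", index=False)
        tally = assignments["transmitter"].value_counts().to_dict()
        report.stages["neurotransmitter"] = {
            "outputs": {"assignments": "nt_assignments.tsv"},
            "tally": {k: int(v) for k, v in sorted(tally.items())},
            "conflicts": conflicts,
        }

        # --- paracrine -----------------------------------------------------------
        calls = para_mod.expression_calls(expression, config.gene_classes(), params)
        cluster_members: dict[str, list[str]] = {}
        for nid, ct in grouping.items():
            cluster_members.setdefault(ct, []).append(nid)
        dist = para_mod.cluster_distance_matrix(cluster_members, conn.skeletons)
        dist.to_csv(out / "cluster_distances.tsv", sep="\t")
        pairs = para_mod.filter_lr_pairs(catalog, params.ec50_max)
        edges_loose = para_mod.infer_paracrine(calls, pairs, dist, params.diffusion_max)
        edges_strict = para_mod.infer_paracrine(
            calls, pairs, dist, params.stringent_diffusion
        )
        retention = para_mod.retention_fraction(edges_loose, edges_strict)
        edges_loose.to_csv(out / "paracrine_edges.tsv", sep="\t", index=False)
        edges_strict.to_csv(out / "paracrine_edges_stringent.tsv", sep="\t", index=False)
        (out / "retention.json").write_text(
            json.dumps(
                {
                    "diffusion_max_um": params.diffusion_max,
                    "stringent_diffusion_um": params.stringent_diffusion,
                    "n_loose": int(len(edges_loose)),
                    "n_strict": int(len(edges_strict)),
                    "retention_fraction": retention,
                },
                indent=1,
                sort_keys=True,
            )
            + "\n"
        )
        report.stages["paracrine"] = {
            "outputs": {
                "edges": "paracrine_edges.tsv",
                "edges_stringent": "paracrine_edges_stringent.tsv",
                "distances": "cluster_distances.tsv",
                "retention": "retention.json",
            },
            "n_edges": int(len(edges_loose)),
            "n_edges_stringent": int(len(edges_strict)),
            "retention_fraction": retention,
        }

        # --- merge ------------------------------------------------------------
        sig_edges = pd.read_csv(out / "cluster_edges_significant.tsv", sep="\t")
        combined = para_mod.merge_synaptic_paracrine(sig_edges, edges_loose)
        combined.to_csv(out / "combined_edges.tsv", sep="\t", index=False)
        report.stages["merge"] = {
            "outputs": {"combined": "combined_edges.tsv"},
            "modality_counts": {
                k: int(v)
                for k, v in sorted(combined["modality"].value_counts().to_dict().items())
            },
        }

        report.warnings = sorted({str(w.message) for w in caught})

    report.save(out / "report.json")
    return report
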