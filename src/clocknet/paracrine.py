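"""Inference of putative peptidergic paracrine connections between clock
neuron clusters.

Neuropeptides released non-synaptically can act on any receptor-bearing
cluster within diffusion range.  A paracrine edge S → T mediated by a
peptide–receptor pair (p, r) is emitted when four independent filters all
pass:

1. expression — cluster S expresses peptide p and cluster T expresses
   receptor r.  A single-cell call requires > 49% of the cluster's cells
   expressing the gene *and* a mean scaled expression above a class-specific
   cut (0.208 for peptides, 0.067 for receptors).  Peptides additionally
   need two independent methods of evidence; receptors need two methods or a
   single live-imaging demonstration.
2. potency — (p, r) is in the ligand–receptor catalog with EC50 ≤ 500 nM
   (pairs needing more than 500 nM to half-activate are disregarded; EC50 is
   a pass/fail filter, never an edge weight).
3. distance — the minimum skeleton node-to-node distance between any neuron
   of S and any neuron of T is within the diffusion cut-off.  The default of
   14 µm is calibrated on a demonstrated paracrine pair; 1 µm gives a
   stringent near-touching criterion.

Self-edges (S = T, autocrine) are allowed and pass the distance filter
trivially.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import Skeleton

PARACRINE_EDGE_COLUMNS = [
    "source_cluster",
    "target_cluster",
    "peptide",
    "receptor",
    "min_distance_um",
]


@dataclass(frozen=True)
class ParacrineParams:
    """Thresholds of the paracrine inference.

    ``fraction_min`` — fraction of cells in a cluster that must express a
    gene (exclusive; 0.49 encodes "more than 49% of cells").
    ``peptide_expr_min`` / ``receptor_expr_min`` — mean scaled expression
    cuts (exclusive), calibrated against established expression data.
    ``min_methods`` — independent evidence methods required.
    ``ec50_max`` — maximum ligand potency in nM (inclusive).
    ``diffusion_max`` / ``stringent_diffusion`` — skeleton distance cut-offs
    in µm (inclusive).
    """

    fraction_min: float = 0.49
    peptide_expr_min: float = 0.208
    receptor_expr_min: float = 0.067
    min_methods: int = 2
    receptor_live_imaging_sufficient: bool = True
    live_imaging_method: str = "live_imaging"
    ec50_max: float = 500.0
    diffusion_max: float = 14.0
    stringent_diffusion: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_min < 1.0):
            raise ValueError("fraction_min must be in [0, 1)")
        for name in ("peptide_expr_min", "receptor_expr_min", "ec50_max", "diffusion_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.stringent_diffusion > self.diffusion_max:
            raise ValueError("stringent_diffusion must be <= diffusion_max")
        if self.min_methods < 1:
            raise ValueError("min_methods must be >= 1")

    def expr_min(self, gene_class: str) -> float:
        if gene_class == "peptide":
            return self.peptide_expr_min
        if gene_class == "receptor":
            return self.receptor_expr_min
        raise ValueError(f"gene_class must be 'peptide' or 'receptor', got {gene_class!r}")


DEFAULT_PARAMS = ParacrineParams()


# ---------------------------------------------------------------------------
# Expression calling
# ---------------------------------------------------------------------------


def call_expression(
    expression: pd.DataFrame,
    cluster: str,
    gene: str,
    gene_class: str,
    params: ParacrineParams = DEFAULT_PARAMS,
    method: str = "scrna",
) -> bool:
    """Single-method expression call: strictly more than ``fraction_min`` of
    cells expressing AND mean scaled expression strictly above the class
    threshold.  A missing record is a negative call with a warning."""
    sel = expression[
        (expression["cluster"] == cluster)
        & (expression["gene"] == gene)
        & (expression["method"] == method)
    ]
    if len(sel) == 0:
        warnings.warn(
            f"no {method} record for ({cluster}, {gene}); negative call", stacklevel=2
        )
        return False
    row = sel.iloc[0]
    return bool(
        row["fraction_expressing"] > params.fraction_min
        and row["mean_scaled"] > params.expr_min(gene_class)
    )


def method_calls(
    expression: pd.DataFrame,
    cluster: str,
    gene: str,
    gene_class: str,
    params: ParacrineParams = DEFAULT_PARAMS,
) -> dict[str, bool]:
    """Per-method calls for one (cluster, gene), over the methods present."""
    sel = expression[
        (expression["cluster"] == cluster) & (expression["gene"] == gene)
    ]
    cut = params.expr_min(gene_class)
    return {
        str(r.method): bool(
            r.fraction_expressing > params.fraction_min and r.mean_scaled > cut
        )
        for r in sel.itertuples(index=False)
    }


def integrate_evidence(
    calls: Mapping[str, bool],
    gene_class: str,
    params: ParacrineParams = DEFAULT_PARAMS,
) -> bool:
    """Combine per-method calls.

    Peptide: at least ``min_methods`` independent positive methods.
    Receptor: the same, or a positive live-imaging call on its own.
    """
    n_positive = sum(bool(v) for v in calls.values())
    if n_positive >= params.min_methods:
        return True
    if (
        gene_class == "receptor"
        and params.receptor_live_imaging_sufficient
        and calls.get(params.live_imaging_method, False)
    ):
        return True
    return False


def expression_calls(
    expression: pd.DataFrame,
    gene_classes: Mapping[str, str],
    params: ParacrineParams = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """Integrated expression call per (cluster, gene).

    Returns columns cluster, gene, gene_class, expressed.  Genes absent from
    ``gene_classes`` are ignored.
    """
    rows = []
    known = expression[expression["gene"].isin(gene_classes)]
    for (cluster, gene), _ in known.groupby(["cluster", "gene"], sort=True):
        gene_class = gene_classes[gene]
        calls = method_calls(expression, cluster, gene, gene_class, params)
        rows.append(
            {
                "cluster": cluster,
                "gene": gene,
                "gene_class": gene_class,
                "expressed": integrate_evidence(calls, gene_class, params),
            }
        )
    return pd.DataFrame(rows, columns=["cluster", "gene", "gene_class", "expressed"])


# ---------------------------------------------------------------------------
# Skeleton distances
# ---------------------------------------------------------------------------


def skeleton_min_distance(
    skeletons_a: Iterable[Skeleton],
    skeletons_b: Iterable[Skeleton],
) -> float:
    """Minimum Euclidean distance over all (node of A, node of B) pairs, µm.

    Implemented with a KD-tree over the larger node set; equivalent to the
    brute-force all-pairs loop.
    """
    coords_a = [s.coords() for s in skeletons_a]
    coords_b = [s.coords() for s in skeletons_b]
    if not coords_a or not coords_b:
        raise ValueError("both skeleton sets must be non-empty")
    a = np.vstack(coords_a)
    b = np.vstack(coords_b)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("empty skeleton")
    if b.shape[0] >= a.shape[0]:
        tree, query = cKDTree(b), a
    else:
        tree, query = cKDTree(a), b
    dists, _ = tree.query(query, k=1)
    return float(np.min(dists))


def cluster_distance_matrix(
    cluster_members: Mapping[str, Iterable[str]],
    skeletons: Mapping[str, Skeleton],
) -> pd.DataFrame:
    """Symmetric cluster × cluster matrix of minimum skeleton distances (µm).

    Diagonal is 0 by definition.  A cluster without any skeletonized member
    gets a NaN row/column and a warning.
    """
    clusters = sorted(cluster_members)
    sets: dict[str, list[Skeleton]] = {}
    for c in clusters:
        sk = [skeletons[nid] for nid in cluster_members[c] if nid in skeletons]
        if not sk:
            warnings.warn(f"cluster {c!r} has no skeletonized members", stacklevel=2)
        sets[c] = sk
    n = len(clusters)
    mat = np.full((n, n), np.nan)
    for i, a in enumerate(clusters):
        if sets[a]:
            mat[i, i] = 0.0
        for j in range(i + 1, n):
            b = clusters[j]
            if sets[a] and sets[b]:
                d = skeleton_min_distance(sets[a], sets[b])
                mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=clusters, columns=clusters)


# ---------------------------------------------------------------------------
# Catalog filtering and edge inference
# ---------------------------------------------------------------------------


def filter_lr_pairs(catalog: pd.DataFrame, ec50_max: float = DEFAULT_PARAMS.ec50_max) -> pd.DataFrame:
    """Retain peptide–receptor pairs with EC50 ≤ ``ec50_max`` (inclusive:
    only pairs *above* the cut are disregarded)."""
    return catalog[catalog["ec50_nm"] <= ec50_max].reset_index(drop=True)


def infer_paracrine(
    calls: pd.DataFrame,
    catalog: pd.DataFrame,
    distance_matrix: pd.DataFrame,
    diffusion_max: float = DEFAULT_PARAMS.diffusion_max,
) -> pd.DataFrame:
    """Emit edge (S → T, peptide, receptor) when S expresses the peptide, T
    expresses the receptor, the pair is in the (already EC50-filtered)
    catalog, and min skeleton distance(S, T) ≤ ``diffusion_max``.

    ``calls`` is the output of :func:`expression_calls`.  Clusters missing
    from the distance matrix are skipped with a warning.
    """
    positive = calls[calls["expressed"]]
    pep_clusters: dict[str, list[str]] = {}
    rec_clusters: dict[str, list[str]] = {}
    for r in positive.itertuples(index=False):
        d = pep_clusters if r.gene_class == "peptide" else rec_clusters
        d.setdefault(r.gene, []).append(r.cluster)
    known = set(distance_matrix.index)
    warned: set[str] = set()
    rows = []
    for pair in catalog.itertuples(index=False):
        for src in pep_clusters.get(pair.peptide, ()):
            for tgt in rec_clusters.get(pair.receptor, ()):
                if src not in known or tgt not in known:
                    for c in (src, tgt):
                        if c not in known and c not in warned:
                            warnings.warn(
                                f"cluster {c!r} missing from distance matrix; edges skipped",
                                stacklevel=2,
                            )
                            warned.add(c)
                    continue
                d = float(distance_matrix.at[src, tgt])
                if np.isnan(d):
                    continue
                if d <= diffusion_max:
                    rows.append(
                        {
                            "source_cluster": src,
                            "target_cluster": tgt,
                            "peptide": pair.peptide,
                            "receptor": pair.receptor,
                            "min_distance_um": d,
                        }
                    )
    out = pd.DataFrame(rows, columns=PARACRINE_EDGE_COLUMNS)
    return out.sort_values(PARACRINE_EDGE_COLUMNS[:4], ignore_index=True)


def edge_keys(edges: pd.DataFrame) -> set[tuple[str, str, str, str]]:
    return {
        (r.source_cluster, r.target_cluster, r.peptide, r.receptor)
        for r in edges.itertuples(index=False)
    }


def retention_fraction(edges_loose: pd.DataFrame, edges_strict: pd.DataFrame) -> float:
    """|strict| / |loose| over edge keys; the strict set must be a subset of
    the loose set.  An empty loose set yields 1.0 by convention (logged)."""
    loose = edge_keys(edges_loose)
    strict = edge_keys(edges_strict)
    if not strict <= loose:
        raise ValueError(
            f"strict edge set is not a subset of the loose set: {sorted(strict - loose)[:3]}"
        )
    if not loose:
        warnings.warn("loose edge set empty; retention defined as 1.0", stacklevel=2)
        return 1.0
    return len(strict) / len(loose)


def merge_synaptic_paracrine(
    cluster_edges: pd.DataFrame,
    paracrine_edges: pd.DataFrame,
) -> pd.DataFrame:
    """Combined labelled edge list over a shared cluster vocabulary.

    Each (source, target) is labelled ``synaptic``, ``paracrine`` or
    ``both``; paracrine mediators are ';'-joined as peptide→receptor.
    Suitable for chord-diagram export.
    """
    syn = {
        (r.pre_cluster, r.post_cluster): int(r.total_synapses)
        for r in cluster_edges.itertuples(index=False)
    }
    para: dict[tuple[str, str], list[str]] = {}
    for r in paracrine_edges.itertuples(index=False):
        para.setdefault((r.source_cluster, r.target_cluster), []).append(
            f"{r.peptide}->{r.receptor}"
        )
    rows = []
    for key in sorted(set(syn) | set(para)):
        modality = "both" if key in syn and key in para else (
            "synaptic" if key in syn else "paracrine"
        )
        rows.append(
            {
                "source": key[0],
                "target": key[1],
                "modality": modality,
                "total_synapses": syn.get(key, 0),
                "mediators": ";".join(sorted(para.get(key, []))),
            }
        )
    return pd.DataFrame(
        rows, columns=["source", "target", "modality", "total_synapses", "mediators"]
    )
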