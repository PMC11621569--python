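"""Thresholded synaptic-connectivity analyses on directed synapse tables.

All operations start from per-neuron-pair synapse counts (duplicate rows
summed).  Connection strength thresholds follow the analysis conventions of
the fly clock connectome: a neuron pair is *significantly* connected above 4
synapses (i.e. ≥ 5), *strongly* above 9, and a *relaxed* criterion of > 2
synapses is used when tracing weak multi-step light-input pathways.  The
per-pair threshold is applied before any cluster-level aggregation, so a
cluster edge is a sum over individually significant neuron pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist


@dataclass(frozen=True)
class Thresholds:
    """Synapse-count thresholds (each is the minimum count that passes).

    ``significant``: per-pair cut for ordinary connectivity (> 4 synapses);
    ``strong``: strong connections (> 9); ``relaxed``: permissive tracing
    cut (> 2); ``top_partner``: per-neuron total for shortlisting the very
    strongest partners (≥ 80, i.e. "more than 79 synapses per neuron");
    ``descending_focus``: strongest synaptic inputs cut (> 49).
    """

    significant: int = 5
    strong: int = 10
    relaxed: int = 3
    top_partner: int = 80
    descending_focus: int = 50

    def __post_init__(self) -> None:
        if not (1 <= self.relaxed <= self.significant <= self.strong):
            raise ValueError(
                "thresholds must satisfy 1 <= relaxed <= significant <= strong"
            )
        if self.top_partner < 1 or self.descending_focus < 1:
            raise ValueError("thresholds must be >= 1")


DEFAULT_THRESHOLDS = Thresholds()

CLUSTER_EDGE_COLUMNS = [
    "pre_cluster",
    "post_cluster",
    "n_pairs",
    "total_synapses",
    "mean_synapses_per_pair",
    "ipsi_synapses",
    "contra_synapses",
    "unassigned_synapses",
]


def pair_counts(synapses: pd.DataFrame) -> pd.DataFrame:
    """Collapse a synapse table to one row per (pre_id, post_id)."""
    if len(synapses) == 0:
        return pd.DataFrame(columns=["pre_id", "post_id", "n_synapses"])
    return (
        synapses.groupby(["pre_id", "post_id"], as_index=False, sort=True)["n_synapses"]
        .sum()
    )


def _hemisphere_map(annotations: pd.DataFrame | None) -> dict[str, str]:
    if annotations is None:
        return {}
    return dict(zip(annotations["neuron_id"], annotations["hemisphere"]))


def aggregate_edges(
    synapses: pd.DataFrame,
    grouping: Mapping[str, str],
    threshold: int = DEFAULT_THRESHOLDS.significant,
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cluster-level edges from per-pair thresholded synapse counts.

    Neuron pairs below ``threshold`` are discarded first; survivors are
    summed per (pre_cluster, post_cluster).  A pair is contralateral iff the
    hemisphere labels of its endpoints differ; pairs with a missing label go
    to the ``unassigned`` bucket with a warning.  Neurons absent from
    ``grouping`` are routed to cluster ``"other"`` with a warning.
    """
    pairs = pair_counts(synapses)
    pairs = pairs[pairs["n_synapses"] >= threshold]
    if len(pairs) == 0:
        return pd.DataFrame(columns=CLUSTER_EDGE_COLUMNS)
    missing = sorted(
        set(pairs["pre_id"]).union(pairs["post_id"]) - set(grouping)
    )
    if missing:
        warnings.warn(
            f"{len(missing)} neurons missing from grouping routed to 'other'"
            f" (first: {missing[0]})",
            stacklevel=2,
        )
    hemi = _hemisphere_map(annotations)
    rows = []
    for r in pairs.itertuples(index=False):
        pre_h, post_h = hemi.get(r.pre_id), hemi.get(r.post_id)
        if pre_h is None or post_h is None:
            lat = "unassigned"
            if annotations is not None:
                warnings.warn(
                    f"pair ({r.pre_id}, {r.post_id}): missing hemisphere label",
                    stacklevel=2,
                )
        else:
            lat = "ipsi" if pre_h == post_h else "contra"
        rows.append(
            {
                "pre_cluster": grouping.get(r.pre_id, "other"),
                "post_cluster": grouping.get(r.post_id, "other"),
                "n_synapses": r.n_synapses,
                "laterality": lat,
            }
        )
    df = pd.DataFrame(rows)
    grouped = df.groupby(["pre_cluster", "post_cluster"], sort=True)
    out = grouped.agg(
        n_pairs=("n_synapses", "size"),
        total_synapses=("n_synapses", "sum"),
    ).reset_index()
    for lat in ("ipsi", "contra", "unassigned"):
        lat_sum = (
            df[df["laterality"] == lat]
            .groupby(["pre_cluster", "post_cluster"])["n_synapses"]
            .sum()
        )
        out[f"{lat}_synapses"] = (
            out.set_index(["pre_cluster", "post_cluster"]).index.map(lat_sum).fillna(0).astype(int)
        )
    out["mean_synapses_per_pair"] = out["total_synapses"] / out["n_pairs"]
    return out[CLUSTER_EDGE_COLUMNS]


def laterality_split(
    synapses: pd.DataFrame,
    annotations: pd.DataFrame,
    threshold: int = 1,
) -> dict[str, int]:
    """Total synapses in ipsi-, contra-lateral and unassigned buckets."""
    pairs = pair_counts(synapses)
    pairs = pairs[pairs["n_synapses"] >= threshold]
    hemi = _hemisphere_map(annotations)
    out = {"ipsi": 0, "contra": 0, "unassigned": 0}
    for r in pairs.itertuples(index=False):
        pre_h, post_h = hemi.get(r.pre_id), hemi.get(r.post_id)
        if pre_h is None or post_h is None:
            warnings.warn(
                f"pair ({r.pre_id}, {r.post_id}): missing hemisphere label", stacklevel=2
            )
            out["unassigned"] += int(r.n_synapses)
        elif pre_h == post_h:
            out["ipsi"] += int(r.n_synapses)
        else:
            out["contra"] += int(r.n_synapses)
    return out


def superclass_breakdown(
    synapses: pd.DataFrame,
    annotations: pd.DataFrame,
    focus: Iterable[str],
    direction: str = "in",
    threshold: int = 1,
) -> pd.Series:
    """Fraction of the focus set's synapses per partner super class.

    ``direction="in"`` partitions synapses onto the focus set by the super
    class of the presynaptic partner; ``"out"`` partitions synapses from the
    focus set by the postsynaptic partner.  Fractions sum to 1 over the
    non-empty classes.
    """
    if direction not in ("in", "out"):
        raise ValueError(f"direction must be 'in' or 'out', got {direction!r}")
    focus = set(focus)
    pairs = pair_counts(synapses)
    pairs = pairs[pairs["n_synapses"] >= threshold]
    if direction == "in":
        pairs = pairs[pairs["post_id"].isin(focus)]
        partner_col = "pre_id"
    else:
        pairs = pairs[pairs["pre_id"].isin(focus)]
        partner_col = "post_id"
    if len(pairs) == 0:
        return pd.Series(dtype=float)
    super_class = dict(zip(annotations["neuron_id"], annotations["super_class"]))
    partner_sc = pairs[partner_col].map(lambda nid: super_class.get(nid, "unannotated"))
    totals = pairs.groupby(partner_sc)["n_synapses"].sum().sort_index()
    return totals / totals.sum()


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """dot(a, b) / (‖a‖ ‖b‖) for non-negative vectors; in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def build_profiles(
    synapses: pd.DataFrame,
    focus: Iterable[str],
    partners: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Connectivity profile per focus neuron: input counts and output counts
    concatenated over a fixed, shared partner index (unthresholded — the
    profile uses *all* input and output synapses)."""
    focus = sorted(set(focus))
    pairs = pair_counts(synapses)
    if partners is None:
        partners = sorted(set(pairs["pre_id"]).union(pairs["post_id"]))
    else:
        partners = sorted(set(partners))
    pidx = {p: j for j, p in enumerate(partners)}
    fidx = {f: i for i, f in enumerate(focus)}
    mat = np.zeros((len(focus), 2 * len(partners)))
    for r in pairs.itertuples(index=False):
        if r.post_id in fidx and r.pre_id in pidx:  # input
            mat[fidx[r.post_id], pidx[r.pre_id]] += r.n_synapses
        if r.pre_id in fidx and r.post_id in pidx:  # output
            mat[fidx[r.pre_id], len(partners) + pidx[r.post_id]] += r.n_synapses
    columns = pd.MultiIndex.from_tuples(
        [("in", p) for p in partners] + [("out", p) for p in partners]
    )
    return pd.DataFrame(mat, index=pd.Index(focus, name="neuron_id"), columns=columns)


@dataclass
class ProfileClustering:
    """Hierarchical agglomeration of connectivity profiles on 1 − cosine."""

    ids: list[str]
    linkage_matrix: np.ndarray

    def cut(self, n_clusters: int) -> dict[str, int]:
        labels = fcluster(self.linkage_matrix, t=n_clusters, criterion="maxclust")
        return dict(zip(self.ids, (int(v) for v in labels)))

    def cophenetic_height(self, a: str, b: str) -> float:
        """Merge height of the smallest clade containing both neurons."""
        from scipy.cluster.hierarchy import cophenet

        dm = cophenet(self.linkage_matrix)
        n = len(self.ids)
        i, j = self.ids.index(a), self.ids.index(b)
        if i == j:
            return 0.0
        if i > j:
            i, j = j, i
        # condensed index
        k = n * i - (i * (i + 1)) // 2 + (j - i - 1)
        return float(dm[k])

    def to_newick(self) -> str:
        tree = to_tree(self.linkage_matrix)

        def rec(node) -> str:
            if node.is_leaf():
                return self.ids[node.id]
            left, right = rec(node.left), rec(node.right)
            bl_l = node.dist - node.left.dist
            bl_r = node.dist - node.right.dist
            return f"({left}:{bl_l:.6g},{right}:{bl_r:.6g})"

        return rec(tree) + ";"


def cluster_profiles(
    profiles: pd.DataFrame,
    method: str = "average",
) -> ProfileClustering:
    """Agglomerate profiles on cosine distance (1 − cosine similarity).

    Rows are sorted by neuron id before linkage so the dendrogram is
    independent of input order.  Zero profiles have undefined similarity and
    are rejected.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to cluster")
    profiles = profiles.sort_index()
    mat = profiles.to_numpy(dtype=float)
    zero = np.where(np.linalg.norm(mat, axis=1) == 0)[0]
    if len(zero):
        raise ValueError(
            f"zero connectivity profile for {profiles.index[zero[0]]!r}:"
            " cosine similarity undefined"
        )
    dist = np.clip(pdist(mat, metric="cosine"), 0.0, None)
    z = linkage(dist, method=method)
    return ProfileClustering(ids=[str(i) for i in profiles.index], linkage_matrix=z)


def disynaptic_connections(
    sources: Iterable[str],
    targets: Iterable[str],
    synapses: pd.DataFrame,
    threshold: int = DEFAULT_THRESHOLDS.significant,
) -> pd.DataFrame:
    """All two-hop paths source → mid → target where each hop passes the
    per-pair threshold.  A neuron may appear in both the source and target
    sets; the middle neuron is unconstrained."""
    sources = set(sources)
    targets = set(targets)
    pairs = pair_counts(synapses)
    pairs = pairs[pairs["n_synapses"] >= threshold]
    hop1 = pairs[pairs["pre_id"].isin(sources)]
    hop2 = pairs[pairs["post_id"].isin(targets)]
    merged = hop1.merge(
        hop2,
        left_on="post_id",
        right_on="pre_id",
        suffixes=("_1", "_2"),
    )
    if len(merged) == 0:
        return pd.DataFrame(
            columns=["source", "mid", "target", "hop1_synapses", "hop2_synapses"]
        )
    out = pd.DataFrame(
        {
            "source": merged["pre_id_1"],
            "mid": merged["post_id_1"],
            "target": merged["post_id_2"],
            "hop1_synapses": merged["n_synapses_1"].astype(int),
            "hop2_synapses": merged["n_synapses_2"].astype(int),
        }
    )
    return out.sort_values(["source", "mid", "target"], ignore_index=True)


def summarize_disynaptic(
    paths: pd.DataFrame,
    grouping: Mapping[str, str],
) -> pd.DataFrame:
    """Aggregate two-hop paths per (source cluster, mid type, target cluster).

    Per-hop synapse counts are averaged over the contributing neuron pairs
    (the denominator is recorded in the column names).
    """
    if len(paths) == 0:
        return pd.DataFrame(
            columns=[
                "source_cluster",
                "mid_cluster",
                "target_cluster",
                "n_paths",
                "mean_hop1_synapses_per_pair",
                "mean_hop2_synapses_per_pair",
            ]
        )
    df = paths.assign(
        source_cluster=paths["source"].map(lambda n: grouping.get(n, "other")),
        mid_cluster=paths["mid"].map(lambda n: grouping.get(n, "other")),
        target_cluster=paths["target"].map(lambda n: grouping.get(n, "other")),
    )
    grouped = df.groupby(["source_cluster", "mid_cluster", "target_cluster"], sort=True)
    out = grouped.agg(
        n_paths=("hop1_synapses", "size"),
        mean_hop1_synapses_per_pair=("hop1_synapses", "mean"),
        mean_hop2_synapses_per_pair=("hop2_synapses", "mean"),
    ).reset_index()
    return out


def top_partners(
    synapses: pd.DataFrame,
    focus: Iterable[str],
    direction: str = "in",
    min_total: int = DEFAULT_THRESHOLDS.top_partner,
) -> pd.DataFrame:
    """Partners whose per-neuron synapse total with the focus set reaches
    ``min_total`` (inclusive), ranked by descending total."""
    if direction not in ("in", "out"):
        raise ValueError(f"direction must be 'in' or 'out', got {direction!r}")
    focus = set(focus)
    pairs = pair_counts(synapses)
    if direction == "in":
        pairs = pairs[pairs["post_id"].isin(focus)]
        partner_col = "pre_id"
    else:
        pairs = pairs[pairs["pre_id"].isin(focus)]
        partner_col = "post_id"
    if len(pairs) == 0:
        return pd.DataFrame(columns=["partner", "total_synapses"])
    totals = pairs.groupby(partner_col)["n_synapses"].sum()
    totals = totals[totals >= min_total]
    out = totals.reset_index()
    out.columns = ["partner", "total_synapses"]
    return out.sort_values(
        ["total_synapses", "partner"], ascending=[False, True], ignore_index=True
    )


def fan_in_estimate(
    n_upstream: int, n_downstream: int, synapses_per_connection: int
) -> float:
    """Expected synapses per downstream neuron under uniform convergence:
    (n_upstream / n_downstream) × synapses_per_connection.

    With synapses_per_connection = 1 this is the expected number of
    converging upstream partners per downstream neuron.
    """
    if n_downstream < 1:
        raise ValueError("n_downstream must be >= 1")
    if n_upstream < 0 or synapses_per_connection < 0:
        raise ValueError("counts must be non-negative")
    return (n_upstream / n_downstream) * synapses_per_connection


def input_share(
    synapses: pd.DataFrame,
    target: str,
    source_set: Iterable[str],
) -> float:
    """Fraction of a target neuron's input synapses arriving from a source set."""
    source_set = set(source_set)
    pairs = pair_counts(synapses)
    onto = pairs[pairs["post_id"] == target]
    total = int(onto["n_synapses"].sum())
    if total == 0:
        raise ValueError(f"target {target!r} has no input synapses")
    from_sources = int(onto[onto["pre_id"].isin(source_set)]["n_synapses"].sum())
    return from_sources / total
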