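"""Synthetic connectome fixtures with planted ground truth.

The generator emulates the structure of a whole-brain connectome restricted
to a circadian network: cell-type-labelled neurons whose somata form compact
per-hemisphere clouds mirrored across the brain midline, sparse directed
synapse tables where planted cell-type motifs stand clearly above the
significance threshold while background edges stay below it, branching
skeletons rooted at the soma, cluster × gene expression summaries with
planted peptide/receptor signals across evidence methods, a ligand–receptor
catalog with potency values, and per-neuron transmitter predictions with
controlled confidence.  Every planted fact is recorded in a
:class:`GroundTruth` object so downstream recovery can be scored exactly.

The default configuration is a scaled-down clock network: one cluster per
major clock cell type (PDF-expressing small and large ventrolateral neurons,
dorsolateral and ITP-expressing lateral neurons, lateral posterior neurons,
and the dorsal groups), the reported strong cell-type motifs (e.g. the
contralateral DN_1p_A hub), the reported lateral-cholinergic /
dorsal-glutamatergic transmitter split, and a peptide complement anchored on
PDF/sNPF in the ventrolateral neurons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .connectivity import DEFAULT_THRESHOLDS
from .io import (
    ANNOTATION_COLUMNS,
    SWC_COLUMNS,
    SYNAPSE_COLUMNS,
    Skeleton,
    write_annotations,
    write_expression_long,
    write_lr_catalog,
    write_mapping_table,
    write_roster_table,
    write_skeletons,
    write_synapse_table,
)
from .paracrine import DEFAULT_PARAMS
from .roster import ClockRoster

# Expected mean pairwise distance of an isotropic 3-D Gaussian cloud with
# standard deviation sigma: sigma * sqrt(2) * E||Z_3|| = sigma * 2 * sqrt(2/pi) * sqrt(2).
_MPD_FACTOR = float(np.sqrt(2.0) * np.sqrt(2.0) * 2.0 / np.sqrt(np.pi))


class ConfigurationError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass(frozen=True)
class CellTypePlan:
    name: str
    clock_class: str | None
    n_per_hemisphere: int


@dataclass(frozen=True)
class SynapseMotif:
    """A planted cell-type-level connection: every (pre, post) neuron pair
    respecting the laterality is connected with probability ``probability``
    and a synapse count around ``mean_synapses``."""

    pre_type: str
    post_type: str
    laterality: str  # "ipsi" or "contra"
    mean_synapses: float
    probability: float = 1.0


@dataclass(frozen=True)
class PlantedExpression:
    """A (cluster, gene) signal exceeding both expression thresholds in the
    named evidence methods (default: the two counting methods)."""

    cluster: str
    gene: str
    mean_scaled: float
    fraction_expressing: float
    methods: tuple[str, ...] | None = None


@dataclass(frozen=True)
class LRPair:
    peptide: str
    receptor: str
    ec50_nm: float


_DEFAULT_CELL_TYPES = (
    CellTypePlan("s-LN_v", "LN_v_PDF", 4),
    CellTypePlan("l-LN_v", "LN_v_PDF", 4),
    CellTypePlan("LN_d_CRY+", "LN_d", 3),
    CellTypePlan("LN_ITP", "LN_ITP", 2),
    CellTypePlan("LPN", "LPN", 3),
    CellTypePlan("DN_1a", "DN_1a", 2),
    CellTypePlan("DN_1p_A", "DN_1p", 4),
    CellTypePlan("s-CPDN_3_C", "DN_3", 5),
    CellTypePlan("APDN_3", "DN_3", 3),
)

_DEFAULT_MOTIFS = (
    SynapseMotif("DN_1a", "LN_ITP", "ipsi", 14.0),
    SynapseMotif("DN_1p_A", "LN_ITP", "contra", 12.0),
    SynapseMotif("DN_1p_A", "LN_d_CRY+", "ipsi", 10.0),
    SynapseMotif("DN_1p_A", "s-CPDN_3_C", "contra", 12.0),
    SynapseMotif("s-CPDN_3_C", "DN_1p_A", "ipsi", 8.0),
    SynapseMotif("s-LN_v", "s-CPDN_3_C", "ipsi", 7.0),
)

_DEFAULT_PEPTIDES = ("Pdf", "sNPF", "Dh44", "AstC", "Proc")
_DEFAULT_RECEPTORS = ("Pdfr", "sNPF-R", "Dh44-R1", "AstC-R2", "Proc-R")

_DEFAULT_LR_PAIRS = (
    LRPair("Pdf", "Pdfr", 10.0),
    LRPair("sNPF", "sNPF-R", 150.0),
    LRPair("Dh44", "Dh44-R1", 300.0),
    LRPair("AstC", "AstC-R2", 80.0),
    LRPair("Proc", "Proc-R", 600.0),  # above the 500 nM potency cut
)

_DEFAULT_PLANTED_EXPRESSION = (
    # peptides
    PlantedExpression("s-LN_v", "Pdf", 2.5, 0.95),
    PlantedExpression("s-LN_v", "sNPF", 1.5, 0.85),
    PlantedExpression("l-LN_v", "Pdf", 3.0, 0.98),
    PlantedExpression("LPN", "AstC", 0.8, 0.70),
    PlantedExpression("DN_1a", "Dh44", 0.5, 0.60),
    PlantedExpression("DN_1p_A", "Proc", 1.0, 0.80),
    # single-method entry: must stay negative after evidence integration
    PlantedExpression("APDN_3", "Dh44", 0.6, 0.75, methods=("scrna",)),
    # receptors
    PlantedExpression("s-LN_v", "Pdfr", 0.30, 0.70),
    PlantedExpression("l-LN_v", "Pdfr", 0.30, 0.70),
    PlantedExpression("LN_d_CRY+", "Pdfr", 0.25, 0.65),
    PlantedExpression("LN_ITP", "Pdfr", 0.25, 0.65),
    PlantedExpression("LPN", "Pdfr", 0.25, 0.65),
    PlantedExpression("DN_1a", "Pdfr", 0.20, 0.60),
    PlantedExpression("DN_1p_A", "Pdfr", 0.20, 0.60),
    PlantedExpression("s-CPDN_3_C", "Pdfr", 0.20, 0.60),
    # receptor shown by live imaging alone: positive by the receptor rule
    PlantedExpression("APDN_3", "Pdfr", 0.20, 0.60, methods=("live_imaging",)),
    PlantedExpression("DN_1p_A", "sNPF-R", 0.20, 0.60),
    PlantedExpression("LPN", "sNPF-R", 0.15, 0.55),
    PlantedExpression("l-LN_v", "sNPF-R", 0.15, 0.55),
    PlantedExpression("LN_ITP", "Dh44-R1", 0.30, 0.60),
    PlantedExpression("DN_1p_A", "AstC-R2", 0.25, 0.60),
    PlantedExpression("LPN", "Proc-R", 0.30, 0.60),
)

# Lateral clock neurons are cholinergic, dorsal ones glutamatergic.
_DEFAULT_NT_LABELS: dict[str, str] = {
    "s-LN_v": "ACh",
    "l-LN_v": "ACh",
    "LN_d_CRY+": "ACh",
    "LN_ITP": "ACh",
    "LPN": "ACh",
    "DN_1a": "Glu",
    "DN_1p_A": "Glu",
    "s-CPDN_3_C": "Glu",
    "APDN_3": "Glu",
}


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic connectome.

    ``soma_dispersion_um`` is the per-cluster Gaussian soma spread;
    ``cluster_spacing_um`` the distance between neighbouring cluster centres
    within a hemisphere (chosen so that neighbouring arbors fall within the
    14 µm peptide diffusion range while distant clusters do not);
    ``distractor_offset_factor`` places distractor somata at that multiple of
    the expected mean pairwise soma distance away from the nearest cluster
    centroid, i.e. well outside the 2× acceptance radius of the roster
    filter.
    """

    seed: int = 0
    cell_types: tuple[CellTypePlan, ...] = _DEFAULT_CELL_TYPES
    soma_dispersion_um: float = 4.0
    cluster_spacing_um: float = 25.0
    hemisphere_offset_um: float = 60.0
    midline_x_um: float = 0.0
    skeleton_nodes: tuple[int, int] = (30, 60)
    skeleton_step_um: float = 2.0
    branch_probability: float = 0.3
    synapse_motifs: tuple[SynapseMotif, ...] = _DEFAULT_MOTIFS
    planted_min_synapses: int = DEFAULT_THRESHOLDS.significant
    background_edge_probability: float = 0.05
    distractor_count: int = 12
    distractor_offset_factor: float = 4.0
    peptides: tuple[str, ...] = _DEFAULT_PEPTIDES
    receptors: tuple[str, ...] = _DEFAULT_RECEPTORS
    planted_expression: tuple[PlantedExpression, ...] = _DEFAULT_PLANTED_EXPRESSION
    methods: tuple[str, ...] = ("scrna", "anatomical", "live_imaging")
    lr_pairs: tuple[LRPair, ...] = _DEFAULT_LR_PAIRS
    nt_labels: tuple[tuple[str, str], ...] = tuple(sorted(_DEFAULT_NT_LABELS.items()))
    nt_low_confidence_fraction: float = 0.25
    nt_anatomical_only: tuple[str, ...] = ("LN_ITP",)

    def nt_label_map(self) -> dict[str, str]:
        return dict(self.nt_labels)

    def gene_classes(self) -> dict[str, str]:
        out = {g: "peptide" for g in self.peptides}
        out.update({g: "receptor" for g in self.receptors})
        return out


def default_config(seed: int = 0) -> SynthConfig:
    return SynthConfig(seed=seed)


def validate_config(config: SynthConfig) -> None:
    names = [ct.name for ct in config.cell_types]
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate cell type names")
    known = set(names)
    for m in config.synapse_motifs:
        if m.pre_type not in known or m.post_type not in known:
            raise ConfigurationError(
                f"motif {m.pre_type}->{m.post_type} references an unknown cell type"
            )
        if m.laterality not in ("ipsi", "contra"):
            raise ConfigurationError(f"motif laterality {m.laterality!r} invalid")
        if m.mean_synapses < 0 or not (0.0 <= m.probability <= 1.0):
            raise ConfigurationError("motif mean must be >= 0 and probability in [0, 1]")
    motif_keys = [(m.pre_type, m.post_type, m.laterality) for m in config.synapse_motifs]
    if len(set(motif_keys)) != len(motif_keys):
        raise ConfigurationError("duplicate synapse motif")
    genes = set(config.peptides) | set(config.receptors)
    gene_classes = config.gene_classes()
    for p in config.planted_expression:
        if p.cluster not in known:
            raise ConfigurationError(f"planted expression for unknown cluster {p.cluster!r}")
        if p.gene not in genes:
            raise ConfigurationError(f"planted expression for unknown gene {p.gene!r}")
        if not (0.0 <= p.fraction_expressing <= 1.0):
            raise ConfigurationError("fraction_expressing must be in [0, 1]")
        # planted signals must actually clear the calling thresholds
        cut = (
            DEFAULT_PARAMS.peptide_expr_min
            if gene_classes[p.gene] == "peptide"
            else DEFAULT_PARAMS.receptor_expr_min
        )
        if not (p.mean_scaled > cut and p.fraction_expressing > DEFAULT_PARAMS.fraction_min):
            raise ConfigurationError(
                f"planted ({p.cluster}, {p.gene}) does not exceed the calling thresholds"
            )
        if p.methods is not None and any(m not in config.methods for m in p.methods):
            raise ConfigurationError(f"planted ({p.cluster}, {p.gene}) names unknown methods")
    pair_keys = [(lr.peptide, lr.receptor) for lr in config.lr_pairs]
    if len(set(pair_keys)) != len(pair_keys):
        raise ConfigurationError("duplicate ligand-receptor pair")
    for lr in config.lr_pairs:
        if lr.ec50_nm <= 0:
            raise ConfigurationError(f"EC50 must be > 0 for pair {lr.peptide}->{lr.receptor}")
        if lr.peptide not in config.peptides or lr.receptor not in config.receptors:
            raise ConfigurationError(
                f"catalog pair {lr.peptide}->{lr.receptor} references unknown genes"
            )
    nt = config.nt_label_map()
    for ct in nt:
        if ct not in known:
            raise ConfigurationError(f"transmitter label for unknown cell type {ct!r}")
    for ct in config.nt_anatomical_only:
        if ct not in nt:
            raise ConfigurationError(
                f"anatomical-only cell type {ct!r} has no transmitter label"
            )
    if config.skeleton_nodes[0] < 1 or config.skeleton_nodes[1] < config.skeleton_nodes[0]:
        raise ConfigurationError("skeleton_nodes must be a valid (low, high) range")
    if config.soma_dispersion_um <= 0 or config.cluster_spacing_um <= 0:
        raise ConfigurationError("geometry scales must be > 0")
    if not (0.0 <= config.nt_low_confidence_fraction < 1.0):
        raise ConfigurationError("nt_low_confidence_fraction must be in [0, 1)")


@dataclass
class GroundTruth:
    """Planted facts of one synthetic connectome."""

    true_roster: dict[str, tuple[str, str]]
    planted_cluster_edges: set[tuple[str, str, str]]
    planted_paracrine_edges: set[tuple[str, str, str, str]]
    planted_nt: dict[str, str]
    total_synapses: int

    def to_dict(self) -> dict:
        return {
            "true_roster": {
                nid: list(label) for nid, label in sorted(self.true_roster.items())
            },
            "planted_cluster_edges": sorted(list(e) for e in self.planted_cluster_edges),
            "planted_paracrine_edges": sorted(
                list(e) for e in self.planted_paracrine_edges
            ),
            "planted_nt": dict(sorted(self.planted_nt.items())),
            "total_synapses": self.total_synapses,
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            true_roster={k: (v[0], v[1]) for k, v in d["true_roster"].items()},
            planted_cluster_edges={tuple(e) for e in d["planted_cluster_edges"]},
            planted_paracrine_edges={tuple(e) for e in d["planted_paracrine_edges"]},
            planted_nt=dict(d["planted_nt"]),
            total_synapses=int(d["total_synapses"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SyntheticConnectome:
    """Bundle of generated tables plus the bookkeeping a pipeline run needs."""

    neurons: pd.DataFrame
    synapses: pd.DataFrame
    skeletons: dict[str, Skeleton]
    morphology_clusters: dict[str, str]
    seed_roster: ClockRoster
    nt_predictions: pd.DataFrame
    nt_overrides: dict[str, str]
    ground_truth: GroundTruth


def _cluster_centers(config: SynthConfig) -> dict[tuple[str, str], np.ndarray]:
    """Deterministic per (cell type, hemisphere) soma-cloud centres, mirrored
    across the midline plane x = midline_x."""
    centers: dict[tuple[str, str], np.ndarray] = {}
    for i, ct in enumerate(config.cell_types):
        y = i * config.cluster_spacing_um
        right = np.array([config.midline_x_um + config.hemisphere_offset_um, y, 0.0])
        left = right.copy()
        left[0] = 2 * config.midline_x_um - right[0]
        centers[(ct.name, "right")] = right
        centers[(ct.name, "left")] = left
    return centers


def _grow_skeleton(
    neuron_id: str, soma: np.ndarray, rng: np.random.Generator, config: SynthConfig
) -> Skeleton:
    lo, hi = config.skeleton_nodes
    n = int(rng.integers(lo, hi + 1))
    coords = np.empty((n, 3))
    parents = np.empty(n, dtype=int)
    coords[0] = soma
    parents[0] = -1
    for k in range(1, n):
        # Extend from the previous node most of the time; otherwise branch
        # from a random earlier node.
        if k == 1 or rng.random() > config.branch_probability:
            parent = k - 1
        else:
            parent = int(rng.integers(0, k))
        step = rng.normal(0.0, config.skeleton_step_um, size=3)
        coords[k] = coords[parent] + step
        parents[k] = parent
    nodes = pd.DataFrame(
        {
            "node_id": np.arange(1, n + 1),
            "structure": np.concatenate(([1], np.full(n - 1, 3))).astype(int),
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "radius": np.full(n, 0.1),
            "parent_id": np.where(parents == -1, -1, parents + 1),
        },
        columns=SWC_COLUMNS,
    )
    return Skeleton(neuron_id=neuron_id, nodes=nodes)


def build_synthetic_connectome(config: SynthConfig) -> SyntheticConnectome:
    """Generate neurons, synapses, skeletons, transmitter predictions and the
    planted ground truth.  Deterministic given the config (seed included)."""
    validate_config(config)
    rng = np.random.default_rng(config.seed)
    centers = _cluster_centers(config)
    expected_mpd = _MPD_FACTOR * config.soma_dispersion_um

    # --- neurons -----------------------------------------------------------
    rows = []
    neurons_by_type: dict[str, list[str]] = {}
    for ct in config.cell_types:
        for hemi in ("left", "right"):
            center = centers[(ct.name, hemi)]
            for k in range(ct.n_per_hemisphere):
                nid = f"{ct.name}.{hemi[0]}{k}"
                soma = center + rng.normal(0.0, config.soma_dispersion_um, size=3)
                rows.append(
                    {
                        "neuron_id": nid,
                        "cell_type": ct.name,
                        "super_class": "central",
                        "hemilineage": f"hl:{ct.name}",
                        "hemisphere": hemi,
                        "x": soma[0],
                        "y": soma[1],
                        "z": soma[2],
                    }
                )
                neurons_by_type.setdefault(ct.name, []).append(nid)
    # Distractors live far below the cluster band: at least
    # distractor_offset_factor × expected mean pairwise distance from every
    # cluster centroid, so the soma-distance filter must reject them.
    offset = config.distractor_offset_factor * expected_mpd
    distractors: list[str] = []
    for k in range(config.distractor_count):
        hemi = "left" if k % 2 == 0 else "right"
        x = config.midline_x_um + (
            config.hemisphere_offset_um if hemi == "right" else -config.hemisphere_offset_um
        )
        nid = f"distractor.{k}"
        soma = np.array([x, -offset - 3.0 * k, 0.0]) + rng.normal(0.0, 1.0, size=3)
        rows.append(
            {
                "neuron_id": nid,
                "cell_type": f"distractor_{k}",
                "super_class": "central",
                "hemilineage": "hl:distractor",
                "hemisphere": hemi,
                "x": soma[0],
                "y": soma[1],
                "z": soma[2],
            }
        )
        distractors.append(nid)
    neurons = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)

    # --- skeletons ---------------------------------------------------------
    skeletons: dict[str, Skeleton] = {}
    for r in neurons.itertuples(index=False):
        soma = np.array([r.x, r.y, r.z])
        skeletons[r.neuron_id] = _grow_skeleton(r.neuron_id, soma, rng, config)

    # --- synapses ----------------------------------------------------------
    hemi_of = dict(zip(neurons["neuron_id"], neurons["hemisphere"]))
    syn_rows: list[tuple[str, str, int]] = []
    realized_motifs: set[tuple[str, str, str]] = set()
    for m in config.synapse_motifs:
        for pre in neurons_by_type[m.pre_type]:
            for post in neurons_by_type[m.post_type]:
                if pre == post:
                    continue
                same = hemi_of[pre] == hemi_of[post]
                if (m.laterality == "ipsi") != same:
                    continue
                if rng.random() >= m.probability:
                    continue
                count = max(
                    int(rng.poisson(m.mean_synapses)), config.planted_min_synapses
                )
                syn_rows.append((pre, post, count))
                realized_motifs.add((m.pre_type, m.post_type, m.laterality))
    # Sub-threshold background noise between pairs not covered by any motif.
    motif_type_pairs = {(m.pre_type, m.post_type) for m in config.synapse_motifs}
    type_of = dict(zip(neurons["neuron_id"], neurons["cell_type"]))
    all_ids = list(neurons["neuron_id"])
    if config.background_edge_probability > 0 and config.planted_min_synapses > 1:
        for pre in all_ids:
            for post in all_ids:
                if pre == post:
                    continue
                if (type_of[pre], type_of[post]) in motif_type_pairs:
                    continue
                if rng.random() < config.background_edge_probability:
                    count = int(rng.integers(1, config.planted_min_synapses))
                    syn_rows.append((pre, post, count))
    synapses = pd.DataFrame(syn_rows, columns=SYNAPSE_COLUMNS)
    synapses = (
        synapses.groupby(["pre_id", "post_id"], as_index=False, sort=True)["n_synapses"]
        .sum()
        if len(synapses)
        else synapses
    )

    # --- transmitter predictions -------------------------------------------
    nt_map = config.nt_label_map()
    planted_nt: dict[str, str] = {}
    pred_rows = []
    anatomical_only = set(config.nt_anatomical_only)
    for ct in config.cell_types:
        transmitter = nt_map.get(ct.name)
        members = neurons_by_type[ct.name]
        if transmitter is None:
            continue
        for nid in members:
            planted_nt[nid] = transmitter
        if ct.name in anatomical_only:
            low = set(members)  # EM prediction uninformative for the whole type
        else:
            order = list(members)
            rng.shuffle(order)
            n_low = int(np.floor(config.nt_low_confidence_fraction * len(order)))
            low = set(order[:n_low])
        for nid in members:
            if nid in low:
                conf = float(rng.uniform(0.30, 0.60))
            else:
                conf = float(rng.uniform(0.70, 0.99))
            pred_rows.append((nid, transmitter, conf))
    for nid in distractors:
        planted_nt[nid] = "GABA"
        pred_rows.append((nid, "GABA", float(rng.uniform(0.70, 0.99))))
    nt_predictions = pd.DataFrame(
        pred_rows, columns=["neuron_id", "predicted", "confidence"]
    )
    nt_overrides = {ct: nt_map[ct] for ct in config.nt_anatomical_only}

    # --- roster bookkeeping --------------------------------------------------
    true_roster: dict[str, tuple[str, str]] = {}
    for ct in config.cell_types:
        if ct.clock_class is None:
            continue
        for nid in neurons_by_type[ct.name]:
            true_roster[nid] = (ct.clock_class, ct.name)
    seed_members: dict[str, tuple[str, str]] = {}
    for ct in config.cell_types:
        if ct.clock_class is None:
            continue
        for hemi in ("left", "right"):
            first = min(
                nid for nid in neurons_by_type[ct.name] if hemi_of[nid] == hemi
            )
            seed_members[first] = (ct.clock_class, ct.name)
    seed_roster = ClockRoster(seed_members)
    morphology_clusters: dict[str, str] = {}
    clock_types = [ct.name for ct in config.cell_types if ct.clock_class is not None]
    for ct_name in clock_types:
        for nid in neurons_by_type[ct_name]:
            morphology_clusters[nid] = f"morph:{ct_name}"
    for k, nid in enumerate(distractors):
        morphology_clusters[nid] = f"morph:{clock_types[k % len(clock_types)]}"

    # --- paracrine bookkeeping ----------------------------------------------
    # Integrated expression calls implied by the planted entries, under the
    # study's default thresholds (validated above to clear them).
    counting_methods = [
        m for m in config.methods if m != DEFAULT_PARAMS.live_imaging_method
    ]
    gene_classes = config.gene_classes()
    positive: dict[str, set[tuple[str, str]]] = {"peptide": set(), "receptor": set()}
    for p in config.planted_expression:
        methods = p.methods if p.methods is not None else tuple(counting_methods)
        n_counting = sum(m in counting_methods for m in methods)
        gc = gene_classes[p.gene]
        ok = n_counting >= DEFAULT_PARAMS.min_methods
        if gc == "receptor" and DEFAULT_PARAMS.live_imaging_method in methods:
            ok = True
        if ok:
            positive[gc].add((p.cluster, p.gene))
    # Brute-force cluster distances from the generated skeleton nodes.
    coords_by_cluster = {
        ct: np.vstack([skeletons[nid].coords() for nid in neurons_by_type[ct]])
        for ct in clock_types
    }
    planted_paracrine: set[tuple[str, str, str, str]] = set()
    for lr in config.lr_pairs:
        if lr.ec50_nm > DEFAULT_PARAMS.ec50_max:
            continue
        sources = [c for c, g in positive["peptide"] if g == lr.peptide]
        targets = [c for c, g in positive["receptor"] if g == lr.receptor]
        for src in sources:
            for tgt in targets:
                if src == tgt:
                    d = 0.0
                else:
                    d = float(
                        cdist(coords_by_cluster[src], coords_by_cluster[tgt]).min()
                    )
                if d <= DEFAULT_PARAMS.diffusion_max:
                    planted_paracrine.add((src, tgt, lr.peptide, lr.receptor))

    ground_truth = GroundTruth(
        true_roster=true_roster,
        planted_cluster_edges=realized_motifs,
        planted_paracrine_edges=planted_paracrine,
        planted_nt=planted_nt,
        total_synapses=int(synapses["n_synapses"].sum()) if len(synapses) else 0,
    )
    return SyntheticConnectome(
        neurons=neurons,
        synapses=synapses,
        skeletons=skeletons,
        morphology_clusters=morphology_clusters,
        seed_roster=seed_roster,
        nt_predictions=nt_predictions,
        nt_overrides=nt_overrides,
        ground_truth=ground_truth,
    )


def build_synthetic_expression(config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster × gene × method expression table.

    Planted entries carry their configured (above-threshold) values in the
    named methods; every other record gets background values below the mean
    cut (receptor cut 0.067 is the tighter one) and below the cell-fraction
    cut, so unplanted entries can never be called.  Returns the long table
    and a bookkeeping table of planted flags.
    """
    validate_config(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    clusters = [ct.name for ct in config.cell_types if ct.clock_class is not None]
    planted = {
        (p.cluster, p.gene, m): p
        for p in config.planted_expression
        for m in (p.methods if p.methods is not None else tuple(
            mm for mm in config.methods if mm != DEFAULT_PARAMS.live_imaging_method
        ))
    }
    genes = list(config.peptides) + list(config.receptors)
    rows = []
    flags = []
    for cluster in clusters:
        for gene in genes:
            for method in config.methods:
                p = planted.get((cluster, gene, method))
                if p is not None:
                    mean, frac, is_planted = p.mean_scaled, p.fraction_expressing, True
                else:
                    mean = float(rng.uniform(0.0, 0.04))
                    frac = float(rng.uniform(0.0, 0.30))
                    is_planted = False
                rows.append((cluster, gene, method, mean, frac))
                flags.append((cluster, gene, method, is_planted))
    expression = pd.DataFrame(
        rows, columns=["cluster", "gene", "method", "mean_scaled", "fraction_expressing"]
    )
    evidence = pd.DataFrame(flags, columns=["cluster", "gene", "method", "planted"])
    return expression, evidence


def build_ligand_receptor_catalog(config: SynthConfig) -> pd.DataFrame:
    """One catalog row per (peptide, receptor) with its EC50 in nM."""
    validate_config(config)
    return pd.DataFrame(
        [(lr.peptide, lr.receptor, lr.ec50_nm) for lr in config.lr_pairs],
        columns=["peptide", "receptor", "ec50_nm"],
    )


def write_synthetic_dataset(
    conn: SyntheticConnectome,
    expression: pd.DataFrame,
    catalog: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, str]:
    """Write the whole fixture as plain-text files; returns relative paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_annotations(conn.neurons, out / "annotations.tsv")
    write_synapse_table(conn.synapses, out / "synapses.tsv")
    write_skeletons(conn.skeletons, out / "skeletons")
    write_mapping_table(
        conn.morphology_clusters, "neuron_id", "morphology_cluster",
        out / "morphology_clusters.tsv",
    )
    write_roster_table(conn.seed_roster.to_frame(), out / "seed_roster.tsv")
    conn.nt_predictions.to_csv(out / "nt_predictions.tsv", sep="\t", index=False)
    write_mapping_table(
        conn.nt_overrides, "cell_type", "transmitter", out / "nt_overrides.tsv"
    )
    write_expression_long(expression, out / "expression.tsv")
    write_lr_catalog(catalog, out / "lr_catalog.tsv")
    conn.ground_truth.save(out / "ground_truth.json")
    return {
        "annotations": "annotations.tsv",
        "synapses": "synapses.tsv",
        "skeletons": "skeletons",
        "morphology_clusters": "morphology_clusters.tsv",
        "seed_roster": "seed_roster.tsv",
        "nt_predictions": "nt_predictions.tsv",
        "nt_overrides": "nt_overrides.tsv",
        "expression": "expression.tsv",
        "lr_catalog": "lr_catalog.tsv",
        "ground_truth": "ground_truth.json",
    }
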