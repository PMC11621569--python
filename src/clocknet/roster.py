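"""Iterative identification of circadian clock neurons and the roster census.

The clock network of the fly brain is identified from a small set of
confidently known neurons (the seed roster) by alternating three steps until
a fixed point:

1. *expand*: every neuron sharing a morphology cluster with a roster member
   becomes a candidate (morphology clustering itself is an input, not
   computed here);
2. *filter*: a candidate is kept only if its soma lies less than twice the
   cluster's mean pairwise soma distance away from the same-hemisphere
   cluster centroid — clock somata of one cell type form compact clouds per
   hemisphere;
3. *close*: cell types are atomic, so if any neuron of a cell type is in the
   roster, all neurons of that cell type join with the same clock labels.

The procedure is monotone (the roster never shrinks) and idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .io import ROSTER_COLUMNS

# The eight anatomical clock classes and their DN/LN super class.
CLOCK_CLASS_SUPER: dict[str, str] = {
    "DN_1a": "DN",
    "DN_1p": "DN",
    "DN_2": "DN",
    "DN_3": "DN",
    "LPN": "LN",
    "LN_d": "LN",
    "LN_ITP": "LN",
    "LN_v_PDF": "LN",
}


class UndefinedDistanceError(ValueError):
    """Mean pairwise distance requested for fewer than two somata."""


class RosterConflictError(ValueError):
    """One cell type would be labelled with two different clock classes."""


ClockLabel = tuple[str, str]  # (clock_class, clock_cell_type)


@dataclass
class ClockRoster:
    """Membership map: neuron_id → (clock_class, clock_cell_type)."""

    membership: dict[str, ClockLabel] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.membership)

    def __contains__(self, neuron_id: str) -> bool:
        return neuron_id in self.membership

    def ids(self) -> set[str]:
        return set(self.membership)

    def copy(self) -> "ClockRoster":
        return ClockRoster(dict(self.membership))

    def members_of_cell_type(self, clock_cell_type: str) -> set[str]:
        return {
            nid
            for nid, (_, ct) in self.membership.items()
            if ct == clock_cell_type
        }

    def cluster_map(self) -> dict[str, str]:
        """neuron_id → clock_cell_type, the grouping used by connectivity."""
        return {nid: ct for nid, (_, ct) in self.membership.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"neuron_id": nid, "clock_class": cc, "clock_cell_type": ct}
            for nid, (cc, ct) in sorted(self.membership.items())
        ]
        return pd.DataFrame(rows, columns=ROSTER_COLUMNS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ClockRoster":
        return cls(
            {
                str(r.neuron_id): (str(r.clock_class), str(r.clock_cell_type))
                for r in df.itertuples(index=False)
            }
        )


def _soma_index(annotations: pd.DataFrame) -> pd.DataFrame:
    return annotations.set_index("neuron_id")


def mean_pairwise_soma_distance(
    members: Iterable[str],
    annotations: pd.DataFrame,
    hemisphere: str,
) -> float:
    """Mean Euclidean distance over all unordered soma pairs in one hemisphere."""
    ann = _soma_index(annotations)
    ids = [m for m in members if ann.at[m, "hemisphere"] == hemisphere]
    if len(ids) < 2:
        raise UndefinedDistanceError(
            f"need >=2 members in hemisphere {hemisphere!r}, got {len(ids)}"
        )
    xyz = ann.loc[ids, ["x", "y", "z"]].to_numpy(dtype=float)
    return float(pdist(xyz).mean())


def soma_distance_filter(
    candidates: Iterable[str],
    cluster_members: Iterable[str],
    annotations: pd.DataFrame,
) -> set[str]:
    """Keep candidates lying < 2 × the cluster's mean pairwise soma distance
    from the same-hemisphere cluster soma centroid (strict inequality).

    Candidates in a hemisphere with fewer than two cluster members cannot be
    assessed and are rejected with a warning.
    """
    ann = _soma_index(annotations)
    members = list(dict.fromkeys(cluster_members))
    accepted: set[str] = set()
    # Per-hemisphere radius and centroid, computed once.
    limits: dict[str, tuple[np.ndarray, float]] = {}
    for hemi in sorted(set(ann.loc[members, "hemisphere"])):
        hemi_ids = [m for m in members if ann.at[m, "hemisphere"] == hemi]
        if len(hemi_ids) < 2:
            continue
        xyz = ann.loc[hemi_ids, ["x", "y", "z"]].to_numpy(dtype=float)
        limits[hemi] = (xyz.mean(axis=0), 2.0 * float(pdist(xyz).mean()))
    for cand in candidates:
        hemi = ann.at[cand, "hemisphere"]
        if hemi not in limits:
            warnings.warn(
                f"candidate {cand}: no assessable cluster members in hemisphere {hemi!r};"
                " rejected",
                stacklevel=2,
            )
            continue
        centroid, radius = limits[hemi]
        soma = ann.loc[cand, ["x", "y", "z"]].to_numpy(dtype=float)
        if float(np.linalg.norm(soma - centroid)) < radius:
            accepted.add(cand)
    return accepted


def cell_type_closure(roster: ClockRoster, annotations: pd.DataFrame) -> ClockRoster:
    """Extend the roster to all neurons of every member cell type.

    Cell types are uniquely identifiable units: one member implies all.  A
    cell type carrying two different clock labels is a hard conflict (the
    original analysis resolved such cases manually).
    """
    ann = _soma_index(annotations)
    label_by_type: dict[str, ClockLabel] = {}
    for nid, label in roster.membership.items():
        ct = str(ann.at[nid, "cell_type"])
        seen = label_by_type.get(ct)
        if seen is not None and seen != label:
            raise RosterConflictError(
                f"cell type {ct!r} labelled both {seen} and {label}"
            )
        label_by_type[ct] = label
    out = roster.copy()
    for ct, label in label_by_type.items():
        for nid in annotations.loc[annotations["cell_type"] == ct, "neuron_id"]:
            prev = out.membership.get(nid)
            if prev is not None and prev != label:
                raise RosterConflictError(
                    f"neuron {nid} labelled both {prev} and {label}"
                )
            out.membership[nid] = label
    return out


def identify_clock_neurons(
    seed_roster: ClockRoster,
    morphology_clusters: Mapping[str, str],
    annotations: pd.DataFrame,
    max_iter: int = 10,
    allow: Iterable[str] | None = None,
    deny: Iterable[str] | None = None,
) -> tuple[ClockRoster, list[dict]]:
    """Run expand → filter → close to a fixed point.

    ``allow``/``deny`` stand in for the manual morphology-comparison step of
    the original pipeline: allowed neurons bypass the soma-distance filter,
    denied neurons are never admitted.

    Returns the final roster and a per-iteration log.  If ``max_iter`` is
    reached before the fixed point, the partial result is returned with a
    warning and the log's last entry flags it.
    """
    if len(seed_roster) == 0:
        raise ValueError("seed roster is empty")
    allow = set(allow or ())
    deny = set(deny or ())
    ann = _soma_index(annotations)
    roster = cell_type_closure(seed_roster, annotations)
    log: list[dict] = []
    converged = False
    for iteration in range(1, max_iter + 1):
        added: set[str] = set()
        # Group current members by morphology cluster, then by clock label.
        members_by_morph: dict[str, list[str]] = {}
        for nid in roster.ids():
            mc = morphology_clusters.get(nid)
            if mc is not None:
                members_by_morph.setdefault(mc, []).append(nid)
        candidate_labels: dict[str, set[ClockLabel]] = {}
        for mc, members in sorted(members_by_morph.items()):
            co_members = sorted(
                nid
                for nid, cluster in morphology_clusters.items()
                if cluster == mc and nid not in roster and nid not in deny
            )
            if not co_members:
                continue
            labels = sorted({roster.membership[m] for m in members})
            for label in labels:
                cluster_ids = roster.members_of_cell_type(label[1])
                passed = soma_distance_filter(co_members, cluster_ids, annotations)
                passed |= allow & set(co_members)
                for cand in passed:
                    candidate_labels.setdefault(cand, set()).add(label)
        for cand, labels in sorted(candidate_labels.items()):
            classes = {cc for cc, _ in labels}
            if len(classes) > 1:
                raise RosterConflictError(
                    f"candidate {cand} accepted by clock classes {sorted(classes)}"
                )
            if len(labels) > 1:
                # Same clock class, several cell types: take the label whose
                # same-hemisphere centroid is nearest (deterministic).
                hemi = ann.at[cand, "hemisphere"]
                soma = ann.loc[cand, ["x", "y", "z"]].to_numpy(dtype=float)

                def _dist(label: ClockLabel) -> tuple[float, ClockLabel]:
                    ids = [
                        m
                        for m in roster.members_of_cell_type(label[1])
                        if ann.at[m, "hemisphere"] == hemi
                    ]
                    xyz = ann.loc[ids, ["x", "y", "z"]].to_numpy(dtype=float)
                    return float(np.linalg.norm(soma - xyz.mean(axis=0))), label

                _, label = min(_dist(lb) for lb in sorted(labels))
            else:
                (label,) = labels
            roster.membership[cand] = label
            added.add(cand)
        roster = cell_type_closure(roster, annotations)
        log.append(
            {
                "iteration": iteration,
                "added": sorted(added),
                "roster_size": len(roster),
                "converged": not added,
            }
        )
        if not added:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"identify_clock_neurons: max_iter={max_iter} reached before fixed point;"
            " result is partial",
            stacklevel=2,
        )
    return roster, log


@dataclass
class Census:
    """Hierarchical roster counts: cell type ⊂ clock class ⊂ DN/LN super class."""

    by_cell_type: dict[str, int]
    by_class: dict[str, int]
    by_super_class: dict[str, int]
    total: int

    def to_dict(self) -> dict:
        return {
            "by_cell_type": dict(sorted(self.by_cell_type.items())),
            "by_class": dict(sorted(self.by_class.items())),
            "by_super_class": dict(sorted(self.by_super_class.items())),
            "total": self.total,
        }


def _super_class_of(clock_class: str) -> str:
    if clock_class in CLOCK_CLASS_SUPER:
        return CLOCK_CLASS_SUPER[clock_class]
    if clock_class.startswith("DN"):
        return "DN"
    if clock_class.startswith("LN") or clock_class.startswith("LPN"):
        return "LN"
    return "other"


def census(roster: ClockRoster) -> Census:
    """Count roster members per clock cell type, clock class and super class.

    Totals are conserved across levels by construction: each neuron is
    counted exactly once at every level.
    """
    by_cell_type: dict[str, int] = {}
    by_class: dict[str, int] = {}
    by_super: dict[str, int] = {}
    for _, (clock_class, cell_type) in roster.membership.items():
        by_cell_type[cell_type] = by_cell_type.get(cell_type, 0) + 1
        by_class[clock_class] = by_class.get(clock_class, 0) + 1
        sc = _super_class_of(clock_class)
        by_super[sc] = by_super.get(sc, 0) + 1
    return Census(by_cell_type, by_class, by_super, len(roster))
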