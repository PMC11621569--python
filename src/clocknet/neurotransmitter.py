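"""Consolidation of per-neuron fast-neurotransmitter predictions.

Electron-microscopy-based classifiers emit a transmitter and a confidence
per neuron.  Consolidation applies, in order:

1. confidence filter — keep a prediction only above 62% certainty, and only
   for the fast transmitters acetylcholine (ACh), glutamate (Glu) and GABA;
2. group fill by cell type, then by hemilineage — a neuron with no confident
   prediction inherits the group transmitter when every assigned group
   member agrees (one fast transmitter per hemilineage; mixed groups are
   left untouched);
3. anatomical overrides — transmitter-marker expression mapping (ChAT /
   VGlut / VGAT driver lines) fills remaining unknowns per cell type, but
   never overwrites a confident EM assignment; disagreements are reported as
   conflicts, not applied.

A neuron carries at most one fast transmitter throughout (Dale's principle),
and the number of unknowns never increases along the chain.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

FAST_TRANSMITTERS = ("ACh", "Glu", "GABA")
UNKNOWN = "unknown"
ASSIGNMENT_COLUMNS = ["neuron_id", "transmitter", "provenance"]

DEFAULT_MIN_CONFIDENCE = 0.62


class OverrideConfigError(ValueError):
    """An anatomical override names a cell type absent from the annotations."""


def filter_confident(
    predictions: pd.DataFrame,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> pd.DataFrame:
    """Assign a transmitter iff confidence is strictly above the cut and the
    predicted class is a fast transmitter; everything else is unknown."""
    rows = []
    for r in predictions.itertuples(index=False):
        if r.predicted in FAST_TRANSMITTERS and r.confidence > min_confidence:
            rows.append((r.neuron_id, r.predicted, "em_prediction"))
        else:
            rows.append((r.neuron_id, UNKNOWN, ""))
    return pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)


def harmonize_by_group(
    assignments: pd.DataFrame,
    annotations: pd.DataFrame,
    group_key: str,
) -> pd.DataFrame:
    """Fill unknowns from unanimous groups (``group_key`` ∈ {cell_type,
    hemilineage}).  Groups with two or more distinct assigned transmitters
    give no information and their unknowns stay unknown."""
    if group_key not in annotations.columns:
        raise KeyError(f"annotation column {group_key!r} not present")
    group_of = dict(zip(annotations["neuron_id"], annotations[group_key]))
    df = assignments.copy()
    groups = df["neuron_id"].map(group_of)
    fill: dict[str, str] = {}
    for group, sub in df.groupby(groups):
        known = sorted(set(sub.loc[sub["transmitter"] != UNKNOWN, "transmitter"]))
        if len(known) == 1:
            fill[group] = known[0]
    mask = (df["transmitter"] == UNKNOWN) & groups.map(lambda g: g in fill)
    df.loc[mask, "transmitter"] = groups[mask].map(fill)
    df.loc[mask, "provenance"] = "group_fill"
    return df


def apply_anatomical_overrides(
    assignments: pd.DataFrame,
    annotations: pd.DataFrame,
    overrides: Mapping[str, str],
) -> tuple[pd.DataFrame, list[str]]:
    """Fill unknown neurons of the named cell types from anatomical mapping.

    Existing assignments take precedence; an override disagreeing with an
    assigned transmitter is recorded as a conflict and not applied.
    """
    known_types = set(annotations["cell_type"])
    for cell_type, transmitter in overrides.items():
        if cell_type not in known_types:
            raise OverrideConfigError(f"override for unknown cell type {cell_type!r}")
        if transmitter not in FAST_TRANSMITTERS:
            raise OverrideConfigError(
                f"override transmitter {transmitter!r} is not one of {FAST_TRANSMITTERS}"
            )
    type_of = dict(zip(annotations["neuron_id"], annotations["cell_type"]))
    df = assignments.copy()
    conflicts: list[str] = []
    for i in df.index:
        nid = df.at[i, "neuron_id"]
        override = overrides.get(type_of.get(nid, ""))
        if override is None:
            continue
        current = df.at[i, "transmitter"]
        if current == UNKNOWN:
            df.at[i, "transmitter"] = override
            df.at[i, "provenance"] = "anatomical"
        elif current != override:
            conflicts.append(
                f"neuron {nid}: anatomical override {override} vs assigned {current}"
                " (override not applied)"
            )
    return df, conflicts


def consolidate(
    predictions: pd.DataFrame,
    annotations: pd.DataFrame,
    overrides: Mapping[str, str] | None = None,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
    group_order: Sequence[str] = ("cell_type", "hemilineage"),
) -> tuple[pd.DataFrame, list[str]]:
    """Full rule chain: confidence filter → group fill (cell type, then
    hemilineage) → anatomical overrides.  Deterministic; returns the
    assignment table and the conflict log."""
    assignments = filter_confident(predictions, min_confidence)
    for key in group_order:
        assignments = harmonize_by_group(assignments, annotations, key)
    conflicts: list[str] = []
    if overrides:
        assignments, conflicts = apply_anatomical_overrides(
            assignments, annotations, overrides
        )
    return assignments, conflicts


def hemilineage_conflicts(
    assignments: pd.DataFrame, annotations: pd.DataFrame
) -> list[str]:
    """Hemilineages whose assigned members carry more than one transmitter."""
    hl = dict(zip(annotations["neuron_id"], annotations["hemilineage"]))
    out = []
    assigned = assignments[assignments["transmitter"] != UNKNOWN]
    for group, sub in assigned.groupby(assigned["neuron_id"].map(hl)):
        kinds = sorted(set(sub["transmitter"]))
        if len(kinds) > 1:
            out.append(f"hemilineage {group}: mixed transmitters {kinds}")
    return out
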