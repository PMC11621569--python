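"""Readers and writers for connectome-style file formats.

Everything on disk is plain text: TSV tables with a mandatory header row,
SWC skeleton files, and JSON for configuration, ground truth and reports.
The internal length unit is the micrometre everywhere; any conversion from
raw voxel or nanometre coordinates belongs at this boundary and nowhere
else, because the biologically meaningful distance thresholds (peptide
diffusion ranges of 1 and 14 µm) are stated in µm.

Neuron identifiers are opaque strings.  Connectome root ids exceed 53-bit
float precision, so id columns are never parsed numerically: a round trip
through a float would silently corrupt them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Malformed input file; the message names the offending file and line."""


ANNOTATION_COLUMNS = [
    "neuron_id",
    "cell_type",
    "super_class",
    "hemilineage",
    "hemisphere",
    "x",
    "y",
    "z",
]
SYNAPSE_COLUMNS = ["pre_id", "post_id", "n_synapses"]
EXPRESSION_COLUMNS = ["cluster", "gene", "method", "mean_scaled", "fraction_expressing"]
CATALOG_COLUMNS = ["peptide", "receptor", "ec50_nm"]
ROSTER_COLUMNS = ["neuron_id", "clock_class", "clock_cell_type"]
SWC_COLUMNS = ["node_id", "structure", "x", "y", "z", "radius", "parent_id"]

HEMISPHERES = ("left", "right")


# ---------------------------------------------------------------------------
# Skeletons (SWC)
# ---------------------------------------------------------------------------


@dataclass
class Skeleton:
    """A neuron skeleton: a rooted tree of 3-D nodes in µm.

    ``nodes`` follows the SWC column layout.  Exactly one node has
    ``parent_id == -1`` (the root, by convention the soma); every other
    parent pointer must resolve to a node id in the same skeleton, and the
    parent relation must form a single connected tree.
    """

    neuron_id: str
    nodes: pd.DataFrame

    def __post_init__(self) -> None:
        nodes = self.nodes
        missing = [c for c in SWC_COLUMNS if c not in nodes.columns]
        if missing:
            raise FormatError(f"skeleton {self.neuron_id}: missing columns {missing}")
        ids = nodes["node_id"].to_numpy()
        if len(ids) == 0:
            raise FormatError(f"skeleton {self.neuron_id}: empty skeleton")
        if len(np.unique(ids)) != len(ids):
            raise FormatError(f"skeleton {self.neuron_id}: duplicate node ids")
        parents = nodes["parent_id"].to_numpy()
        roots = ids[parents == -1]
        if len(roots) == 0:
            raise FormatError(f"skeleton {self.neuron_id}: missing root (no parent_id -1)")
        if len(roots) > 1:
            raise FormatError(
                f"skeleton {self.neuron_id}: multiple roots {sorted(roots.tolist())}"
            )
        known = set(ids.tolist())
        dangling = [p for p in parents if p != -1 and p not in known]
        if dangling:
            raise FormatError(
                f"skeleton {self.neuron_id}: unresolved parent ids {sorted(set(dangling))}"
            )
        # With a single root and resolved parents, the parent-pointer graph has
        # n-1 edges; it is a tree iff it is connected (a cycle would strand a
        # component away from the root).
        if len(ids) > 1:
            g = nx.Graph()
            g.add_nodes_from(ids.tolist())
            g.add_edges_from(
                (int(n), int(p))
                for n, p in zip(ids, parents)
                if p != -1
            )
            if not nx.is_connected(g):
                raise FormatError(
                    f"skeleton {self.neuron_id}: cyclic parent links (graph not a rooted tree)"
                )

    @property
    def root_id(self) -> int:
        parents = self.nodes["parent_id"].to_numpy()
        return int(self.nodes["node_id"].to_numpy()[parents == -1][0])

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int((self.nodes["parent_id"].to_numpy() != -1).sum())

    def coords(self) -> np.ndarray:
        """Node coordinates as an (n, 3) float array in µm."""
        return self.nodes[["x", "y", "z"]].to_numpy(dtype=float)


def read_swc(path: str | Path, neuron_id: str | None = None) -> Skeleton:
    """Read one SWC file.

    Header comment lines (``#``) are permitted.  Parent references may point
    to node ids defined later in the file; validation happens after the full
    read, as the format allows.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 7:
                raise FormatError(f"{path}:{lineno}: expected 7 SWC fields, got {len(fields)}")
            try:
                rows.append(
                    (
                        int(fields[0]),
                        int(fields[1]),
                        float(fields[2]),
                        float(fields[3]),
                        float(fields[4]),
                        float(fields[5]),
                        int(fields[6]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparsable SWC fields: {exc}") from exc
    nodes = pd.DataFrame(rows, columns=SWC_COLUMNS)
    return Skeleton(neuron_id=neuron_id or path.stem, nodes=nodes)


def write_swc(skeleton: Skeleton, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# neuron_id {skeleton.neuron_id}\n")
        fh.write("# units micrometres\n")
        fh.write("# node_id structure x y z radius parent_id\n")
        for row in skeleton.nodes.itertuples(index=False):
            fh.write(
                f"{int(row.node_id)} {int(row.structure)} "
                f"{row.x:.6f} {row.y:.6f} {row.z:.6f} {row.radius:.6f} {int(row.parent_id)}\n"
            )


def read_skeletons(path: str | Path) -> dict[str, Skeleton]:
    """Read every ``*.swc`` file in a directory; the stem is the neuron id."""
    path = Path(path)
    if not path.is_dir():
        raise FormatError(f"{path}: not a directory of SWC files")
    out: dict[str, Skeleton] = {}
    for swc in sorted(path.glob("*.swc")):
        out[swc.stem] = read_swc(swc)
    return out


def write_skeletons(skeletons: Mapping[str, Skeleton], path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for neuron_id, skel in skeletons.items():
        write_swc(skel, path / f"{neuron_id}.swc")


# ---------------------------------------------------------------------------
# Tabular formats
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, columns: list[str], str_columns: Iterable[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={c: str for c in str_columns})
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed TSV
        raise FormatError(f"{path}: cannot parse TSV: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def _line(idx: int) -> int:
    # Data row `idx` sits on file line idx + 2 (1-based, after the header).
    return int(idx) + 2


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Neuron annotation table; soma coordinates in µm."""
    df = _read_tsv(
        path, ANNOTATION_COLUMNS, ["neuron_id", "cell_type", "super_class", "hemilineage", "hemisphere"]
    )
    dup = df.index[df["neuron_id"].duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate neuron_id at line {_line(dup[0])}")
    xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
    bad = np.where(~np.isfinite(xyz).all(axis=1))[0]
    if len(bad):
        raise FormatError(f"{path}: non-finite soma coordinate at line {_line(bad[0])}")
    bad_hemi = df.index[~df["hemisphere"].isin(HEMISPHERES)]
    if len(bad_hemi):
        raise FormatError(
            f"{path}: hemisphere must be one of {HEMISPHERES}, line {_line(bad_hemi[0])}"
        )
    return df[ANNOTATION_COLUMNS].copy()


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_synapse_table(path: str | Path) -> pd.DataFrame:
    """Directed pre→post synapse counts.

    Duplicate (pre_id, post_id) rows are summed; counts must be positive
    integers.
    """
    df = _read_tsv(path, SYNAPSE_COLUMNS, ["pre_id", "post_id"])
    if len(df) == 0:
        return pd.DataFrame(columns=SYNAPSE_COLUMNS).astype({"n_synapses": int})
    counts = pd.to_numeric(df["n_synapses"], errors="coerce")
    bad = df.index[counts.isna() | (counts != counts.round())]
    if len(bad):
        raise FormatError(f"{path}: non-integer synapse count at line {_line(bad[0])}")
    bad = df.index[counts <= 0]
    if len(bad):
        raise FormatError(f"{path}: non-positive synapse count at line {_line(bad[0])}")
    df = df.assign(n_synapses=counts.astype(int))
    df = (
        df.groupby(["pre_id", "post_id"], as_index=False, sort=True)["n_synapses"]
        .sum()
    )
    return df[SYNAPSE_COLUMNS]


def write_synapse_table(df: pd.DataFrame, path: str | Path) -> None:
    df[SYNAPSE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_expression_long(path: str | Path) -> pd.DataFrame:
    """Cluster × gene expression summaries, one row per (cluster, gene, method)."""
    df = _read_tsv(path, EXPRESSION_COLUMNS, ["cluster", "gene", "method"])
    dup = df.index[df.duplicated(subset=["cluster", "gene", "method"])]
    if len(dup):
        raise FormatError(f"{path}: duplicate (cluster, gene, method) at line {_line(dup[0])}")
    frac = pd.to_numeric(df["fraction_expressing"], errors="coerce")
    bad = df.index[frac.isna() | (frac < 0) | (frac > 1)]
    if len(bad):
        raise FormatError(f"{path}: fraction_expressing outside [0, 1] at line {_line(bad[0])}")
    mean = pd.to_numeric(df["mean_scaled"], errors="coerce")
    bad = df.index[mean.isna()]
    if len(bad):
        raise FormatError(f"{path}: unparsable mean_scaled at line {_line(bad[0])}")
    return df.assign(mean_scaled=mean.astype(float), fraction_expressing=frac.astype(float))[
        EXPRESSION_COLUMNS
    ]


def write_expression_long(df: pd.DataFrame, path: str | Path) -> None:
    df[EXPRESSION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_lr_catalog(path: str | Path) -> pd.DataFrame:
    """Ligand–receptor catalog with half-maximal activation (EC50) in nM."""
    df = _read_tsv(path, CATALOG_COLUMNS, ["peptide", "receptor"])
    dup = df.index[df.duplicated(subset=["peptide", "receptor"])]
    if len(dup):
        raise FormatError(f"{path}: duplicate (peptide, receptor) pair at line {_line(dup[0])}")
    ec50 = pd.to_numeric(df["ec50_nm"], errors="coerce")
    bad = df.index[ec50.isna() | (ec50 <= 0)]
    if len(bad):
        raise FormatError(f"{path}: EC50 must be a positive number, line {_line(bad[0])}")
    return df.assign(ec50_nm=ec50.astype(float))[CATALOG_COLUMNS]


def write_lr_catalog(df: pd.DataFrame, path: str | Path) -> None:
    df[CATALOG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_roster_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, ROSTER_COLUMNS, ROSTER_COLUMNS)
    dup = df.index[df["neuron_id"].duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate neuron_id at line {_line(dup[0])}")
    return df[ROSTER_COLUMNS].copy()


def write_roster_table(df: pd.DataFrame, path: str | Path) -> None:
    df[ROSTER_COLUMNS].to_csv(path, sep="\t", index=False)


def read_mapping_table(path: str | Path, key: str, value: str) -> dict[str, str]:
    """Two-column TSV → dict (e.g. morphology clusters, cluster-name maps)."""
    df = _read_tsv(path, [key, value], [key, value])
    dup = df.index[df[key].duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate {key} at line {_line(dup[0])}")
    return dict(zip(df[key], df[value]))


def write_mapping_table(mapping: Mapping[str, str], key: str, value: str, path: str | Path) -> None:
    pd.DataFrame({key: list(mapping.keys()), value: list(mapping.values())}).to_csv(
        path, sep="\t", index=False
    )
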