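"""Residue contact graphs and connectivity of mutationally sensitive sets.

A contact graph has one node per residue and an edge wherever the minimum
heavy-atom inter-residue distance is within a cutoff (default 4.5 A, a
standard van-der-Waals contact proxy). Given a set of sensitive residues,
the induced subgraph's connected components describe whether the set is
contiguous in the structure, and its articulation vertices are the
"bridge" residues whose removal disconnects a cluster — the graph-theoretic
form of asking which single residue holds the sensitive network together.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "ResidueSet",
    "ContactGraph",
    "read_residue_atoms",
    "build_contact_graph",
    "induced_components",
    "bridge_residues",
    "threshold_scan",
    "expand_positions",
]

ResidueKey = tuple[str, int]


@dataclass(frozen=True)
class ResidueSet:
    """A set of residues with the threshold and source that produced it."""

    members: frozenset[ResidueKey]
    theta: float | None = None
    source: str = ""

    def __iter__(self):
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ContactGraph:
    """Undirected residue contact graph with its construction parameters."""

    graph: nx.Graph
    cutoff: float
    scheme: str

    @property
    def nodes(self) -> set[ResidueKey]:
        return set(self.graph.nodes)

    def missing_members(self, members: Iterable[ResidueKey]) -> set[ResidueKey]:
        """Requested residues absent from the graph or flagged as coordinate-less."""
        out = set()
        for m in members:
            if m not in self.graph:
                out.add(m)
            elif self.graph.nodes[m].get("isolated_by_missing_data"):
                out.add(m)
        return out

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [
            {"chain_i": a[0], "residue_i": a[1], "chain_j": b[0], "residue_j": b[1]}
            for a, b in sorted(self.graph.edges)
        ]
        return pd.DataFrame(rows, columns=["chain_i", "residue_i", "chain_j", "residue_j"])

    def to_edge_tsv(self, path) -> None:
        self.to_edge_frame().to_csv(path, sep="\t", index=False)

    def to_adjlist(self, path) -> None:
        nx.write_adjlist(self.graph, path, delimiter="|")


def read_residue_atoms(
    path,
    chains: Sequence[str] | None = None,
    heavy_only: bool = True,
) -> dict[ResidueKey, dict]:
    """Residue -> atom coordinates from a PDB or mmCIF file.

    Residues keep the author chain id and author residue number verbatim;
    waters are skipped, hydrogens optionally. Each value carries
    ``resname``, ``coords`` (n_atoms x 3) and ``atom_names``.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    out: dict[ResidueKey, dict] = {}
    for chain in model:
        if chains is not None and chain.name not in chains:
            continue
        for res in chain:
            if res.is_water():
                continue
            coords, names = [], []
            for atom in res:
                if heavy_only and atom.element.is_hydrogen:
                    continue
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                names.append(atom.name)
            if not coords:
                continue
            key = (chain.name, res.seqid.num)
            out[key] = {
                "resname": res.name,
                "coords": np.asarray(coords, dtype=float),
                "atom_names": names,
            }
    return out


def _as_atom_dict(residue_atoms: Mapping) -> dict[ResidueKey, dict]:
    out = {}
    for key, val in residue_atoms.items():
        if isinstance(val, Mapping):
            out[key] = {
                "coords": np.asarray(val["coords"], dtype=float),
                "atom_names": list(val.get("atom_names", [])),
            }
        else:
            out[key] = {"coords": np.atleast_2d(np.asarray(val, dtype=float)), "atom_names": []}
    return out


def build_contact_graph(
    residue_atoms: Mapping[ResidueKey, object],
    cutoff: float = 4.5,
    scheme: str = "heavy",
    roster: Iterable[ResidueKey] | None = None,
) -> ContactGraph:
    """Contact graph with an edge wherever two residues are within ``cutoff``.

    ``residue_atoms`` maps (chain, residue number) to atom coordinates
    (an (n, 3) array or the dict produced by :func:`read_residue_atoms`).
    Scheme "heavy" uses the minimum inter-atom distance; "representative"
    uses one point per residue (the CA atom when atom names are available,
    otherwise the centroid). Residues named in ``roster`` but absent from
    the coordinates are kept as nodes flagged isolated-by-missing-data.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    atoms = _as_atom_dict(residue_atoms)
    g = nx.Graph()
    keys = sorted(atoms)
    g.add_nodes_from(keys)
    if scheme == "heavy":
        all_coords = []
        owner = []
        for i, key in enumerate(keys):
            c = atoms[key]["coords"]
            all_coords.append(c)
            owner.extend([i] * len(c))
        stacked = np.vstack(all_coords)
        owner = np.asarray(owner)
        tree = cKDTree(stacked)
        for a, b in tree.query_pairs(cutoff):
            ia, ib = owner[a], owner[b]
            if ia != ib:
                g.add_edge(keys[ia], keys[ib])
    elif scheme == "representative":
        points = []
        for key in keys:
            names = atoms[key]["atom_names"]
            coords = atoms[key]["coords"]
            if "CA" in names:
                points.append(coords[names.index("CA")])
            else:
                points.append(coords.mean(axis=0))
        tree = cKDTree(np.asarray(points))
        for a, b in tree.query_pairs(cutoff):
            g.add_edge(keys[a], keys[b])
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if roster is not None:
        for key in roster:
            if key not in g:
                g.add_node(key, isolated_by_missing_data=True)
    return ContactGraph(graph=g, cutoff=cutoff, scheme=scheme)


def induced_components(
    cg: ContactGraph, members: Iterable[ResidueKey]
) -> list[set[ResidueKey]]:
    """Connected components of the subgraph induced by ``members``.

    Members without coordinates appear as singleton components; members
    absent from the graph entirely are ignored (see
    :meth:`ContactGraph.missing_members`).
    """
    present = [m for m in members if m in cg.graph]
    sub = cg.graph.subgraph(present)
    return [set(c) for c in nx.connected_components(sub)]


def bridge_residues(
    cg: ContactGraph, members: Iterable[ResidueKey]
) -> set[ResidueKey]:
    """Residues whose removal increases the induced subgraph's component count.

    These are the articulation vertices, computed per connected component:
    a residue that alone connects two clusters of the sensitive set.
    """
    present = [m for m in members if m in cg.graph]
    sub = cg.graph.subgraph(present)
    return set(nx.articulation_points(sub))


def expand_positions(
    positions: Iterable[int], chains: Sequence[str]
) -> frozenset[ResidueKey]:
    """Map protein positions to the same residue number in each chain.

    The ATPase subunit occupies several equivalent chains of the complex,
    so one profile position names one residue per subunit chain.
    """
    return frozenset((chain, pos) for pos in positions for chain in chains)


def threshold_scan(
    mean_effects: pd.Series,
    cg: ContactGraph,
    thetas: Sequence[float],
    chains: Sequence[str] = ("A",),
) -> pd.DataFrame:
    """Trace set size, component count and bridges as the threshold relaxes.

    The sensitive set at each theta is every position with mean effect
    <= theta, expanded over ``chains``. The grid is scanned from the most
    stringent (most negative) theta upward, so the set grows monotonically
    down the trace as the definition of "sensitive" is broadened.
    """
    thetas = sorted(thetas)
    rows = []
    for theta in thetas:
        positions = [int(p) for p, v in mean_effects.items() if np.isfinite(v) and v <= theta]
        members = expand_positions(positions, chains)
        comps = induced_components(cg, members)
        bridges = bridge_residues(cg, members)
        rows.append(
            {
                "theta": theta,
                "n_residues": len(members),
                "n_components": len(comps),
                "bridges": tuple(sorted(bridges)),
                "n_bridges": len(bridges),
            }
        )
    return pd.DataFrame(rows, columns=["theta", "n_residues", "n_components", "bridges", "n_bridges"])
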