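"""Construction and serialization of activity-stratified proximity networks.

For every (activity, period) combination the herd forms one simple
undirected binary network over the *full* roster vertex set, in fixed
roster order: an edge (i, j) exists iff the two animals were recorded in
proximity in that period while both performing that activity.  Animals
performing another activity (or none recorded) appear as isolated
vertices, and combinations in which the activity did not occur yield an
empty network; both are first-class members of the ensemble, so a
complete campaign with 7 activities and P periods always gives exactly
7 x P networks over N vertices each (the default design: 1680 networks,
152,880 vertex-cases).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence
from xml.etree import ElementTree as ET

import numpy as np

from .records import ACTIVITIES, Animal, ObservationRecord, ValidationError


@dataclass(frozen=True)
class ProximityNetwork:
    """Binary undirected proximity network for one (activity, period).

    ``adjacency`` is an N x N symmetric 0/1 matrix with zero diagonal over
    the full-herd ``vertex_ids`` (roster order, identical across the
    ensemble).
    """

    activity: str
    period_id: int
    vertex_ids: tuple[str, ...]
    adjacency: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        a = self.adjacency
        n = len(self.vertex_ids)
        if a.shape != (n, n):
            raise ValidationError(
                f"adjacency shape {a.shape} does not match {n} vertices"
            )
        if not np.array_equal(a, a.T):
            raise ValidationError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValidationError("adjacency diagonal must be zero (no self-proximity)")
        if not np.isin(a, (0, 1)).all():
            raise ValidationError("adjacency must be binary")

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def network_id(self) -> str:
        return f"{self.activity}_p{self.period_id:03d}"

    def edges(self) -> list[tuple[str, str]]:
        """Edge list as (id, id) pairs with i < j in roster order."""
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return [(self.vertex_ids[i], self.vertex_ids[j]) for i, j in zip(ii, jj)]


@dataclass(frozen=True)
class NetworkEnsemble:
    """All 7 x P networks of one campaign, activity-major then period order."""

    networks: tuple[ProximityNetwork, ...]
    n_periods: int
    vertex_ids: tuple[str, ...]

    @property
    def n_activities(self) -> int:
        return len(ACTIVITIES)

    def __len__(self) -> int:
        return len(self.networks)

    def __iter__(self) -> Iterator[ProximityNetwork]:
        return iter(self.networks)

    def get(self, activity: str, period_id: int) -> ProximityNetwork:
        idx = ACTIVITIES.index(activity) * self.n_periods + (period_id - 1)
        return self.networks[idx]


def build_ensemble(
    records: Sequence[ObservationRecord], roster: Sequence[Animal]
) -> NetworkEnsemble:
    """Build the complete ensemble of binary proximity networks.

    One network per (activity, period) over the fixed roster vertex set;
    periods are 1..max(period_id) so the ensemble is complete even when an
    activity never occurs (empty networks are kept).
    """
    ids = tuple(a.animal_id for a in roster)
    index = {a: i for i, a in enumerate(ids)}
    if len(index) != len(ids):
        raise ValidationError("roster ids are not unique")
    n = len(ids)
    n_periods = max((r.period_id for r in records), default=0)
    mats: dict[tuple[str, int], np.ndarray] = {}
    for rec in records:
        if rec.animal_id not in index:
            raise ValidationError(
                f"record animal {rec.animal_id!r} is not on the roster"
            )
        if not rec.partners:
            continue
        key = (rec.activity, rec.period_id)
        mat = mats.get(key)
        if mat is None:
            mat = mats[key] = np.zeros((n, n), dtype=np.int8)
        i = index[rec.animal_id]
        for partner in rec.partners:
            j = index[partner]
            mat[i, j] = mat[j, i] = 1
    empty = np.zeros((n, n), dtype=np.int8)
    networks = tuple(
        ProximityNetwork(
            activity=act,
            period_id=p,
            vertex_ids=ids,
            adjacency=mats.get((act, p), empty),
        )
        for act in ACTIVITIES
        for p in range(1, n_periods + 1)
    )
    return NetworkEnsemble(networks=networks, n_periods=n_periods, vertex_ids=ids)


# ---------------------------------------------------------------------------
# Serialization: GraphML and edge-list CSV (isolates preserved in both)

_FORMATS = ("graphml", "csv")
_NAME_RE = re.compile(r"(?P<activity>[a-z]+)_p(?P<period>\d+)")


def write_network(network: ProximityNetwork, path: str | Path, format: str = "graphml") -> None:
    """Serialize one network with all N vertices declared.

    GraphML stores activity and period as graph attributes.  The CSV
    format writes the edge list plus a ``.vertices.csv`` sidecar listing
    every vertex (edge lists alone lose isolates); activity and period are
    encoded in the conventional ``<activity>_p<period>`` file stem.
    """
    path = Path(path)
    if format == "graphml":
        _write_graphml(network, path)
    elif format == "csv":
        _write_csv(network, path)
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")


def read_network(path: str | Path, format: str = "graphml") -> ProximityNetwork:
    path = Path(path)
    if format == "graphml":
        return _read_graphml(path)
    if format == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")


_GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"


def _write_graphml(network: ProximityNetwork, path: Path) -> None:
    ET.register_namespace("", _GRAPHML_NS)
    root = ET.Element(f"{{{_GRAPHML_NS}}}graphml")
    for key_id, attr in (("activity", "activity"), ("period_id", "period_id")):
        key = ET.SubElement(root, f"{{{_GRAPHML_NS}}}key")
        key.set("id", key_id)
        key.set("for", "graph")
        key.set("attr.name", attr)
        key.set("attr.type", "string" if key_id == "activity" else "int")
    graph = ET.SubElement(root, f"{{{_GRAPHML_NS}}}graph")
    graph.set("id", network.network_id)
    graph.set("edgedefault", "undirected")
    for key_id, value in (("activity", network.activity), ("period_id", network.period_id)):
        data = ET.SubElement(graph, f"{{{_GRAPHML_NS}}}data")
        data.set("key", key_id)
        data.text = str(value)
    for vid in network.vertex_ids:
        node = ET.SubElement(graph, f"{{{_GRAPHML_NS}}}node")
        node.set("id", vid)
    for a, b in network.edges():
        edge = ET.SubElement(graph, f"{{{_GRAPHML_NS}}}edge")
        edge.set("source", a)
        edge.set("target", b)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def _read_graphml(path: Path) -> ProximityNetwork:
    root = ET.parse(path).getroot()
    graph = root.find(f"{{{_GRAPHML_NS}}}graph")
    if graph is None:
        raise ValidationError(f"{path}: no <graph> element")
    meta = {d.get("key"): (d.text or "") for d in graph.findall(f"{{{_GRAPHML_NS}}}data")}
    vertex_ids = tuple(
        node.get("id") for node in graph.findall(f"{{{_GRAPHML_NS}}}node")
    )
    index = {v: i for i, v in enumerate(vertex_ids)}
    adj = np.zeros((len(vertex_ids), len(vertex_ids)), dtype=np.int8)
    for edge in graph.findall(f"{{{_GRAPHML_NS}}}edge"):
        i, j = index[edge.get("source")], index[edge.get("target")]
        adj[i, j] = adj[j, i] = 1
    return ProximityNetwork(
        activity=meta["activity"],
        period_id=int(meta["period_id"]),
        vertex_ids=vertex_ids,
        adjacency=adj,
    )


def _write_csv(network: ProximityNetwork, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target"])
        writer.writerows(network.edges())
    sidecar = path.with_suffix(".vertices.csv")
    with open(sidecar, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["animal_id"])
        writer.writerows([v] for v in network.vertex_ids)


def _read_csv(path: Path) -> ProximityNetwork:
    match = _NAME_RE.search(Path(path).stem)
    if match is None:
        raise ValidationError(
            f"{path}: file stem must encode '<activity>_p<period>' for csv format"
        )
    sidecar = Path(path).with_suffix(".vertices.csv")
    with open(sidecar, newline="") as fh:
        vertex_ids = tuple(row[0] for row in list(csv.reader(fh))[1:])
    index = {v: i for i, v in enumerate(vertex_ids)}
    adj = np.zeros((len(vertex_ids), len(vertex_ids)), dtype=np.int8)
    with open(path, newline="") as fh:
        for a, b in list(csv.reader(fh))[1:]:
            i, j = index[a], index[b]
            adj[i, j] = adj[j, i] = 1
    return ProximityNetwork(
        activity=match.group("activity"),
        period_id=int(match.group("period")),
        vertex_ids=vertex_ids,
        adjacency=adj,
    )


def write_ensemble(
    ensemble: NetworkEnsemble, directory: str | Path, format: str = "graphml"
) -> list[Path]:
    """Write every network as ``<activity>_p<period>.<ext>`` in a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = "graphml" if format == "graphml" else "csv"
    paths = []
    for net in ensemble:
        p = directory / f"{net.network_id}.{ext}"
        write_network(net, p, format=format)
        paths.append(p)
    return paths
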