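"""Domain types and I/O for signed protein networks, disease
characterisations and drug target profiles.

The central object is :class:`ProteinNetwork`: a signed, directed
protein–protein interaction graph.  Proteins are keyed by their UniProtKB
accession; gene symbols are carried for display only.  Interaction files
use a SIF-like tab-separated layout (``source TAB type TAB target``) whose
type tokens are mapped to signs through an editable *dialect* table, so the
same reader serves curated resources with different sign vocabularies.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, TextIO, Union

import networkx as nx

from .errors import (
    ConflictingActionError,
    DisjointCharacterisationError,
    EmptyNetworkError,
    EmptyProfileError,
    UnknownInteractionTypeError,
)

__all__ = [
    "ProteinRef",
    "InteractionEdge",
    "ProteinNetwork",
    "EffectorState",
    "Motive",
    "DiseaseCharacterisation",
    "DrugTargetProfile",
    "DialectEntry",
    "DEFAULT_DIALECT",
    "read_network",
    "write_network",
    "read_drug_profile",
    "write_drug_profile",
    "combine_profiles",
    "build_disease_interactome",
    "InteractomeResult",
    "read_characterisation",
    "read_characterisation_tsv",
    "write_characterisation",
    "summarize_characterisation",
    "CharacterisationSummary",
]


@dataclass(frozen=True)
class ProteinRef:
    """A protein identified by a UniProtKB-style accession.

    Equality and hashing use the accession alone; the gene symbol is a
    display annotation and never participates in identity.
    """

    accession: str
    symbol: str | None = None

    def __post_init__(self):
        if not self.accession:
            raise ValueError("ProteinRef accession must be non-empty")

    def __eq__(self, other):
        if isinstance(other, ProteinRef):
            return self.accession == other.accession
        return NotImplemented

    def __hash__(self):
        return hash(self.accession)

    def __repr__(self):
        if self.symbol:
            return f"ProteinRef({self.accession!r}, {self.symbol!r})"
        return f"ProteinRef({self.accession!r})"


@dataclass(frozen=True)
class InteractionEdge:
    """A signed, directed interaction: ``source`` acts on ``target``."""

    source: ProteinRef
    target: ProteinRef
    sign: int
    provenance: str = ""

    def __post_init__(self):
        if self.sign not in (+1, -1):
            raise ValueError(f"edge sign must be +1 or -1, got {self.sign}")

    @property
    def triple(self) -> tuple[str, str, int]:
        return (self.source.accession, self.target.accession, self.sign)


class ProteinNetwork:
    """A signed, directed protein interaction graph.

    Nodes are stored in insertion order; that order is the canonical node
    order used by every numeric routine downstream, so a network built
    twice from the same rows yields bit-identical computations.
    Duplicate ``(source, target, sign)`` triples are collapsed on
    construction.  Self-loops are permitted and propagate like any edge.
    """

    def __init__(
        self,
        nodes: Iterable[ProteinRef] = (),
        edges: Iterable[InteractionEdge] = (),
    ):
        self._nodes: dict[str, ProteinRef] = {}
        self._edges: list[InteractionEdge] = []
        self._edge_keys: set[tuple[str, str, int]] = set()
        for ref in nodes:
            self.add_node(ref)
        for edge in edges:
            self.add_edge(edge)

    # -- construction ------------------------------------------------------

    def add_node(self, ref: ProteinRef) -> None:
        existing = self._nodes.get(ref.accession)
        if existing is None:
            self._nodes[ref.accession] = ref
        elif existing.symbol is None and ref.symbol is not None:
            self._nodes[ref.accession] = ref

    def add_edge(self, edge: InteractionEdge) -> None:
        key = edge.triple
        if key in self._edge_keys:
            return
        self._edge_keys.add(key)
        self.add_node(edge.source)
        self.add_node(edge.target)
        self._edges.append(edge)

    # -- views -------------------------------------------------------------

    @property
    def nodes(self) -> list[ProteinRef]:
        return list(self._nodes.values())

    @property
    def node_order(self) -> list[str]:
        """Accessions in canonical (insertion) order."""
        return list(self._nodes)

    @property
    def edges(self) -> list[InteractionEdge]:
        return list(self._edges)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def __contains__(self, protein: Union[str, ProteinRef]) -> bool:
        acc = protein.accession if isinstance(protein, ProteinRef) else protein
        return acc in self._nodes

    def node_index(self) -> dict[str, int]:
        return {acc: i for i, acc in enumerate(self._nodes)}

    def to_directed_graph(self) -> nx.MultiDiGraph:
        """networkx view with a ``sign`` attribute per edge."""
        g = nx.MultiDiGraph()
        g.add_nodes_from(self._nodes)
        for e in self._edges:
            g.add_edge(
                e.source.accession,
                e.target.accession,
                sign=e.sign,
                provenance=e.provenance,
            )
        return g

    def to_undirected_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from(
            (e.source.accession, e.target.accession) for e in self._edges
        )
        return g

    def induced_subnetwork(self, accessions: Iterable[str]) -> "ProteinNetwork":
        keep = set(accessions)
        nodes = [r for a, r in self._nodes.items() if a in keep]
        edges = [
            e
            for e in self._edges
            if e.source.accession in keep and e.target.accession in keep
        ]
        return ProteinNetwork(nodes=nodes, edges=edges)

    def __repr__(self):
        return f"<ProteinNetwork {self.n_nodes} nodes, {self.n_edges} edges>"


@dataclass(frozen=True)
class EffectorState:
    """An effector protein with its disease activation sign.

    ``disease_sign`` is +1 when the protein is active/up in the disease
    state and -1 when inactive/down.
    """

    protein: ProteinRef
    disease_sign: int

    def __post_init__(self):
        if self.disease_sign not in (+1, -1):
            raise ValueError(
                f"disease_sign must be +1 or -1, got {self.disease_sign}"
            )


@dataclass(frozen=True)
class Motive:
    """A named pathophysiological hallmark process with its effectors."""

    name: str
    effectors: tuple[EffectorState, ...]

    def __init__(self, name: str, effectors: Iterable[EffectorState]):
        effectors = tuple(effectors)
        if not effectors:
            raise ValueError(f"motive {name!r} has no effectors")
        seen = set()
        for st in effectors:
            if st.protein.accession in seen:
                raise ValueError(
                    f"duplicate effector {st.protein.accession} in motive "
                    f"{name!r}"
                )
            seen.add(st.protein.accession)
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "effectors", effectors)

    @property
    def accessions(self) -> set[str]:
        return {st.protein.accession for st in self.effectors}

    def __len__(self):
        return len(self.effectors)


@dataclass(frozen=True)
class DiseaseCharacterisation:
    """A disease described as named motives, each a set of signed effectors."""

    name: str
    motives: tuple[Motive, ...]

    def __init__(self, name: str, motives: Iterable[Motive]):
        motives = tuple(motives)
        names = [m.name for m in motives]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate motive names in {name!r}")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "motives", motives)

    def motive(self, name: str) -> Motive:
        for m in self.motives:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def motive_names(self) -> list[str]:
        return [m.name for m in self.motives]

    def all_accessions(self) -> set[str]:
        out: set[str] = set()
        for m in self.motives:
            out |= m.accessions
        return out


@dataclass(frozen=True)
class DrugTargetProfile:
    """A drug plus its (protein, action) targets.

    ``action`` is +1 for activation and -1 for inhibition of the target.
    """

    drug_name: str
    targets: tuple[tuple[ProteinRef, int], ...]

    def __init__(
        self, drug_name: str, targets: Iterable[tuple[ProteinRef, int]]
    ):
        collapsed: dict[str, tuple[ProteinRef, int]] = {}
        for protein, action in targets:
            if action not in (+1, -1):
                raise ValueError(f"target action must be +1/-1, got {action}")
            prev = collapsed.get(protein.accession)
            if prev is not None and prev[1] != action:
                raise ConflictingActionError(
                    f"{drug_name}: protein {protein.accession} listed with "
                    f"conflicting actions"
                )
            collapsed[protein.accession] = (protein, action)
        if not collapsed:
            raise EmptyProfileError(f"{drug_name}: profile has no targets")
        object.__setattr__(self, "drug_name", drug_name)
        object.__setattr__(self, "targets", tuple(collapsed.values()))

    @property
    def accessions(self) -> set[str]:
        return {p.accession for p, _ in self.targets}

    def action_of(self, accession: str) -> int:
        for p, a in self.targets:
            if p.accession == accession:
                return a
        raise KeyError(accession)

    def __len__(self):
        return len(self.targets)


# ---------------------------------------------------------------------------
# Interaction dialect
# ---------------------------------------------------------------------------

class DialectEntry(NamedTuple):
    """How one interaction-type token is interpreted.

    ``directed=False`` records are expanded into two directed edges of the
    same sign (one per direction).
    """

    sign: int
    directed: bool = True


#: Default SIF sign vocabulary.  SIF has no standard; this table is the
#: declared default and callers may pass their own.
DEFAULT_DIALECT: dict[str, DialectEntry] = {
    "activates": DialectEntry(+1),
    "stimulates": DialectEntry(+1),
    "activation": DialectEntry(+1),
    "inhibits": DialectEntry(-1),
    "represses": DialectEntry(-1),
    "inhibition": DialectEntry(-1),
}


def load_dialect(path: Union[str, Path]) -> dict[str, DialectEntry]:
    """Load a dialect table from JSON: ``{token: {"sign": ±1, "directed": bool}}``."""
    raw = json.loads(Path(path).read_text())
    out = {}
    for token, entry in raw.items():
        out[token] = DialectEntry(
            sign=int(entry["sign"]), directed=bool(entry.get("directed", True))
        )
    return out


# ---------------------------------------------------------------------------
# Network I/O
# ---------------------------------------------------------------------------

def _open_rows(source: Union[str, Path, TextIO]) -> Iterable[str]:
    if isinstance(source, (str, Path)):
        return Path(source).read_text(encoding="utf-8").splitlines()
    return source.read().splitlines()


def read_network(
    source: Union[str, Path, TextIO],
    dialect: Mapping[str, DialectEntry] | None = None,
    provenance: str = "",
) -> ProteinNetwork:
    """Read a SIF-like tab-separated interaction stream.

    Rows need at least three columns: ``source  type  target``.  Blank
    lines and ``#`` comment lines are skipped.  Duplicate
    ``(source, target, sign)`` triples collapse to one edge.
    """
    dialect = DEFAULT_DIALECT if dialect is None else dialect
    edges: list[InteractionEdge] = []
    lone_nodes: list[ProteinRef] = []
    for row_no, raw in enumerate(_open_rows(source), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            parts = line.split()
        if len(parts) == 1:
            # SIF node-only row: an unconnected protein
            lone_nodes.append(ProteinRef(parts[0]))
            continue
        if len(parts) < 3:
            raise UnknownInteractionTypeError("<malformed row>", row_no)
        src, token, dst = parts[0], parts[1], parts[2]
        entry = dialect.get(token)
        if entry is None:
            raise UnknownInteractionTypeError(token, row_no)
        s, t = ProteinRef(src), ProteinRef(dst)
        edges.append(InteractionEdge(s, t, entry.sign, provenance))
        if not entry.directed:
            edges.append(InteractionEdge(t, s, entry.sign, provenance))
    if not edges and not lone_nodes:
        raise EmptyNetworkError("interaction stream contained no rows")
    return ProteinNetwork(nodes=lone_nodes, edges=edges)


_SIGN_TOKEN = {+1: "activates", -1: "inhibits"}


def write_network(network: ProteinNetwork, path: Union[str, Path]) -> None:
    """Write a network as tab-separated SIF (default dialect tokens).

    Unconnected proteins are written as node-only rows so the read/write
    round trip preserves the node set exactly.
    """
    connected: set[str] = set()
    lines = []
    for e in network.edges:
        lines.append(
            f"{e.source.accession}\t{_SIGN_TOKEN[e.sign]}\t{e.target.accession}"
        )
        connected.add(e.source.accession)
        connected.add(e.target.accession)
    lines += [a for a in network.node_order if a not in connected]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_graphml(
    network: ProteinNetwork,
    path: Union[str, Path],
    node_attributes: Mapping[str, Mapping[str, float]] | None = None,
) -> None:
    """Export to GraphML, optionally with per-node numeric attributes
    (e.g. ``{"activity": {accession: value}}``)."""
    g = network.to_directed_graph()
    if node_attributes:
        for attr, values in node_attributes.items():
            nx.set_node_attributes(
                g, {n: float(v) for n, v in values.items()}, attr
            )
    nx.write_graphml(g, str(path))


# ---------------------------------------------------------------------------
# Drug profile I/O
# ---------------------------------------------------------------------------

def read_drug_profile(source: Union[str, Path, TextIO, Mapping]) -> DrugTargetProfile:
    """Read a drug target profile from a JSON document.

    Layout::

        {"drug_name": "...",
         "targets": [{"accession": "...", "symbol": "...", "action": -1}, ...]}

    Duplicate proteins with identical action collapse; conflicting actions
    raise :class:`ConflictingActionError`.
    """
    if isinstance(source, Mapping):
        doc = source
    elif isinstance(source, (str, Path)):
        doc = json.loads(Path(source).read_text(encoding="utf-8"))
    else:
        doc = json.load(source)
    targets = [
        (ProteinRef(t["accession"], t.get("symbol")), int(t["action"]))
        for t in doc.get("targets", [])
    ]
    return DrugTargetProfile(doc.get("drug_name", "unnamed"), targets)


def write_drug_profile(profile: DrugTargetProfile, path: Union[str, Path]) -> None:
    doc = {
        "drug_name": profile.drug_name,
        "targets": [
            {"accession": p.accession, "symbol": p.symbol, "action": a}
            for p, a in profile.targets
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def combine_profiles(
    a: DrugTargetProfile, b: DrugTargetProfile
) -> DrugTargetProfile:
    """Union of two profiles, named ``a+b``.

    A protein present in both with opposite action raises
    :class:`ConflictingActionError` (the constructor enforces it).
    """
    return DrugTargetProfile(
        f"{a.drug_name}+{b.drug_name}", list(a.targets) + list(b.targets)
    )


# ---------------------------------------------------------------------------
# Disease characterisation I/O
# ---------------------------------------------------------------------------

def read_characterisation(
    source: Union[str, Path, TextIO, Mapping]
) -> DiseaseCharacterisation:
    """Read a characterisation from JSON::

        {"name": "...",
         "motives": [{"name": "...",
                      "effectors": [{"accession": "...", "symbol": "...",
                                     "disease_sign": 1}, ...]}, ...]}
    """
    if isinstance(source, Mapping):
        doc = source
    elif isinstance(source, (str, Path)):
        doc = json.loads(Path(source).read_text(encoding="utf-8"))
    else:
        doc = json.load(source)
    motives = [
        Motive(
            m["name"],
            [
                EffectorState(
                    ProteinRef(e["accession"], e.get("symbol")),
                    int(e["disease_sign"]),
                )
                for e in m["effectors"]
            ],
        )
        for m in doc["motives"]
    ]
    return DiseaseCharacterisation(doc.get("name", "unnamed"), motives)


def read_characterisation_tsv(
    source: Union[str, Path], name: str = "unnamed"
) -> DiseaseCharacterisation:
    """Read a characterisation from TSV with header
    (motive, protein_accession, sign); motives appear in first-row order."""
    rows = [
        line.split("\t")
        for line in _open_rows(source)
        if line.strip() and not line.startswith("#")
    ]
    header, body = rows[0], rows[1:]
    if [c.strip().lower() for c in header[:3]] != [
        "motive", "protein_accession", "sign"
    ]:
        raise ValueError(
            "characterisation TSV needs header: motive, protein_accession, sign"
        )
    grouped: dict[str, list[EffectorState]] = {}
    for motive, accession, sign in (r[:3] for r in body):
        grouped.setdefault(motive, []).append(
            EffectorState(ProteinRef(accession), int(sign))
        )
    return DiseaseCharacterisation(
        name, [Motive(m, states) for m, states in grouped.items()]
    )


def write_characterisation(
    disease: DiseaseCharacterisation, path: Union[str, Path]
) -> None:
    doc = {
        "name": disease.name,
        "motives": [
            {
                "name": m.name,
                "effectors": [
                    {
                        "accession": st.protein.accession,
                        "symbol": st.protein.symbol,
                        "disease_sign": st.disease_sign,
                    }
                    for st in m.effectors
                ],
            }
            for m in disease.motives
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Disease interactome
# ---------------------------------------------------------------------------

class InteractomeResult(NamedTuple):
    network: ProteinNetwork
    missing_effectors: list[str]


def build_disease_interactome(
    network: ProteinNetwork,
    disease: DiseaseCharacterisation,
    max_hops: int,
) -> InteractomeResult:
    """Induced subnetwork of all nodes within ``max_hops`` undirected hops
    of any mapped disease effector.

    Returns the subnetwork plus the effector accessions that do not map to
    the network.  Raises :class:`DisjointCharacterisationError` when no
    effector maps at all.
    """
    if max_hops < 0:
        raise ValueError("max_hops must be >= 0")
    effectors = disease.all_accessions()
    mapped = sorted(a for a in effectors if a in network)
    missing = sorted(effectors - set(mapped))
    if not mapped:
        raise DisjointCharacterisationError(
            f"no effector of {disease.name!r} maps to the network"
        )
    # multi-source BFS on the undirected view, capped at max_hops
    g = network.to_undirected_graph()
    dist = {a: 0 for a in mapped}
    queue = deque(mapped)
    while queue:
        u = queue.popleft()
        if dist[u] == max_hops:
            continue
        for v in g.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return InteractomeResult(network.induced_subnetwork(dist), missing)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

class CharacterisationSummary(NamedTuple):
    per_motive: dict[str, int]
    unique_proteins: int

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(self.per_motive.values())


def summarize_characterisation(
    disease: DiseaseCharacterisation,
) -> CharacterisationSummary:
    """Per-motive effector counts (in declared motive order) plus the
    number of unique proteins across all motives."""
    per = {m.name: len(m) for m in disease.motives}
    return CharacterisationSummary(per, len(disease.all_accessions()))
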