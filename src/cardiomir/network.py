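"""Compartmentalized multi-miRNA protein-interaction network construction.

From a scored, STRING-flavoured edge list a high-confidence network is kept
(combined score >= 700 of 1000 by default), one subnetwork per miRNA is
induced on that miRNA's differentially expressed genes plus any genes of
interest, and the subnetworks are merged into a single multi-network whose
edges carry the set of supporting miRNAs.  Nodes are then classified by
regulation role (downregulated, downregulated bioinformatic target,
upregulated by all miRNAs) and annotated with GO-style compartment labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from cardiomir.exceptions import ConfigurationError, InputError
from cardiomir.expression import DE_DOWN, DE_UP
from cardiomir.targetome import Targetome

SCORE_MIN, SCORE_MAX = 0, 1000
DEFAULT_SCORE_CUTOFF = 700

ROLE_DOWN_TARGET = "down_target"
ROLE_DOWN_ANY = "down_any"
ROLE_UP_ALL = "up_all"
ROLE_OTHER = "other"

# Built-in compartment labels with the GO ids they aggregate.  The two Hippo
# compartments are literature-curated pathway lists rather than GO terms and
# ship as user-editable GMT entries.
COMPARTMENT_GO_IDS: dict[str, tuple[str, ...]] = {
    "cell_division": ("GO:0051301", "GO:0000086"),
    "actin_cytoskeleton": ("GO:0015629", "GO:0030036", "GO:0031532", "GO:0008154"),
    "oxidative_stress": ("GO:0006979",),
    "hippo_canonical": (),
    "hippo_noncanonical": (),
}


@dataclass
class CompartmentCatalogue:
    """Label -> (GO ids, gene set) mapping for network compartmentalization."""

    compartments: dict[str, set] = field(default_factory=dict)
    go_ids: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, genes in self.compartments.items():
            if not genes:
                raise InputError(f"compartment {label!r} has an empty gene set")
            self.go_ids.setdefault(label, COMPARTMENT_GO_IDS.get(label, ()))

    @classmethod
    def from_gene_sets(cls, gene_sets: Mapping[str, Iterable]) -> "CompartmentCatalogue":
        return cls(compartments={k: set(v) for k, v in gene_sets.items()})

    def labels_of(self, gene) -> set[str]:
        return {label for label, genes in self.compartments.items() if gene in genes}


def read_string_edges(path) -> pd.DataFrame:
    """Read a `protein1 protein2 combined_score` whitespace/tab edge list."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"protein1", "protein2", "combined_score"}
    if not required <= set(df.columns):
        raise InputError(f"edge list needs columns {sorted(required)}")
    return df


def filter_edges(
    edges: pd.DataFrame,
    score_cutoff: int = DEFAULT_SCORE_CUTOFF,
    allowed_nodes: set | None = None,
) -> nx.Graph:
    """High-confidence undirected graph from a scored edge list.

    Edges with combined_score >= score_cutoff are kept (inclusive reading of
    the cutoff), (a,b)/(b,a) duplicates collapse to one undirected edge with
    the maximum score, and self-loops are discarded.  ``allowed_nodes``
    restricts edges to a single identifier namespace (e.g. rat proteins
    only); edges touching any foreign identifier are rejected.
    """
    if not SCORE_MIN <= score_cutoff <= SCORE_MAX:
        raise ConfigurationError(f"score_cutoff must lie in [{SCORE_MIN}, {SCORE_MAX}]")
    scores = edges["combined_score"]
    if ((scores < SCORE_MIN) | (scores > SCORE_MAX)).any():
        raise InputError("combined scores must lie in [0, 1000]")
    graph = nx.Graph()
    kept = edges[scores >= score_cutoff]
    for a, b, s in kept[["protein1", "protein2", "combined_score"]].itertuples(index=False):
        if a == b:
            continue
        if allowed_nodes is not None and (a not in allowed_nodes or b not in allowed_nodes):
            continue
        if graph.has_edge(a, b):
            graph[a][b]["combined_score"] = max(graph[a][b]["combined_score"], int(s))
        else:
            graph.add_edge(a, b, combined_score=int(s))
    return graph


def extract_subnetwork(
    graph: nx.Graph,
    de_genes: Iterable,
    genes_of_interest: Iterable = (),
) -> nx.Graph:
    """Induced subgraph on (DE genes ∪ genes of interest).

    Nodes absent from the scored network are ignored (a gene with no
    high-confidence interaction has nowhere to sit); nodes left isolated by
    the induction are retained so roles stay reportable.
    """
    wanted = set(de_genes) | set(genes_of_interest)
    return nx.Graph(graph.subgraph(n for n in wanted if n in graph))


def merge_multinet(subnetworks: Mapping[str, nx.Graph]) -> nx.Graph:
    """Merge per-miRNA subnetworks; edges carry the supporting miRNA set."""
    if not subnetworks:
        raise InputError("at least one subnetwork required")
    merged = nx.Graph()
    for mirna in sorted(subnetworks):
        sub = subnetworks[mirna]
        merged.add_nodes_from(sub.nodes)
        for a, b, data in sub.edges(data=True):
            if merged.has_edge(a, b):
                merged[a][b]["supporting_mirnas"].add(mirna)
            else:
                merged.add_edge(
                    a,
                    b,
                    supporting_mirnas={mirna},
                    combined_score=data.get("combined_score"),
                )
    return merged


def classify_nodes(
    multinet: nx.Graph,
    de_records: pd.DataFrame,
    targetomes: Mapping[str, Targetome],
) -> nx.Graph:
    """Assign regulation roles in place (and return the graph).

    down_target: downregulated by >=1 miRNA and a bioinformatic target of
    >=1 miRNA; down_any: downregulated by >=1 miRNA; up_all: upregulated by
    every configured miRNA; other: none of the above.
    """
    mirnas = sorted(targetomes)
    down_by: dict = {}
    up_by: dict = {}
    for mirna in mirnas:
        sub = de_records[de_records["mirna"] == mirna]
        if sub.empty:
            raise InputError(f"miRNA {mirna!r} absent from DE table")
        for gene in sub.loc[sub["de_status"] == DE_DOWN, "gene_id"]:
            down_by.setdefault(gene, set()).add(mirna)
        for gene in sub.loc[sub["de_status"] == DE_UP, "gene_id"]:
            up_by.setdefault(gene, set()).add(mirna)
    predicted_by = {
        mirna: targetomes[mirna].predicted_rat_genes for mirna in mirnas
    }
    for node in multinet.nodes:
        de_by = down_by.get(node, set())
        target_of = {m for m in mirnas if node in predicted_by[m]}
        if de_by and target_of:
            role = ROLE_DOWN_TARGET
        elif de_by:
            role = ROLE_DOWN_ANY
        elif up_by.get(node, set()) == set(mirnas):
            role = ROLE_UP_ALL
        else:
            role = ROLE_OTHER
        multinet.nodes[node].update(
            role=role,
            de_by=set(de_by),
            up_by=set(up_by.get(node, set())),
            target_of=target_of,
        )
    return multinet


def compartmentalize(multinet: nx.Graph, catalogue: CompartmentCatalogue) -> nx.Graph:
    """Annotate each node with the compartment labels containing it."""
    if not catalogue.compartments:
        raise InputError("compartment catalogue is empty")
    for node in multinet.nodes:
        multinet.nodes[node]["compartments"] = catalogue.labels_of(node)
    return multinet


def _stringify_sets(graph: nx.Graph) -> nx.Graph:
    """Copy with set-valued attributes serialized for GraphML export."""
    out = graph.copy()
    for _, data in out.nodes(data=True):
        for key, value in list(data.items()):
            if isinstance(value, (set, frozenset)):
                data[key] = ";".join(sorted(value))
    for _, _, data in out.edges(data=True):
        for key, value in list(data.items()):
            if isinstance(value, (set, frozenset)):
                data[key] = ";".join(sorted(value))
            elif value is None:
                del data[key]
    return out


def write_graphml(graph: nx.Graph, path, drop_isolated: bool = False) -> None:
    out = _stringify_sets(graph)
    if drop_isolated:
        out.remove_nodes_from(list(nx.isolates(out)))
    nx.write_graphml(out, path)


def node_table(graph: nx.Graph) -> pd.DataFrame:
    rows = []
    for node, data in sorted(graph.nodes(data=True)):
        rows.append(
            {
                "gene_id": node,
                "role": data.get("role", ""),
                "de_by": ";".join(sorted(data.get("de_by", ()))),
                "target_of": ";".join(sorted(data.get("target_of", ()))),
                "compartments": ";".join(sorted(data.get("compartments", ()))),
                "degree": graph.degree(node),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "role", "de_by", "target_of", "compartments", "degree"]
    )


def edge_table(graph: nx.Graph) -> pd.DataFrame:
    rows = []
    for a, b, data in graph.edges(data=True):
        a, b = sorted((a, b))
        rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "combined_score": data.get("combined_score"),
                "supporting_mirnas": ";".join(sorted(data.get("supporting_mirnas", ()))),
            }
        )
    df = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "combined_score", "supporting_mirnas"]
    )
    return df.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
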