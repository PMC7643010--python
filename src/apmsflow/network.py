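"""Trace filtering and abundance-scaled interaction-network assembly.

Evidence comes from an offline STRING detailed-links table (live database
queries are deliberately unsupported for reproducibility); only the
experimental channel is consulted, with a high-confidence default threshold
of 700. Every retained non-bait protein additionally receives one imputed
edge to the bait, mirroring the experimentally observed co-purification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from apmsflow.errors import ParseError, ValidationError

#: 2% of the bait's SI_GI == a 50-fold cutoff (1 / 0.02 = 50).
DEFAULT_TRACE_FRACTION = 0.02
DEFAULT_MIN_EVIDENCE_SCORE = 700


@dataclass(frozen=True)
class EvidenceEdge:
    protein_a: str
    protein_b: str
    experimental_score: int
    combined_score: int

    def key(self) -> frozenset[str]:
        return frozenset((self.protein_a, self.protein_b))


@dataclass
class EvidenceTable:
    edges: list[EvidenceEdge] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.edges)

    def score(self, a: str, b: str) -> int | None:
        want = frozenset((a, b))
        for e in self.edges:
            if e.key() == want:
                return e.experimental_score
        return None

    def restricted_to(self, accessions: set[str]) -> "EvidenceTable":
        return EvidenceTable(
            [e for e in self.edges if e.protein_a in accessions and e.protein_b in accessions]
        )


@dataclass
class NetworkNode:
    accession: str
    si_gi: float
    annotation_term: str
    node_size: float


@dataclass
class NetworkEdge:
    a: str
    b: str
    source: str  # "evidence" | "bait_imputed"
    score: int


@dataclass
class ComplexNetwork:
    bait: str
    nodes: list[NetworkNode]
    edges: list[NetworkEdge]

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for node in self.nodes:
            g.add_node(
                node.accession,
                si_gi=node.si_gi,
                annotation_term=node.annotation_term,
                node_size=node.node_size,
                is_bait=node.accession == self.bait,
            )
        for edge in self.edges:
            g.add_edge(edge.a, edge.b, source=edge.source, score=edge.score)
        return g

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))

    def write_edge_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as handle:
            handle.write("protein_a\tprotein_b\tsource\tscore\n")
            for e in self.edges:
                handle.write(f"{e.a}\t{e.b}\t{e.source}\t{e.score}\n")

    def write_node_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as handle:
            handle.write("accession\tsi_gi\tannotation_term\tnode_size\tis_bait\n")
            for n in self.nodes:
                handle.write(
                    f"{n.accession}\t{n.si_gi:.6g}\t{n.annotation_term}\t"
                    f"{n.node_size:.6g}\t{int(n.accession == self.bait)}\n"
                )


def trace_filter(
    si_by_protein: Mapping[str, float],
    bait_accession: str,
    fraction: float = DEFAULT_TRACE_FRACTION,
    inclusive: bool = True,
) -> list[str]:
    """Drop "trace" proteins below ``fraction`` of the bait's SI_GI.

    Retains protein p iff SI_GI(p) >= fraction × SI_GI(bait) (boundary
    inclusive by default; set ``inclusive=False`` for a strict >). The bait
    itself is always retained. fraction=0.02 is equivalent to a 50-fold
    cutoff.
    """
    if bait_accession not in si_by_protein:
        raise ValidationError(f"bait {bait_accession!r} absent from SI_GI table")
    if not 0 < fraction < 1:
        raise ValidationError(f"trace fraction must be in (0, 1), got {fraction}")
    cutoff = fraction * si_by_protein[bait_accession]
    retained = []
    for acc, si in si_by_protein.items():
        if acc == bait_accession:
            retained.append(acc)
        elif si >= cutoff if inclusive else si > cutoff:
            retained.append(acc)
    return retained


def load_evidence(path: str | Path, min_score: int = DEFAULT_MIN_EVIDENCE_SCORE) -> EvidenceTable:
    """Read a STRING protein.links.detailed file, keeping high-confidence
    experimental edges.

    Rows whose ``experimental`` channel is below ``min_score`` are dropped
    regardless of their combined score. (a,b)/(b,a) duplicates collapse to
    a single undirected edge keeping the maximum scores.
    """
    path = Path(path)
    best: dict[frozenset[str], EvidenceEdge] = {}
    with path.open() as handle:
        header = handle.readline().split()
        try:
            ia = header.index("protein1")
            ib = header.index("protein2")
            ie = header.index("experimental")
            ic = header.index("combined_score")
        except ValueError as exc:
            raise ParseError(
                f"{path}: header must contain protein1, protein2, experimental, combined_score"
            ) from exc
        for line_no, line in enumerate(handle, start=2):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != len(header):
                raise ParseError(f"{path}: line {line_no}: expected {len(header)} fields")
            try:
                exp = int(fields[ie])
                comb = int(fields[ic])
            except ValueError as exc:
                raise ParseError(f"{path}: line {line_no}: non-integer score") from exc
            if not (0 <= exp <= 1000 and 0 <= comb <= 1000):
                raise ParseError(f"{path}: line {line_no}: score outside [0, 1000]")
            if exp < min_score:
                continue
            edge = EvidenceEdge(fields[ia], fields[ib], exp, comb)
            key = edge.key()
            old = best.get(key)
            if old is None or edge.experimental_score > old.experimental_score:
                best[key] = edge
    return EvidenceTable(list(best.values()))


def build_network(
    retained: Sequence[str],
    si_by_protein: Mapping[str, float],
    evidence: EvidenceTable,
    bait_accession: str,
    annotations: Mapping[str, str] | None = None,
    size_range: tuple[float, float] = (10.0, 50.0),
) -> ComplexNetwork:
    """Assemble the abundance-scaled complex network for one band.

    Nodes are the trace-filter survivors, sized s_min + (s_max − s_min) ×
    si_gi / max(si_gi). Evidence edges are restricted to retained×retained;
    each non-bait node additionally gets one imputed bait edge (these are
    kept distinct from evidence edges, so a pair may carry both).
    """
    if not retained:
        raise ValidationError("build_network: empty retained list")
    if bait_accession not in retained:
        raise ValidationError(f"bait {bait_accession!r} not among retained proteins")
    annotations = annotations or {}
    s_min, s_max = size_range
    max_si = max(si_by_protein[acc] for acc in retained)
    if max_si <= 0:
        raise ValidationError("build_network: all retained SI_GI values are zero")
    nodes = [
        NetworkNode(
            accession=acc,
            si_gi=si_by_protein[acc],
            annotation_term=annotations.get(acc, ""),
            node_size=s_min + (s_max - s_min) * si_by_protein[acc] / max_si,
        )
        for acc in retained
    ]
    retained_set = set(retained)
    edges = [
        NetworkEdge(e.protein_a, e.protein_b, "evidence", e.experimental_score)
        for e in evidence.restricted_to(retained_set).edges
    ]
    for acc in retained:
        if acc != bait_accession:
            edges.append(NetworkEdge(bait_accession, acc, "bait_imputed", 0))
    return ComplexNetwork(bait=bait_accession, nodes=nodes, edges=edges)


def load_annotations(path: str | Path) -> dict[str, str]:
    """Read a protein→term table (TSV: accession, term, score), keeping the
    highest-scoring term per protein."""
    best: dict[str, tuple[float, str]] = {}
    with Path(path).open() as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header[:3] != ["accession", "term", "score"]:
            raise ParseError(f"{path}: expected header 'accession\\tterm\\tscore'")
        for line_no, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            acc, term, score_s = line.split("\t")[:3]
            try:
                score = float(score_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {line_no}: non-numeric score") from exc
            if acc not in best or score > best[acc][0]:
                best[acc] = (score, term)
    return {acc: term for acc, (_, term) in best.items()}
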