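"""Detection of independently arisen loss-of-function alleles per gene.

Samples whose ORFS is interrupted are grouped into haplotype classes by the
signature of their ORFS-shifting variants; each class is a node.  Two nodes
are joined by an edge when any variant of one overlaps any variant of the
other in genomic position (deletions: shared reference base; insertions:
identical anchor).  Alleles sharing a single mutational origin all carry the
ancestral lesion, so their graph is complete; a graph missing at least one
edge implies at least two independent loss-of-function events.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from varsync.core_io import VariantCall


@dataclass(frozen=True)
class VariantSpan:
    """Genomic footprint of one ORFS-shifting variant."""

    chrom: str
    start: int
    end: int  # == start for insertions (anchor point)

    @classmethod
    def from_call(cls, c: VariantCall) -> "VariantSpan":
        return cls(c.chrom, c.pos, c.pos + len(c.ref_allele))

    def overlaps(self, other: "VariantSpan") -> bool:
        if self.chrom != other.chrom:
            return False
        if self.start == self.end or other.start == other.end:
            # insertion: anchors must coincide, or the anchor must fall
            # strictly inside the other variant's consumed span
            a, b = (self, other) if self.start == self.end else (other, self)
            if b.start == b.end:
                return a.start == b.start
            return b.start <= a.start < b.end or a.start == b.start
        return self.start < other.end and other.start < self.end


@dataclass
class OrfsShiftGraph:
    """Haplotype-class overlap graph of a gene's loss-of-function alleles."""

    gene_id: str
    nodes: list[frozenset[VariantSpan]]
    edges: set[tuple[int, int]]
    carriers: int  # samples across all nodes

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def missing_edges(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2 - self.n_edges


def build_orfs_shift_graph(
    gene_id: str,
    shifting_variants: dict[str, list[VariantCall]],
) -> OrfsShiftGraph:
    """Build the overlap graph from per-sample ORFS-shifting variant sets.

    Only samples with interrupted, trustable ORFS belong here; samples with
    identical variant-set signatures collapse into one node (identical by
    descent).
    """
    signatures: dict[frozenset[VariantSpan], int] = {}
    counts: dict[int, int] = {}
    for sample, calls in shifting_variants.items():
        sig = frozenset(VariantSpan.from_call(c) for c in calls)
        if not sig:
            continue
        node = signatures.setdefault(sig, len(signatures))
        counts[node] = counts.get(node, 0) + 1
    nodes = [sig for sig, _ in sorted(signatures.items(), key=lambda kv: kv[1])]
    edges: set[tuple[int, int]] = set()
    for i, j in combinations(range(len(nodes)), 2):
        if any(a.overlaps(b) for a in nodes[i] for b in nodes[j]):
            edges.add((i, j))
    return OrfsShiftGraph(gene_id, nodes, edges, sum(counts.values()))


def is_independent(
    graph: OrfsShiftGraph,
    min_carriers: int = 130,
    min_nodes: int = 2,
) -> tuple[bool, int]:
    """A gene carries independent loss-of-function alleles when it is common
    (carriers above the threshold, the ORFS analogue of a MAF filter), has at
    least two distinct allele classes, and its overlap graph is at least one
    edge short of complete.  Returns (verdict, number of missing edges)."""
    missing = graph.missing_edges
    verdict = (
        graph.carriers > min_carriers
        and graph.n_nodes >= min_nodes
        and missing >= 1
    )
    return verdict, missing


def independence_table(
    graphs: dict[str, OrfsShiftGraph],
    min_carriers: int = 130,
):
    """Summary table over genes: nodes, edges, missing edges, carriers, flag."""
    import pandas as pd

    rows = []
    for gene_id, g in graphs.items():
        indep, missing = is_independent(g, min_carriers=min_carriers)
        rows.append(
            {
                "gene_id": gene_id,
                "n_nodes": g.n_nodes,
                "n_edges": g.n_edges,
                "n_missing_edges": missing,
                "carriers": g.carriers,
                "independent": indep,
            }
        )
    return pd.DataFrame(rows)
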