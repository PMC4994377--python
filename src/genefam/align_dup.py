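"""Global pairwise protein alignment and duplication / homoeolog detection.

Duplicated gene pairs are called under three criteria used for plant gene
families: (a) the alignment covers more than 80 % of the longer gene,
(b) the aligned region exceeds 80 % identity, and (c) tightly linked copies
on one chromosome (tandem arrays) count as a single duplication event.
Homoeolog groups are connected components of qualifying pairs that lie on the
same homoeologous group but different sub-genomes: components spanning all of
A, B and D are triads, components spanning two sub-genomes are pairs.

The Needleman-Wunsch engine is Biopython's :class:`PairwiseAligner` (global
mode, affine gaps, BLOSUM62 by default); identity is computed over aligned
non-gap-pair columns and coverage over the longer sequence's length.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from .genome_map import GeneLocus

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5


@dataclass(frozen=True)
class AlignmentResult:
    id_a: str
    id_b: str
    aligned_columns: int  # non-gap-pair columns
    match_columns: int
    identity_pct: float
    coverage_pct: float
    score: float


@dataclass(frozen=True)
class DuplicationPair:
    id_a: str
    id_b: str
    kind: str  # "intra_chromosome" | "segmental_inter_chromosome"
    evidence: AlignmentResult
    collapsed_from: tuple[tuple[str, str], ...] = ()  # tandem pairs this event stands for


@dataclass(frozen=True)
class HomoeologGroup:
    group: int
    members: dict  # subgenome -> tuple of gene ids (usually length 1)
    flagged: bool = False  # True when a sub-genome contributes >1 gene

    @property
    def n_subgenomes(self) -> int:
        return len(self.members)

    @property
    def is_triad(self) -> bool:
        return self.n_subgenomes == 3


def _make_aligner(substitution_matrix, gap_open, gap_extend) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if isinstance(substitution_matrix, str):
        substitution_matrix = substitution_matrices.load(substitution_matrix)
    aligner.substitution_matrix = substitution_matrix
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def global_align(
    a: str,
    b: str,
    substitution_matrix=DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    id_a: str = "a",
    id_b: str = "b",
) -> AlignmentResult:
    """Needleman-Wunsch with affine gaps; deterministic first-optimum traceback."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(substitution_matrix, gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    aligned = matches = 0
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            aligned += 1
            if x == y:
                matches += 1
    identity = 100.0 * matches / aligned if aligned else 0.0
    coverage = 100.0 * aligned / max(len(a), len(b))
    return AlignmentResult(id_a, id_b, aligned, matches, identity, coverage, aln.score)


def call_duplications(
    sequences: dict[str, str],
    loci: dict[str, GeneLocus],
    coverage_min: float = 80.0,
    identity_min: float = 80.0,
    tandem_window: int = 100_000,
    substitution_matrix=DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> list[DuplicationPair]:
    """All qualifying duplication pairs, with tandem arrays collapsed.

    Every gene must have a locus.  Qualifying same-chromosome pairs whose
    starts lie within ``tandem_window`` are grouped transitively into tandem
    clusters; each cluster is reported as the single highest-identity pair.
    """
    missing = [g for g in sequences if g not in loci]
    if missing:
        raise ValueError(f"genes without a locus: {missing}")
    ids = sorted(sequences)
    qualifying: list[AlignmentResult] = []
    for ga, gb in itertools.combinations(ids, 2):
        res = global_align(
            sequences[ga], sequences[gb], substitution_matrix, gap_open, gap_extend,
            id_a=ga, id_b=gb,
        )
        if res.coverage_pct > coverage_min and res.identity_pct > identity_min:
            qualifying.append(res)

    # criterion (c): collapse tightly linked same-chromosome pairs
    tandem = nx.Graph()
    for res in qualifying:
        la, lb = loci[res.id_a], loci[res.id_b]
        if (
            la.placed
            and lb.placed
            and la.chromosome == lb.chromosome
            and la.start is not None
            and lb.start is not None
            and abs(la.start - lb.start) <= tandem_window
        ):
            tandem.add_edge(res.id_a, res.id_b, result=res)

    collapsed: list[DuplicationPair] = []
    in_tandem: set[frozenset] = set()
    for comp in sorted(nx.connected_components(tandem), key=sorted):
        edges = [tandem.edges[e]["result"] for e in tandem.subgraph(comp).edges]
        in_tandem.update(frozenset((r.id_a, r.id_b)) for r in edges)
        best = max(edges, key=lambda r: (r.identity_pct, r.id_a, r.id_b))
        others = tuple(
            sorted((r.id_a, r.id_b) for r in edges if r is not best)
        )
        collapsed.append(
            DuplicationPair(best.id_a, best.id_b, "intra_chromosome", best, others)
        )

    for res in qualifying:
        if frozenset((res.id_a, res.id_b)) in in_tandem:
            continue
        la, lb = loci[res.id_a], loci[res.id_b]
        same_chrom = (
            la.placed and lb.placed and la.chromosome == lb.chromosome
        )
        kind = "intra_chromosome" if same_chrom else "segmental_inter_chromosome"
        collapsed.append(DuplicationPair(res.id_a, res.id_b, kind, res))
    collapsed.sort(key=lambda p: (p.id_a, p.id_b))
    return collapsed


def call_homoeolog_groups(
    pairs: list[DuplicationPair], loci: dict[str, GeneLocus]
) -> list[HomoeologGroup]:
    """Homoeolog triads/pairs from cross-subgenome edges within one group."""
    g = nx.Graph()
    for p in pairs:
        la, lb = loci[p.id_a], loci[p.id_b]
        if (
            la.placed
            and lb.placed
            and la.group == lb.group
            and la.subgenome != lb.subgenome
        ):
            g.add_edge(p.id_a, p.id_b)
    groups = []
    for comp in sorted(nx.connected_components(g), key=sorted):
        members: dict[str, list[str]] = {}
        for gene in sorted(comp):
            members.setdefault(loci[gene].subgenome, []).append(gene)
        if len(members) < 2:
            continue
        groups.append(
            HomoeologGroup(
                group=loci[next(iter(comp))].group,
                members={s: tuple(v) for s, v in sorted(members.items())},
                flagged=any(len(v) > 1 for v in members.values()),
            )
        )
    return groups


def link_table(pairs: list[DuplicationPair], loci: dict[str, GeneLocus]):
    """Circos-style link rows (chrom, start, end for each side of a pair)."""
    rows = []
    for p in pairs:
        la, lb = loci[p.id_a], loci[p.id_b]
        rows.append(
            {
                "chrom_a": la.chromosome, "start_a": la.start, "end_a": la.end,
                "chrom_b": lb.chromosome, "start_b": lb.start, "end_b": lb.end,
                "id_a": p.id_a, "id_b": p.id_b, "kind": p.kind,
            }
        )
    import pandas as pd

    return pd.DataFrame(rows)
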