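"""Exon/intron structure profiling from GFF3-style annotation.

Gene models are exon interval lists in genomic order; introns are the gaps
between consecutive exons.  Intron phase is the cumulative coding length
before the intron modulo 3 (phase 0 introns fall between codons).  Abutting
exons (end + 1 == next start) produce zero-length introns, which are counted
but flagged as likely annotation artifacts rather than silently merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass


@dataclass(frozen=True)
class Intron:
    start: int  # 1-based first intronic base (end_prev_exon + 1)
    end: int  # 1-based last intronic base (start_next_exon - 1)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def zero_length(self) -> bool:
        return self.length == 0


@dataclass
class GeneModel:
    gene_id: str
    strand: str  # "+", "-", "unknown"
    exons: list[tuple[int, int]]  # 1-based inclusive, genomic order
    cds: list[tuple[int, int]] | None = None

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene model without exons")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping exons {(s1, e1)} / {(s2, e2)}")
        if self.cds:
            self.cds = sorted(self.cds)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


def parse_gff(path) -> list[GeneModel]:
    """Group exon (and CDS) features by their Parent attribute (via gffutils).

    Exon rows without a Parent are skipped with a warning.  Returns models
    sorted by gene id; an empty file yields an empty list.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", force=True
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    strands: dict[str, str] = {}
    for ftype, store in (("exon", exons), ("CDS", cds)):
        for feat in db.features_of_type(ftype):
            parents = feat.attributes.get("Parent")
            if not parents:
                warnings.warn(f"{ftype} feature {feat.id} without Parent skipped")
                continue
            for p in parents:
                store.setdefault(p, []).append((feat.start, feat.end))
                strands[p] = feat.strand if feat.strand in "+-" else "unknown"
    return [
        GeneModel(gid, strands[gid], exons[gid], cds.get(gid))
        for gid in sorted(exons)
    ]


def introns(model: GeneModel) -> list[Intron]:
    """Gaps between consecutive exons, in genomic order."""
    out = []
    for (_, e1), (s2, _) in zip(model.exons, model.exons[1:]):
        out.append(Intron(e1 + 1, s2 - 1))
    return out


def intron_count(model: GeneModel) -> int:
    return len(model.exons) - 1


def zero_length_introns(model: GeneModel) -> list[Intron]:
    return [i for i in introns(model) if i.zero_length]


def total_intron_length(model: GeneModel) -> int:
    span = model.span
    return (span[1] - span[0] + 1) - sum(e - s + 1 for s, e in model.exons)


def intron_phase(model: GeneModel, cds: list[tuple[int, int]] | None = None) -> list[int]:
    """Phase of each intron interrupting the coding sequence.

    Phase = cumulative coding length 5' of the intron, modulo 3.  For minus
    strand models the CDS segments are walked in transcription order (highest
    genomic coordinate first).  Returns one phase per CDS-interrupting
    intron; an intron-less CDS yields an empty list.
    """
    segments = cds if cds is not None else model.cds
    if not segments:
        raise ValueError(f"{model.gene_id}: CDS coordinates unavailable")
    segments = sorted(segments)
    if model.strand == "-":
        segments = segments[::-1]
    phases = []
    cumulative = 0
    for seg in segments[:-1]:
        cumulative += seg[1] - seg[0] + 1
        phases.append(cumulative % 3)
    return phases


def structure_table(models: list[GeneModel]):
    """Per-gene exon/intron counts (and phases where CDS is annotated)."""
    import pandas as pd

    rows = []
    for m in models:
        phases = None
        if m.cds:
            phases = ",".join(map(str, intron_phase(m)))
        rows.append(
            {
                "gene_id": m.gene_id,
                "strand": m.strand,
                "n_exons": len(m.exons),
                "n_introns": intron_count(m),
                "n_zero_length_introns": len(zero_length_introns(m)),
                "intron_phases": phases,
            }
        )
    return pd.DataFrame(rows)
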