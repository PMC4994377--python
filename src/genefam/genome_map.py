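"""Genomic locus parsing and chromosomal distributions for allohexaploid wheat.

Bread wheat carries three sub-genomes (A, B, D), each with seven chromosomes
grouped into homoeologous groups 1-7.  Gene locations are written either as
chromosome-anchored spans (``"5D:146319049-146323269"``) or as scaffold-only
placements whose scaffold name encodes the chromosome arm the scaffold was
assigned to (``"scaffold_2BL_6949321:447-1269"``).  Scaffold-only genes still
count toward their encoded chromosome in per-chromosome totals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

SUBGENOMES = ("A", "B", "D")
GROUPS = tuple(range(1, 8))

#: all 21 wheat chromosome labels, "1A" .. "7D"
CHROMOSOMES = tuple(f"{g}{s}" for g in GROUPS for s in SUBGENOMES)

_ANCHORED_RE = re.compile(r"^([1-7])([ABD])([SL])?:(\d+)-(\d+)$")
_SCAFFOLD_RE = re.compile(r"^scaffold_([1-7])([ABD])([SL])?_\d+:(\d+)-(\d+)$")
_COORDS_RE = re.compile(r":(\d+)-(\d+)$")


@dataclass(frozen=True)
class GeneLocus:
    """A parsed genomic location.

    ``group``/``subgenome`` are ``None`` only when the raw string carries no
    recognizable chromosome token; such loci are *unplaced*.  Coordinates are
    1-based inclusive, as printed.
    """

    gene_id: str
    raw: str
    group: int | None
    subgenome: str | None
    arm: str = "unknown"  # "S", "L" or "unknown"
    anchored: bool = False
    start: int | None = None
    end: int | None = None

    @property
    def placed(self) -> bool:
        return self.group is not None

    @property
    def chromosome(self) -> str | None:
        """Chromosome label like ``"3A"``, or None for unplaced loci."""
        if self.group is None:
            return None
        return f"{self.group}{self.subgenome}"

    def canonical(self) -> str:
        """Serialized form; ``parse_locus`` is idempotent on this."""
        if not self.placed:
            return self.raw
        if self.anchored:
            return f"{self.chromosome}:{self.start}-{self.end}"
        return self.raw


def parse_locus(gene_id: str, raw: str) -> GeneLocus:
    """Parse a location string in the family-table notation.

    Raises ValueError for an empty string or for a recognized chromosome with
    start > end.  An unrecognized chromosome token yields an unplaced locus.
    """
    raw = raw.strip()
    if not raw:
        raise ValueError(f"{gene_id}: empty location string")
    m = _ANCHORED_RE.match(raw)
    anchored = m is not None
    if m is None:
        m = _SCAFFOLD_RE.match(raw)
    if m is None:
        # no recognizable chromosome token -> unplaced
        cm = _COORDS_RE.search(raw)
        start = end = None
        if cm:
            s, e = int(cm.group(1)), int(cm.group(2))
            if s <= e:
                start, end = s, e
        return GeneLocus(gene_id, raw, None, None, "unknown", False, start, end)
    group, sub, arm, start, end = m.groups()
    start, end = int(start), int(end)
    if start > end:
        raise ValueError(f"{gene_id}: start > end in {raw!r}")
    return GeneLocus(
        gene_id, raw, int(group), sub, arm or "unknown", anchored, start, end
    )


@dataclass
class Distribution:
    by_chromosome: dict[str, int]
    by_group: dict[int, int]
    by_subgenome: dict[str, int]
    unplaced: int = 0
    n_placed: int = 0


def distribution(loci: list[GeneLocus]) -> Distribution:
    """Count placed loci per chromosome, homoeologous group and sub-genome."""
    by_chrom = {c: 0 for c in CHROMOSOMES}
    by_group = {g: 0 for g in GROUPS}
    by_sub = {s: 0 for s in SUBGENOMES}
    unplaced = 0
    for loc in loci:
        if not loc.placed:
            unplaced += 1
            continue
        by_chrom[loc.chromosome] += 1
        by_group[loc.group] += 1
        by_sub[loc.subgenome] += 1
    return Distribution(by_chrom, by_group, by_sub, unplaced, len(loci) - unplaced)


def to_bed(loci: list[GeneLocus]) -> pd.DataFrame:
    """Placed loci as BED intervals (0-based half-open)."""
    rows = [
        {
            "chrom": loc.chromosome,
            "start": loc.start - 1,
            "end": loc.end,
            "name": loc.gene_id,
        }
        for loc in loci
        if loc.placed and loc.start is not None
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def from_bed(bed: pd.DataFrame) -> list[GeneLocus]:
    """Inverse of :func:`to_bed` (chromosome-anchored loci, 1-based inclusive)."""
    return [
        parse_locus(r["name"], f"{r['chrom']}:{int(r['start']) + 1}-{int(r['end'])}")
        for _, r in bed.iterrows()
    ]


def read_loci_tsv(path) -> list[GeneLocus]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [parse_locus(r["gene_id"], r["location"]) for _, r in df.iterrows()]


def write_loci_tsv(loci: list[GeneLocus], path) -> None:
    pd.DataFrame(
        {"gene_id": [l.gene_id for l in loci], "location": [l.canonical() for l in loci]}
    ).to_csv(path, sep="\t", index=False)
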