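"""Promoter scanning for degenerate cis-regulatory elements.

Extracts the proximal promoter (default 2 kb upstream of the transcription
start) and scans both strands for IUPAC-coded element consensi.  A small
curated element set (ABA/gibberellin/ethylene response elements, drought,
cold and defense boxes, core promoter elements) ships as an example config;
users supply their own table for real screens.  All overlapping matches are
reported; counting conventions are left to downstream code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd
from Bio.Seq import Seq

from .genome_map import GeneLocus

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

CATEGORIES = ("stress", "hormone", "light", "core", "other")


@dataclass(frozen=True)
class CisElement:
    name: str
    category: str
    iupac: str

    def __post_init__(self):
        bad = set(self.iupac.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"element {self.name}: invalid IUPAC codes {sorted(bad)}")
        if self.category not in CATEGORIES:
            raise ValueError(f"element {self.name}: unknown category {self.category!r}")


@dataclass(frozen=True)
class CisHit:
    gene_id: str
    element: str
    strand: str  # "+" or "-"
    offset: int  # 0-based from upstream-region start


def load_default_elements() -> list[CisElement]:
    return load_element_config(
        resources.files("genefam").joinpath("data/cis_elements.tsv")
    )


def load_element_config(path) -> list[CisElement]:
    if hasattr(path, "open"):
        with path.open() as fh:
            df = pd.read_csv(fh, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        CisElement(r["name"], r["category"], r["iupac"].upper())
        for _, r in df.iterrows()
    ]


def extract_upstream(
    contigs: dict[str, str],
    locus: GeneLocus,
    length: int = 2000,
    strand: str = "+",
) -> tuple[str, bool]:
    """The ``length`` bases 5' of the gene start; (sequence, truncated flag).

    Plus strand: bases immediately before ``locus.start``.  Minus strand: the
    reverse complement of the bases immediately after ``locus.end``.  Regions
    are truncated at the contig edge with a flag.
    """
    if not locus.placed:
        raise ValueError(f"{locus.gene_id}: cannot extract upstream of unplaced locus")
    contig = contigs[locus.chromosome]
    if strand == "+":
        lo = max(0, locus.start - 1 - length)
        region = contig[lo : locus.start - 1]
        truncated = len(region) < length
        return region, truncated
    elif strand == "-":
        region = contig[locus.end : locus.end + length]
        truncated = len(region) < length
        return str(Seq(region).reverse_complement()), truncated
    raise ValueError(f"bad strand {strand!r}")


def _iupac_regex(pattern: str) -> re.Pattern:
    # lookahead so overlapping matches are all reported
    body = "".join(f"[{IUPAC[c]}]" for c in pattern.upper())
    return re.compile(f"(?=({body}))")


def scan(
    region: str, elements: list[CisElement], gene_id: str = ""
) -> list[CisHit]:
    """All matches of each element on both strands, ordered by (offset, name,
    strand).  The minus-strand search matches the reverse complement of the
    element against the given region; offsets refer to the region."""
    if not region:
        raise ValueError("empty promoter region")
    region = region.upper()
    hits = []
    for el in elements:
        for m in _iupac_regex(el.iupac).finditer(region):
            hits.append(CisHit(gene_id, el.name, "+", m.start()))
        rc = str(Seq(el.iupac).reverse_complement())
        for m in _iupac_regex(rc).finditer(region):
            hits.append(CisHit(gene_id, el.name, "-", m.start()))
    hits.sort(key=lambda h: (h.offset, h.element, h.strand))
    return hits


def category_counts(
    hits: list[CisHit], elements: list[CisElement]
) -> pd.DataFrame:
    """Per-gene, per-category hit-count matrix."""
    cat = {e.name: e.category for e in elements}
    rows: dict[str, dict[str, int]] = {}
    for h in hits:
        rows.setdefault(h.gene_id, {c: 0 for c in CATEGORIES})
        rows[h.gene_id][cat[h.element]] += 1
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
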