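"""The packaged family table and its summary statistics.

The package ships a transcription of the 155-member wheat MAPKKK gene table
(ids, subfamily assignments, protein length, EST support, pI, Mw, predicted
subcellular compartments and genomic location) as a TSV fixture.  The loader
also accepts user-supplied tables with the same columns, so the same summary
operations apply to any family inventory.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from . import genome_map

SUBFAMILIES = ("MEKK", "ZIK", "Raf")

_COLUMNS = [
    "serial",
    "mapkkk_id",
    "ensembl_id",
    "subfamily",
    "subfamily_id",
    "aa_length",
    "est_count",
    "pi",
    "mw_kda",
    "subcellular",
    "location",
]


@dataclass(frozen=True)
class FamilyRecord:
    serial_no: int
    mapkkk_id: str
    ensembl_id: str
    subfamily: str
    subfamily_id: str
    aa_length: int
    est_count: int
    pi: float
    mw_kda: float
    subcellular: tuple[str, ...]
    location_string: str

    def __post_init__(self):
        if self.subfamily not in SUBFAMILIES:
            raise ValueError(f"row {self.serial_no}: unknown subfamily {self.subfamily!r}")
        if not self.subfamily_id.startswith(f"Ta{self.subfamily}"):
            raise ValueError(
                f"row {self.serial_no}: subfamily id {self.subfamily_id!r} "
                f"does not match subfamily {self.subfamily}"
            )
        if self.aa_length <= 0:
            raise ValueError(f"row {self.serial_no}: non-positive length")
        if self.est_count < 0:
            raise ValueError(f"row {self.serial_no}: negative EST count")
        if not 0 < self.pi < 14:
            raise ValueError(f"row {self.serial_no}: pI {self.pi} outside (0, 14)")


def default_table_path():
    """Path-like handle on the packaged family-table fixture."""
    return resources.files("genefam").joinpath("data/family_table.tsv")


def load_family_table(path=None) -> list[FamilyRecord]:
    """Load the packaged fixture (default) or a user table with the same columns."""
    try:
        if path is None:
            with default_table_path().open("r") as fh:
                df = pd.read_csv(fh, sep="\t", dtype=str)
        else:
            df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError("family table file is empty") from exc
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"family table missing columns: {missing}")
    if df.empty:
        raise ValueError("family table contains no records")
    records = []
    for _, row in df.iterrows():
        serial = row["serial"]
        try:
            records.append(
                FamilyRecord(
                    serial_no=int(serial),
                    mapkkk_id=row["mapkkk_id"],
                    ensembl_id=row["ensembl_id"],
                    subfamily=row["subfamily"],
                    subfamily_id=row["subfamily_id"],
                    aa_length=int(row["aa_length"]),
                    est_count=int(row["est_count"]),
                    pi=float(row["pi"]),
                    mw_kda=float(row["mw_kda"]),
                    subcellular=tuple(str(row["subcellular"]).split(";")),
                    location_string=row["location"],
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed row (serial {serial}): {exc}") from exc
    serials = sorted(r.serial_no for r in records)
    if serials != list(range(1, len(records) + 1)):
        raise ValueError("serial numbers are not unique and contiguous from 1")
    return records


@dataclass
class FamilySummary:
    n_total: int
    n_by_subfamily: dict[str, int]
    n_by_subgenome: dict[str, int]
    n_by_group: dict[int, int]
    n_by_chromosome: dict[str, int]
    n_unplaced: int
    length_range: tuple[int, int]
    pi_range: tuple[float, float]
    mw_range: tuple[float, float]
    n_zero_est: int
    zero_est_genes: tuple[str, ...]
    max_est: tuple[str, int]


def summarize_family(records: list[FamilyRecord]) -> FamilySummary:
    """Printed-table statistics: counts, ranges, extreme and zero-EST genes.

    Chromosome assignment delegates to :mod:`genefam.genome_map`; unparseable
    locations are counted under ``n_unplaced``.
    """
    if not records:
        raise ValueError("no records to summarize")
    loci = [genome_map.parse_locus(r.subfamily_id, r.location_string) for r in records]
    dist = genome_map.distribution(loci)
    lengths = [r.aa_length for r in records]
    pis = [r.pi for r in records]
    mws = [r.mw_kda for r in records]
    zero = tuple(r.subfamily_id for r in records if r.est_count == 0)
    best = max(records, key=lambda r: (r.est_count, r.subfamily_id))
    return FamilySummary(
        n_total=len(records),
        n_by_subfamily={s: sum(1 for r in records if r.subfamily == s) for s in SUBFAMILIES},
        n_by_subgenome=dist.by_subgenome,
        n_by_group=dist.by_group,
        n_by_chromosome=dist.by_chromosome,
        n_unplaced=dist.unplaced,
        length_range=(min(lengths), max(lengths)),
        pi_range=(min(pis), max(pis)),
        mw_range=(min(mws), max(mws)),
        n_zero_est=len(zero),
        zero_est_genes=zero,
        max_est=(best.subfamily_id, best.est_count),
    )
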