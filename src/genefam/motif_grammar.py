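"""Degenerate signature-motif grammar and subfamily classification.

MAP kinase kinase kinases split into three subfamilies, each diagnosed by a
short degenerate signature inside the kinase activation segment:

* MEKK: ``G(T/S)PX(W/Y/F)MAPEV``
* ZIK:  ``GTPEFMAPE(L/V)Y``
* Raf:  ``GTXX(W/Y)MAPE``

A pattern position is a fixed residue, a parenthesized alternative set
``(A/B/...)``, or the wildcard ``X`` (any residue).  The Raf signature is the
most degenerate and is nested inside many MEKK/ZIK instances, so matches are
resolved by a specificity precedence (ZIK before MEKK before Raf); proteins
matching more than one subfamily are flagged as ambiguous rather than
silently resolved.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: default specificity precedence, most specific first (lowest rank)
DEFAULT_RANKS = {"ZIK": 0, "MEKK": 1, "Raf": 2}


@dataclass(frozen=True)
class SignatureMotif:
    subfamily: str
    pattern: str
    #: one entry per position: a frozenset of allowed residues, or None for X
    positions: tuple[frozenset | None, ...]
    specificity_rank: int

    def __len__(self) -> int:
        return len(self.positions)

    def matches_at(self, seq: str, offset: int) -> bool:
        if offset < 0 or offset + len(self) > len(seq):
            return False
        for pos, allowed in zip(range(offset, offset + len(self)), self.positions):
            if allowed is None:  # pattern wildcard X matches anything
                continue
            if seq[pos] not in allowed:  # sequence 'X' fails every fixed position
                return False
        return True

    def find(self, seq: str) -> int | None:
        """Leftmost match offset, or None."""
        for off in range(len(seq) - len(self) + 1):
            if self.matches_at(seq, off):
                return off
        return None


@dataclass(frozen=True)
class SubfamilyCall:
    protein_id: str
    subfamily: str  # "MEKK" / "ZIK" / "Raf" / "unclassified"
    matched_pattern: SignatureMotif | None
    match_start: int | None
    ambiguous: bool = False


def compile_signature(
    pattern_text: str, subfamily: str = "", specificity_rank: int = 0
) -> SignatureMotif:
    """Compile a degenerate pattern string into a positional matcher.

    Raises ValueError on unbalanced parentheses, empty alternative sets or
    non-residue letters.
    """
    positions: list[frozenset | None] = []
    i, text = 0, pattern_text.strip()
    if not text:
        raise ValueError("empty pattern")
    while i < len(text):
        c = text[i]
        if c == "(":
            j = text.find(")", i)
            if j < 0:
                raise ValueError(f"unbalanced parenthesis in {text!r}")
            alts = text[i + 1 : j].split("/")
            if not alts or any(len(a) != 1 or a not in AMINO_ACIDS for a in alts):
                raise ValueError(f"bad alternative set {text[i:j + 1]!r}")
            positions.append(frozenset(alts))
            i = j + 1
        elif c == "X":
            positions.append(None)
            i += 1
        elif c in AMINO_ACIDS:
            positions.append(frozenset(c))
            i += 1
        else:
            raise ValueError(f"non-residue letter {c!r} in pattern {text!r}")
    if len(positions) < 8:
        raise ValueError(f"pattern {text!r} shorter than 8 positions")
    return SignatureMotif(subfamily, text, tuple(positions), specificity_rank)


def load_default_motifs() -> list[SignatureMotif]:
    """The three shipped subfamily signatures, ranked by specificity."""
    return load_motif_config(
        resources.files("genefam").joinpath("data/signature_motifs.tsv")
    )


def load_motif_config(path) -> list[SignatureMotif]:
    """Read ``SUBFAMILY<TAB>PATTERN`` lines; rank = order of appearance."""
    if hasattr(path, "read_text"):
        text = path.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    motifs = []
    for rank, line in enumerate(l for l in text.splitlines() if l.strip()):
        subfamily, pattern = line.split("\t")
        motifs.append(compile_signature(pattern, subfamily, rank))
    return motifs


def classify_protein(
    seq: str, motifs: list[SignatureMotif] | None = None, protein_id: str = ""
) -> SubfamilyCall:
    """Assign a protein to a subfamily by scanning for signature motifs.

    If motifs of several subfamilies match, the most specific (lowest rank)
    wins and the call is flagged ambiguous.  Leftmost match is reported.
    """
    if not seq:
        raise ValueError("empty protein sequence")
    if motifs is None:
        motifs = load_default_motifs()
    hits: dict[str, tuple[int, SignatureMotif, int]] = {}
    for motif in motifs:
        off = motif.find(seq)
        if off is not None and motif.subfamily not in hits:
            hits[motif.subfamily] = (motif.specificity_rank, motif, off)
    if not hits:
        return SubfamilyCall(protein_id, "unclassified", None, None)
    best = min(hits.values(), key=lambda t: t[0])
    return SubfamilyCall(
        protein_id, best[1].subfamily, best[1], best[2], ambiguous=len(hits) > 1
    )


def expand_pattern(motif: SignatureMotif, wildcard_residue: str = "A") -> list[str]:
    """Exhaustive literal instantiations of a motif's alternative sets.

    Wildcard positions are instantiated with ``wildcard_residue`` so the
    number of expansions is the product of the alternative-set sizes.
    """
    choices = [
        [wildcard_residue] if p is None else sorted(p) for p in motif.positions
    ]
    return ["".join(c) for c in itertools.product(*choices)]


def is_instance_of(literal: str, motif: SignatureMotif) -> bool:
    """Whole-string instance test: same length and every position allowed."""
    return len(literal) == len(motif) and motif.matches_at(literal, 0)
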