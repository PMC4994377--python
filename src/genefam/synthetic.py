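"""Seeded generators emulating the statistical structure of the study inputs.

The real inputs (an allohexaploid genome, RNA-seq FPKM tables, qPCR plates)
are not redistributable, so every analysis stage is exercised on synthetic
data with planted, recoverable structure:

* kinase-like proteins carrying exactly one subfamily signature motif inside
  a shared kinase-like block, plus motif-free decoys;
* a 21-chromosome A/B/D genome layout with planted homoeolog triads,
  two-subgenome pairs, tandem arrays and unrelated singletons;
* negative-binomial FPKM matrices with planted tissue-specific, up-, down-
  and stress-specific genes over a control/salt time-course design;
* qPCR Ct tables consistent with planted fold changes under the
  comparative-Ct identity.

Planted counts follow the study design this package emulates: 11 homoeolog
triads, tissue-specific genes per organ (grain 1, root 6, stem 1, leaf 6,
spike 3), 16 silent genes, 4 stress-specific and 4 down-regulated genes.
Every generator is a pure function of its spec (seed included).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_map import GeneLocus, SUBGENOMES, parse_locus
from .motif_grammar import AMINO_ACIDS, SignatureMotif, load_default_motifs, classify_protein

AA = sorted(AMINO_ACIDS)

# common conservative exchanges (BLOSUM62-positive pairs) used when mutating
# a sequence toward a target identity
_EXCHANGE = {
    "A": "GST", "R": "KQ", "N": "DHS", "D": "EN", "C": "AS", "E": "DQK",
    "Q": "ERK", "G": "AS", "H": "NY", "I": "VLM", "L": "IMV", "K": "RQE",
    "M": "LIV", "F": "YWL", "P": "AS", "S": "TAN", "T": "SV", "W": "YF",
    "Y": "FWH", "V": "ILM",
}


@dataclass
class SyntheticSpec:
    seed: int = 0
    # proteins
    n_mekk: int = 8
    n_zik: int = 4
    n_raf: int = 12
    n_decoy: int = 20
    protein_length: tuple[int, int] = (200, 400)
    # genome layout
    n_triads: int = 11
    n_pairs: int = 24
    n_tandem_clusters: int = 2
    tandem_cluster_size: int = 3
    n_singletons: int = 8
    identity_within: tuple[float, float] = (0.85, 0.98)
    identity_between_max: float = 0.40
    chromosome_length: int = 10_000_000
    tandem_window: int = 100_000
    member_length: int = 250
    # expression
    tissues: tuple[str, ...] = ("grain", "root", "stem", "leaf", "spike")
    n_genes_expression: int = 155
    n_tissue_specific: tuple[int, ...] = (1, 6, 1, 6, 3)  # per tissue, in order
    n_silent: int = 16
    n_up: int = 60  # the study reports most family genes up-regulated under stress
    n_down: int = 4
    n_stress_specific: int = 4
    effect_log2fc: float = 3.0
    n_replicates: int = 3
    timepoints: tuple[float, ...] = (0.0, 6.0, 12.0, 24.0, 48.0)
    nb_mean: float = 20.0
    nb_dispersion: float = 0.1
    expressed_threshold: float = 1.0
    # qPCR
    ct_reference_mean: float = 20.0
    ct_target_mean: float = 26.0
    ct_sd: float = 0.15
    ct_fold_changes: tuple[float, ...] = (4.0, 1.0, 0.25)
    ct_replicates: int = 3

    def __post_init__(self):
        counts = [
            self.n_mekk, self.n_zik, self.n_raf, self.n_decoy, self.n_triads,
            self.n_pairs, self.n_tandem_clusters, self.n_singletons,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        lo, hi = self.identity_within
        if not (0 <= lo <= hi <= 1):
            raise ValueError("identity_within must be within [0, 1]")


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.seed) % (2**31), stream])


def _random_protein(rng, length: int) -> str:
    return "".join(rng.choice(AA, size=length))


def _instantiate_motif(motif: SignatureMotif, rng) -> str:
    out = []
    for pos in motif.positions:
        if pos is None:
            out.append(str(rng.choice(AA)))
        else:
            out.append(str(rng.choice(sorted(pos))))
    return "".join(out)


def _mutate_to_identity(seq: str, identity: float, rng, forbidden=()) -> str:
    """Substitute ~(1-identity) of the positions, avoiding the spans in
    ``forbidden`` (list of (start, end) half-open index ranges)."""
    n_mut = round((1.0 - identity) * len(seq))
    allowed = [
        i for i in range(len(seq))
        if not any(s <= i < e for s, e in forbidden)
    ]
    sites = rng.choice(allowed, size=min(n_mut, len(allowed)), replace=False)
    chars = list(seq)
    for i in sites:
        partners = _EXCHANGE.get(chars[i], "A")
        repl = str(rng.choice(list(partners)))
        if repl == chars[i]:
            repl = str(rng.choice([a for a in AA if a != chars[i]]))
        chars[i] = repl
    return "".join(chars)


# ---------------------------------------------------------------- proteins


def gen_proteins(spec: SyntheticSpec):
    """Family proteins with one planted signature each, plus motif-free decoys.

    Returns (sequences dict, truth DataFrame with subfamily and motif offset).
    The family proteins share a kinase-like core block; the signature sits at
    a fixed position inside it.  Decoys are resampled (up to 20 times) until
    they contain no signature; failures are recorded in the truth table.
    """
    rng = _rng(spec, 1)
    motifs = {m.subfamily: m for m in load_default_motifs()}
    core = _random_protein(rng, 60)
    seqs: dict[str, str] = {}
    rows = []
    plan = (
        [("MEKK", i) for i in range(spec.n_mekk)]
        + [("ZIK", i) for i in range(spec.n_zik)]
        + [("Raf", i) for i in range(spec.n_raf)]
    )
    for subfamily, i in plan:
        gid = f"SYN_{subfamily}{i + 1}"
        length = int(rng.integers(*spec.protein_length))
        motif_seq = _instantiate_motif(motifs[subfamily], rng)
        block = core[:25] + motif_seq + core[25 + len(motif_seq):]
        flank_n = int(rng.integers(20, max(21, length - len(block) - 20)))
        protein = (
            _random_protein(rng, flank_n)
            + block
            + _random_protein(rng, max(0, length - len(block) - flank_n))
        )
        offset = flank_n + 25
        seqs[gid] = protein
        rows.append(
            {"gene_id": gid, "subfamily": subfamily, "motif_offset": offset,
             "spurious": False}
        )
    for i in range(spec.n_decoy):
        gid = f"SYN_DECOY{i + 1}"
        spurious = True
        for _ in range(20):
            cand = _random_protein(rng, int(rng.integers(*spec.protein_length)))
            if classify_protein(cand, list(motifs.values())).subfamily == "unclassified":
                spurious = False
                break
        seqs[gid] = cand
        rows.append(
            {"gene_id": gid, "subfamily": "decoy", "motif_offset": -1,
             "spurious": spurious}
        )
    return seqs, pd.DataFrame(rows)


# ------------------------------------------------------------ genome layout


@dataclass
class GenomeLayout:
    sequences: dict[str, str]
    loci: dict[str, GeneLocus]
    truth: pd.DataFrame  # gene_id, unit, role, chromosome, start, end


def gen_genome_layout(spec: SyntheticSpec) -> GenomeLayout:
    """Planted homoeolog triads/pairs, tandem arrays and singleton genes.

    Triad/pair members derive from a shared ancestor mutated to a within-
    group identity drawn from ``identity_within``; unrelated units are
    independent random sequences (expected pairwise identity far below
    ``identity_between_max``).  Tandem copies sit within ``tandem_window`` on
    one chromosome; all other placements are spaced beyond the window.
    """
    rng = _rng(spec, 2)
    seqs: dict[str, str] = {}
    loci: dict[str, GeneLocus] = {}
    rows = []
    next_start: dict[str, int] = {}

    def place(gene_id, chrom, tandem_gap=None):
        gap = (
            int(tandem_gap)
            if tandem_gap is not None
            else int(spec.tandem_window * 2 + rng.integers(0, spec.tandem_window))
        )
        start = next_start.get(chrom, int(rng.integers(1, 50_000))) + gap
        end = start + 3 * spec.member_length
        next_start[chrom] = start
        raw = f"{chrom}:{start}-{end}"
        loci[gene_id] = parse_locus(gene_id, raw)
        return start, end

    unit_no = 0

    def add_unit(role, members):
        nonlocal unit_no
        unit_no += 1
        unit = f"U{unit_no}"
        ancestor = _random_protein(rng, spec.member_length)
        for idx, (gene_id, chrom, tandem_gap) in enumerate(members):
            identity = rng.uniform(*spec.identity_within)
            seq = ancestor if idx == 0 else _mutate_to_identity(ancestor, identity, rng)
            start, end = place(gene_id, chrom, tandem_gap)
            seqs[gene_id] = seq
            rows.append(
                {"gene_id": gene_id, "unit": unit, "role": role,
                 "chromosome": chrom, "start": start, "end": end}
            )

    groups = [1 + (i % 7) for i in range(spec.n_triads)]
    for i, g in enumerate(groups):
        add_unit(
            "triad",
            [(f"SYN_T{i + 1}_{s}", f"{g}{s}", None) for s in SUBGENOMES],
        )
    pair_subs = [("A", "D"), ("A", "B"), ("B", "D")]
    for i in range(spec.n_pairs):
        g = 1 + (i % 7)
        sa, sb = pair_subs[i % 3] if i % 3 else ("A", "D")  # A/D most common
        add_unit(
            "pair",
            [(f"SYN_P{i + 1}_{s}", f"{g}{s}", None) for s in (sa, sb)],
        )
    for i in range(spec.n_tandem_clusters):
        g = 1 + (i % 7)
        chrom = f"{g}A"
        members = [
            (
                f"SYN_TD{i + 1}_{j + 1}",
                chrom,
                None if j == 0 else int(rng.integers(5_000, spec.tandem_window // spec.tandem_cluster_size)),
            )
            for j in range(spec.tandem_cluster_size)
        ]
        add_unit("tandem", members)
    for i in range(spec.n_singletons):
        g = 1 + (i % 7)
        s = SUBGENOMES[i % 3]
        add_unit("singleton", [(f"SYN_S{i + 1}", f"{g}{s}", None)])

    return GenomeLayout(seqs, loci, pd.DataFrame(rows))


# --------------------------------------------------------------- expression


def _nb(rng, mean, dispersion, size=None):
    """Overdispersed expression noise with var = dispersion * mean^2.

    This is the continuous (Gamma mixing) component of a negative-binomial
    model, applied to FPKM directly rather than to read counts — FPKM values
    stay continuous, the squared coefficient of variation equals the
    dispersion, and the dispersion -> 0 limit returns the mean exactly.
    """
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size or np.shape(mean))
    if dispersion <= 0:
        return mean.copy()
    out = np.zeros_like(mean)
    pos = mean > 0
    out[pos] = rng.gamma(shape=1.0 / dispersion, scale=mean[pos] * dispersion)
    return out


@dataclass
class SyntheticExpression:
    tissue_matrix: pd.DataFrame  # genes x tissues
    tissue_truth: pd.DataFrame  # gene_id, role, tissue
    stress_matrix: pd.DataFrame  # genes x samples
    stress_samples: pd.DataFrame  # sample, condition, timepoint, replicate
    stress_truth: pd.DataFrame  # gene_id, role


def gen_expression(spec: SyntheticSpec) -> SyntheticExpression:
    """FPKM matrices for the tissue panel and the control/salt time course.

    Tissue design: one FPKM column per organ; planted tissue-specific genes
    are expressed in exactly one organ, silent genes in none.  Stress design:
    control vs treatment at each timepoint with ``n_replicates`` replicates;
    planted effects (up/down at ``effect_log2fc``, stress-specific on/off)
    apply at every timepoint after 0 h.
    """
    rng = _rng(spec, 3)
    n = spec.n_genes_expression
    genes = [f"SYNEXP{i + 1}" for i in range(n)]
    base = rng.lognormal(mean=math.log(spec.nb_mean), sigma=0.8, size=n)

    # role assignment (deterministic order, disjoint)
    roles = {}
    cursor = 0
    t_rows = []
    for tissue, count in zip(spec.tissues, spec.n_tissue_specific):
        for _ in range(count):
            roles[genes[cursor]] = ("tissue_specific", tissue)
            t_rows.append({"gene_id": genes[cursor], "role": "tissue_specific", "tissue": tissue})
            cursor += 1
    for _ in range(spec.n_silent):
        roles[genes[cursor]] = ("silent", None)
        t_rows.append({"gene_id": genes[cursor], "role": "silent", "tissue": None})
        cursor += 1
    s_rows = []
    for role, count in (
        ("up", spec.n_up), ("down", spec.n_down), ("stress_specific", spec.n_stress_specific)
    ):
        for _ in range(count):
            roles.setdefault(genes[cursor], ("background", None))
            s_rows.append({"gene_id": genes[cursor], "role": role})
            cursor += 1
    stress_role = {r["gene_id"]: r["role"] for r in s_rows}

    # tissue panel
    tissue_mean = np.tile(base[:, None], (1, len(spec.tissues)))
    tissue_mean *= rng.lognormal(0.0, 0.3, size=tissue_mean.shape)
    for i, g in enumerate(genes):
        role, tissue = roles.get(g, ("background", None))
        if role == "tissue_specific":
            mask = np.array([t != tissue for t in spec.tissues])
            tissue_mean[i, mask] = 0.0
            tissue_mean[i, ~mask] = max(tissue_mean[i, ~mask][0], 5.0)
        elif role == "silent":
            tissue_mean[i, :] = 0.0
    tissue_matrix = pd.DataFrame(
        _nb(rng, tissue_mean, spec.nb_dispersion, tissue_mean.shape),
        index=genes, columns=spec.tissues,
    )

    # stress time course
    cols, col_means, sheet = [], [], []
    effect = 2.0 ** spec.effect_log2fc
    for cond in ("control", "treatment"):
        for tp in spec.timepoints:
            for rep in range(1, spec.n_replicates + 1):
                name = f"{cond}_t{tp:g}_r{rep}"
                cols.append(name)
                sheet.append(
                    {"sample": name, "condition": cond, "timepoint": tp, "replicate": rep}
                )
                mean = base.copy()
                for i, g in enumerate(genes):
                    r = stress_role.get(g)
                    if r is None or tp == 0:
                        continue
                    if r == "up" and cond == "treatment":
                        mean[i] *= effect
                    elif r == "down" and cond == "treatment":
                        mean[i] /= effect
                    elif r == "stress_specific":
                        mean[i] = 25.0 if cond == "treatment" else 0.05
                col_means.append(mean)
    stress_matrix = pd.DataFrame(
        np.column_stack(
            [_nb(rng, m, spec.nb_dispersion, (n,)) for m in col_means]
        ),
        index=genes, columns=cols,
    )
    return SyntheticExpression(
        tissue_matrix, pd.DataFrame(t_rows), stress_matrix,
        pd.DataFrame(sheet), pd.DataFrame(s_rows),
    )


# ------------------------------------------------------------------ network


def gen_ortholog_network(
    spec: SyntheticSpec, n_family: int = 18, n_edges: int = 509
):
    """An ortholog map plus a model-organism edge list for projection tests.

    Emulates the study's ortholog-projection design: ``n_family`` family
    genes each map to one model-organism ortholog, and ``n_edges`` distinct
    interaction edges are spread over those orthologs (every gene receives at
    least one).  Projecting the edges yields exactly ``n_edges`` pairs over
    ``n_family`` mapped genes.  Returns (ortholog_map, edges) DataFrames.
    """
    rng = _rng(spec, 5)
    ortholog_map = pd.DataFrame(
        {
            "family_gene": [f"SYNFAM{i + 1}" for i in range(n_family)],
            "ortholog": [f"ORTH{i + 1}" for i in range(n_family)],
        }
    )
    owners = list(range(n_family)) + list(
        rng.integers(0, n_family, size=max(0, n_edges - n_family))
    )
    counters = [0] * n_family
    rows = []
    for owner in owners[:n_edges]:
        counters[owner] += 1
        rows.append({"a": f"ORTH{owner + 1}", "b": f"PARTNER{owner + 1}_{counters[owner]}"})
    return ortholog_map, pd.DataFrame(rows)


# --------------------------------------------------------------------- qPCR


def gen_ct(spec: SyntheticSpec):
    """Ct tables whose comparative-Ct analysis recovers planted fold changes.

    For a planted fold f, treatment target wells run log2(f) cycles earlier
    than control wells relative to the reference gene.  Returns (Ct table,
    truth DataFrame with the planted fold per gene).
    """
    rng = _rng(spec, 4)
    rows, truth = [], []
    for i, fold in enumerate(spec.ct_fold_changes):
        gene = f"SYNCT{i + 1}"
        truth.append({"gene_id": gene, "fold": fold})
        for cond in ("control", "treatment"):
            shift = -math.log2(fold) if cond == "treatment" else 0.0
            for rep in range(1, spec.ct_replicates + 1):
                rows.append(
                    {
                        "gene": gene,
                        "condition": cond,
                        "timepoint": 6.0,
                        "replicate": rep,
                        "ct_target": float(
                            rng.normal(spec.ct_target_mean + shift, spec.ct_sd)
                        ),
                        "ct_reference": float(
                            rng.normal(spec.ct_reference_mean, spec.ct_sd)
                        ),
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(truth)
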