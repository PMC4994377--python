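"""Expression-matrix transforms, specificity/stress calling, clustering, qPCR.

Works on FPKM matrices (genes x samples) with a sample sheet giving either a
tissue per sample or a (condition, timepoint, replicate) design.  Stress
responses are called per timepoint with a fold-change cutoff of 2 and
Welch's t-test on log10(FPKM + 1) across replicates, Benjamini-Hochberg
corrected over the gene set (p and q both < 0.05 by default); genes silent
in the control but expressed under treatment are called stress-specific.
qPCR relative expression uses the comparative-Ct method,
2^-ddCt with ddCt = (Ct_target - Ct_ref)_treatment - (Ct_target - Ct_ref)_control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

DEFAULT_EXPRESSED_FPKM = 1.0
DEFAULT_FC_CUTOFF = 2.0
DEFAULT_ALPHA = 0.05
FC_PSEUDO = 0.1  # added to FPKM means before ratios to avoid division by zero


@dataclass(frozen=True)
class TissueCall:
    gene_id: str
    expressed_in: tuple[str, ...]
    tissue_specific: str | None


@dataclass(frozen=True)
class StressCall:
    gene_id: str
    verdict: str  # "up" | "down" | "unchanged" | "specific"
    log2_fc: float
    p: float | None
    q: float | None


def validate_matrix(m: pd.DataFrame) -> pd.DataFrame:
    if (m.to_numpy() < 0).any():
        raise ValueError("FPKM matrix contains negative values")
    if m.columns.duplicated().any():
        raise ValueError("duplicate sample ids")
    return m


def log_transform(m: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log10(FPKM + 1)."""
    validate_matrix(m)
    return np.log10(m + 1.0)


def call_tissue_specific(
    m: pd.DataFrame, expressed_threshold: float = DEFAULT_EXPRESSED_FPKM
) -> list[TissueCall]:
    """Tissue-specific = expressed (FPKM >= threshold) in exactly one tissue.

    Columns are tissues (one expression value per tissue).
    """
    validate_matrix(m)
    calls = []
    for gene, row in m.iterrows():
        expressed = tuple(t for t in m.columns if row[t] >= expressed_threshold)
        calls.append(
            TissueCall(gene, expressed, expressed[0] if len(expressed) == 1 else None)
        )
    return calls


def call_stress_response(
    m: pd.DataFrame,
    samples: pd.DataFrame,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    alpha: float = DEFAULT_ALPHA,
    expressed_threshold: float = DEFAULT_EXPRESSED_FPKM,
) -> list[StressCall]:
    """Per-gene treatment-vs-control verdicts at one timepoint.

    ``samples`` maps sample id -> condition ("treatment"/"control") via
    columns ``sample`` and ``condition``.  With replicates, Welch's t-test on
    log10(FPKM+1) plus BH correction gates up/down calls; without replicates,
    calls are fold-change-only and p/q are None.
    """
    validate_matrix(m)
    cond = samples.set_index("sample")["condition"]
    treat_cols = [c for c in m.columns if cond.get(c) == "treatment"]
    ctrl_cols = [c for c in m.columns if cond.get(c) == "control"]
    if not ctrl_cols:
        raise ValueError("no control samples in the design")
    if not treat_cols:
        raise ValueError("no treatment samples in the design")
    replicated = len(treat_cols) > 1 and len(ctrl_cols) > 1

    treat_mean = m[treat_cols].mean(axis=1)
    ctrl_mean = m[ctrl_cols].mean(axis=1)
    log2_fc = np.log2((treat_mean + FC_PSEUDO) / (ctrl_mean + FC_PSEUDO))

    if replicated:
        logm = log_transform(m)
        pvals = np.array(
            [
                _welch_p(logm.loc[g, treat_cols], logm.loc[g, ctrl_cols])
                for g in m.index
            ]
        )
        qvals = multipletests(pvals, method="fdr_bh")[1]
    else:
        pvals = qvals = None

    calls = []
    log2_cut = np.log2(fc_cutoff)
    for i, gene in enumerate(m.index):
        fc = float(log2_fc.loc[gene])
        p = float(pvals[i]) if pvals is not None else None
        q = float(qvals[i]) if qvals is not None else None
        significant = (p < alpha and q < alpha) if replicated else True
        if (
            ctrl_mean.loc[gene] < expressed_threshold
            and treat_mean.loc[gene] >= expressed_threshold
            and fc >= log2_cut
            and significant
        ):
            verdict = "specific"
        elif fc >= log2_cut and significant:
            verdict = "up"
        elif fc <= -log2_cut and significant:
            verdict = "down"
        else:
            verdict = "unchanged"
        calls.append(StressCall(gene, verdict, fc, p, q))
    return calls


def _welch_p(x, y) -> float:
    import warnings

    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if np.allclose(x.var(), 0) and np.allclose(y.var(), 0):
        return 1.0 if np.isclose(x.mean(), y.mean()) else 0.0
    with warnings.catch_warnings():
        # near-constant replicate triplets trip scipy's precision warning
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(stats.ttest_ind(x, y, equal_var=False).pvalue)


def call_stress_timecourse(
    m: pd.DataFrame, samples: pd.DataFrame, **kwargs
) -> dict[float, list[StressCall]]:
    """Run :func:`call_stress_response` separately at each timepoint."""
    out = {}
    for tp, sheet in samples.groupby("timepoint"):
        cols = [c for c in sheet["sample"] if c in m.columns]
        out[tp] = call_stress_response(m[cols], sheet, **kwargs)
    return out


def hierarchical_cluster(m: pd.DataFrame):
    """Average-linkage clustering of genes on Euclidean distance of
    log10(FPKM+1) rows; returns (linkage matrix, ordered gene ids).

    Rows are sorted by gene id first so equal-distance merges are resolved
    deterministically.
    """
    if len(m) < 2:
        raise ValueError("need at least 2 genes to cluster")
    m = log_transform(m).sort_index()
    z = hierarchy.linkage(pdist(m.to_numpy()), method="average")
    order = hierarchy.leaves_list(z)
    return z, [m.index[i] for i in order]


@dataclass(frozen=True)
class RelativeExpression:
    gene_id: str
    timepoint: float
    ddct: float
    fold: float  # 2 ** -ddct
    sd_ddct: float


REQUIRED_CT_COLUMNS = ["gene", "condition", "timepoint", "replicate", "ct_target", "ct_reference"]


def ddct(table: pd.DataFrame) -> list[RelativeExpression]:
    """Comparative-Ct relative quantification per gene and timepoint.

    dCt = Ct_target - Ct_reference per well; ddCt = mean dCt(treatment) -
    mean dCt(control) over replicates; relative expression = 2^-ddCt.
    Replicate SDs are propagated in quadrature.  Raises when a gene/timepoint
    lacks either condition.
    """
    missing = [c for c in REQUIRED_CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    bad = table[(table["ct_target"] < 0) | (table["ct_target"] > 45)
                | (table["ct_reference"] < 0) | (table["ct_reference"] > 45)]
    if len(bad):
        raise ValueError("Ct values outside the plausible 0-45 cycle range")
    out = []
    for (gene, tp), grp in table.groupby(["gene", "timepoint"], sort=True):
        dct = grp["ct_target"] - grp["ct_reference"]
        by_cond = {c: dct[grp["condition"] == c] for c in ("treatment", "control")}
        for c, vals in by_cond.items():
            if vals.empty:
                raise ValueError(f"{gene} @ {tp}: missing {c} rows")
        dd = float(by_cond["treatment"].mean() - by_cond["control"].mean())
        sd = float(
            np.sqrt(
                by_cond["treatment"].std(ddof=1) ** 2
                + by_cond["control"].std(ddof=1) ** 2
            )
        ) if min(len(v) for v in by_cond.values()) > 1 else float("nan")
        out.append(RelativeExpression(gene, tp, dd, 2.0 ** (-dd), sd))
    return out
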