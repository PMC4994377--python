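"""Position-specific scoring surrogate for a profile-based candidate screen.

Large-scale kinase-family screens are usually run with BLASTP plus a profile
HMM built from seed alignments.  At desk scale this module replaces that
stage with an ungapped position-specific scoring matrix (PSSM): per-column
log-odds of residue frequency over background, scanned as a sliding window,
combined with a global-alignment identity filter against the seed set
(default 50 % identity over aligned non-gap columns).  Score thresholds are
calibrated empirically on a decoy null (e.g. the 99th percentile of best
window scores over shuffled or random sequences) rather than via E-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import align_dup

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_INDEX = {a: i for i, a in enumerate(ALPHABET)}


@dataclass
class ProfileModel:
    log_odds: np.ndarray  # (length, 20) bits
    background: np.ndarray  # (20,) frequencies summing to 1
    pseudocount: float
    kept_columns: list[int]  # indices of alignment columns retained

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]


@dataclass(frozen=True)
class ScreenHit:
    protein_id: str
    best_window_score: float
    best_window_start: int
    percent_identity_to_best_seed: float
    best_seed_id: str
    passes: bool
    short: bool = False


def uniform_background() -> np.ndarray:
    return np.full(len(ALPHABET), 1.0 / len(ALPHABET))


def build_profile(
    seed_ids: list[str],
    seed_rows: list[str],
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    max_gap_fraction: float = 0.5,
) -> ProfileModel:
    """Per-column log2 odds from an aligned seed set.

    Columns with more than ``max_gap_fraction`` gaps are dropped.  With
    background b and per-column residue counts c over n non-gap rows,

        score(r) = log2( ((c_r + pseudocount * b_r) / (n + pseudocount)) / b_r )
    """
    if len(seed_rows) < 2:
        raise ValueError("need at least 2 aligned seed sequences")
    if len(set(map(len, seed_rows))) != 1:
        raise ValueError("seed alignment rows have unequal lengths")
    if background is None:
        background = uniform_background()
    background = np.asarray(background, dtype=float)
    if abs(background.sum() - 1.0) > 1e-9:
        raise ValueError("background frequencies must sum to 1")
    rows = [r.upper() for r in seed_rows]
    ncols = len(rows[0])
    kept, scores = [], []
    for col in range(ncols):
        column = [r[col] for r in rows]
        gaps = sum(c == "-" for c in column)
        if gaps / len(column) > max_gap_fraction:
            continue
        residues = [c for c in column if c in _INDEX]
        n = len(residues)
        counts = np.zeros(len(ALPHABET))
        for c in residues:
            counts[_INDEX[c]] += 1
        freq = (counts + pseudocount * background) / (n + pseudocount)
        scores.append(np.log2(freq / background))
        kept.append(col)
    return ProfileModel(np.array(scores), background, pseudocount, kept)


def score_window(model: ProfileModel, seq: str, start: int) -> float:
    """Sum of column scores for the window at ``start``; residues outside the
    sequence or outside the 20-letter alphabet are skipped."""
    total = 0.0
    for col in range(model.length):
        pos = start + col
        if 0 <= pos < len(seq):
            idx = _INDEX.get(seq[pos])
            if idx is not None:
                total += model.log_odds[col, idx]
    return total


def best_window(model: ProfileModel, seq: str) -> tuple[float, int]:
    seq = seq.upper()
    n_offsets = max(1, len(seq) - model.length + 1)
    best_s, best_i = -math.inf, 0
    for off in range(n_offsets):
        s = score_window(model, seq, off)
        if s > best_s:
            best_s, best_i = s, off
    return best_s, best_i


def screen(
    candidates: dict[str, str],
    model: ProfileModel,
    seeds: dict[str, str],
    score_threshold: float,
    identity_threshold: float = 50.0,
) -> list[ScreenHit]:
    """One hit per candidate: best ungapped window score plus the best global
    alignment identity against any (ungapped) seed sequence."""
    if not candidates:
        raise ValueError("no candidate sequences")
    seed_seqs = {sid: s.replace("-", "") for sid, s in seeds.items()}
    hits = []
    for cid in sorted(candidates):
        seq = candidates[cid]
        score, start = best_window(model, seq)
        best_pid, best_sid = -1.0, ""
        for sid in sorted(seed_seqs):
            res = align_dup.global_align(seq, seed_seqs[sid], id_a=cid, id_b=sid)
            if res.identity_pct > best_pid:
                best_pid, best_sid = res.identity_pct, sid
        hits.append(
            ScreenHit(
                protein_id=cid,
                best_window_score=score,
                best_window_start=start,
                percent_identity_to_best_seed=best_pid,
                best_seed_id=best_sid,
                passes=score >= score_threshold and best_pid >= identity_threshold,
                short=len(seq) < model.length,
            )
        )
    return hits


def calibrate_score_threshold(
    model: ProfileModel, decoys: list[str], quantile: float = 0.99
) -> float:
    """Score threshold as a quantile of the decoy best-window null."""
    if not decoys:
        raise ValueError("no decoy sequences for calibration")
    null = [best_window(model, d)[0] for d in decoys]
    return float(np.quantile(null, quantile))
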