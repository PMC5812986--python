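"""Running-sum DMR caller.

The genome is traversed CpG by CpG and a local score accumulates
log2(f_i / mean f) minus a per-bp separation penalty for the gap to the
previous CpG, clipped below at zero:

    s_i = max(0, s_{i-1} + log2(f_i / mean_f) - penalty * (d_i - d_{i-1}))

A differentially methylated region is emitted whenever the score drops
back to zero after having been positive (or at a chromosome end while
positive), and spans its first CpG up to the CpG attaining the maximal
score.  The score restarts at zero across chromosome boundaries; the
first CpG of a chromosome carries no gap term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
import pandas as pd

from .methylation import FStatTrack

#: log-ratio assigned to sites with f == 0 (forces the score to zero)
NEG_CLAMP = -1e9


@dataclass
class ScoreTrack:
    """Per-CpG running scores over an f-statistic track."""

    chrom: np.ndarray
    pos: np.ndarray
    f: np.ndarray
    logratio: np.ndarray
    s: np.ndarray
    penalty: float
    mean_f: float

    def __len__(self) -> int:
        return len(self.s)


@dataclass
class DMR:
    """A called region: first CpG of the positive run to its score peak."""

    chrom: str
    start_pos: int
    peak_pos: int
    score: float
    n_cpgs: int
    #: last positive-score CpG after the peak, kept for inspection only
    tail_end_pos: int = None

    def __post_init__(self) -> None:
        if self.tail_end_pos is None:
            self.tail_end_pos = self.peak_pos


def compute_score_track(track: FStatTrack, penalty: float = 0.02) -> ScoreTrack:
    """Apply the running-sum recursion left-to-right per chromosome.

    ``mean_f`` is the track's genome-wide mean of finite f values and
    must be positive.  Sites with f == 0 contribute a clamped log-ratio
    (NEG_CLAMP), resetting the score; capped-infinite f values enter the
    log-ratio at their capped magnitude.
    """
    if len(track) == 0:
        raise ValueError("empty f-statistic track")
    if not track.mean_f > 0:
        raise ValueError("mean_f must be positive to form log-ratios")
    chrom = np.asarray(track.chrom)
    pos = np.asarray(track.pos, dtype=np.int64)
    f = np.asarray(track.f, dtype=float)
    for c in pd.unique(chrom):
        if np.any(np.diff(pos[chrom == c]) <= 0):
            raise ValueError(f"positions not sorted on {c}")
    with np.errstate(divide="ignore"):
        lr = np.where(f > 0, np.log2(np.maximum(f, 1e-300) / track.mean_f), NEG_CLAMP)
    s = np.empty(len(f))
    prev_chrom = None
    for i in range(len(f)):
        if chrom[i] != prev_chrom:
            s[i] = max(0.0, lr[i])  # no gap term at a chromosome start
            prev_chrom = chrom[i]
        else:
            gap = pos[i] - pos[i - 1]
            s[i] = max(0.0, s[i - 1] + lr[i] - penalty * gap)
    return ScoreTrack(chrom=chrom, pos=pos, f=f, logratio=lr, s=s,
                      penalty=penalty, mean_f=track.mean_f)


def call_dmrs(score: ScoreTrack) -> List[DMR]:
    """Emit a DMR for every positive run of the score track.

    A run opens at the first CpG with s > 0 following a zero (or a
    chromosome start) and closes when s returns to 0 or the chromosome
    ends.  The region spans the opening CpG through the argmax CpG; its
    score is the maximal s in the run.  Runs never cross chromosomes.
    """
    out: List[DMR] = []
    n = len(score)
    run_start = None
    peak_idx = None
    peak_val = 0.0
    prev_chrom = None

    def flush(last_positive: int) -> None:
        nonlocal run_start, peak_idx, peak_val
        if run_start is not None:
            out.append(
                DMR(
                    chrom=str(score.chrom[run_start]),
                    start_pos=int(score.pos[run_start]),
                    peak_pos=int(score.pos[peak_idx]),
                    score=float(peak_val),
                    n_cpgs=int(peak_idx - run_start + 1),
                    tail_end_pos=int(score.pos[last_positive]),
                )
            )
        run_start, peak_idx, peak_val = None, None, 0.0

    for i in range(n):
        if score.chrom[i] != prev_chrom:
            flush(i - 1)
            prev_chrom = score.chrom[i]
        si = score.s[i]
        if si > 0:
            if run_start is None:
                run_start = i
                peak_idx, peak_val = i, si
            elif si > peak_val:
                peak_idx, peak_val = i, si
        else:
            flush(i - 1)
    flush(n - 1)
    return out


def dmrs_to_frame(dmrs: List[DMR]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start_pos": r.start_pos,
                "peak_pos": r.peak_pos,
                "score": r.score,
                "n_cpgs": r.n_cpgs,
                "tail_end_pos": r.tail_end_pos,
            }
            for r in dmrs
        ],
        columns=["chrom", "start_pos", "peak_pos", "score", "n_cpgs", "tail_end_pos"],
    )
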