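"""Sliding-window genotype correction for RIL call tracks.

Resequencing-derived RIL genotypes carry isolated miscalls that would
otherwise split bins.  Each SNP call is replaced by the majority call of a
window of W consecutive SNPs centred on it (default 15): if at least T calls
in the window are AA the position becomes AA, else likewise for BB (default
T = 11), else the heterozygous code AB is used to fill and correct the
position.  Missing calls inside the window are ignored for counting; missing
focal calls are filled by the same rule.  Every window is evaluated against
the original track, so corrections never cascade within a pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AA, AB, BB, CODE_TO_LABEL, SnpCallMatrix


@dataclass(frozen=True)
class WindowRule:
    """Window of ``window_size`` SNPs with homozygote majority threshold
    ``majority_threshold`` (the 15 / 11 rule by default)."""

    window_size: int = 15
    majority_threshold: int = 11

    def __post_init__(self) -> None:
        if not 1 <= self.majority_threshold <= self.window_size:
            raise ValueError("need 1 <= majority_threshold <= window_size")


def _window_sums(ind: np.ndarray, left: int, right: int) -> np.ndarray:
    """Per-position windowed column sums of a (m x n) 0/1 indicator, window
    [i - left, i + right] truncated at the track ends."""
    m = ind.shape[0]
    cum = np.vstack([np.zeros((1, ind.shape[1]), dtype=np.int32), np.cumsum(ind, axis=0)])
    hi = np.minimum(np.arange(m) + right + 1, m)
    lo = np.maximum(np.arange(m) - left, 0)
    return cum[hi] - cum[lo]


def slide_correct(calls: SnpCallMatrix, rule: WindowRule = WindowRule()) -> SnpCallMatrix:
    """Apply the window-majority rule to every individual and chromosome.

    Boundary windows are truncated and the threshold is scaled
    proportionally: T' = ceil(T * w / W) for a truncated window of w SNPs.
    The input matrix is left unmodified.
    """
    if calls.population != "ril":
        raise ValueError("sliding-window correction applies to RIL matrices only")
    W, T = rule.window_size, rule.majority_threshold
    left = (W - 1) // 2
    right = W - 1 - left
    out = calls.copy()
    for c in calls.chromosomes:
        idx = calls.chrom_index(c)
        block = calls.calls[idx]
        m = block.shape[0]
        n_aa = _window_sums((block == AA).astype(np.int32), left, right)
        n_bb = _window_sums((block == BB).astype(np.int32), left, right)
        width = np.minimum(np.arange(m) + right + 1, m) - np.maximum(np.arange(m) - left, 0)
        t_eff = np.ceil(T * width / W).astype(np.int32)[:, None]
        corrected = np.where(
            n_aa >= t_eff, AA, np.where(n_bb >= t_eff, BB, AB)
        ).astype(np.int8)
        out.calls[idx] = corrected
    return out


def correction_report(before: SnpCallMatrix, after: SnpCallMatrix) -> pd.DataFrame:
    """Per-individual, per-chromosome counts of changed calls by transition
    type (e.g. ``AA->AB``).  Rows with zero changes are omitted."""
    if before.calls.shape != after.calls.shape or not np.array_equal(before.pos, after.pos):
        raise ValueError("matrices must share shape and marker index")
    rows = []
    for c in before.chromosomes:
        idx = before.chrom_index(c)
        b, a = before.calls[idx], after.calls[idx]
        changed = b != a
        if not changed.any():
            continue
        mi, ii = np.nonzero(changed)
        frm = np.vectorize(CODE_TO_LABEL.get)(b[mi, ii])
        to = np.vectorize(CODE_TO_LABEL.get)(a[mi, ii])
        df = pd.DataFrame(
            {
                "chrom": c,
                "individual": np.asarray(before.samples, dtype=object)[ii],
                "transition": np.char.add(np.char.add(frm.astype(str), "->"), to.astype(str)),
            }
        )
        rows.append(df)
    if not rows:
        return pd.DataFrame(columns=["chrom", "individual", "transition", "count"])
    table = (
        pd.concat(rows, ignore_index=True)
        .groupby(["chrom", "individual", "transition"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return table


def correct_until_stable(
    calls: SnpCallMatrix, rule: WindowRule = WindowRule(), max_passes: int = 3
) -> tuple[SnpCallMatrix, int, bool]:
    """Repeat :func:`slide_correct` until the matrix stabilizes.

    Returns (matrix, passes applied, converged flag).  On realistic RIL data
    the rule stabilizes within a few passes; the flag reports if it did not
    within ``max_passes``.
    """
    current = calls
    for k in range(1, max_passes + 1):
        nxt = slide_correct(current, rule)
        if np.array_equal(nxt.calls, current.calls):
            return nxt, k, True
        current = nxt
    return current, max_passes, False
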