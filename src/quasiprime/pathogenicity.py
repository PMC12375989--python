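"""Pathogenicity-score overlap between quasi-prime loci and the rest of a protein.

Per-residue missense pathogenicity scores (AlphaMissense-style, in [0, 1]) are
partitioned into variants falling inside any quasi-prime hit interval and
variants elsewhere in the same proteins. The two samples are compared with the
two-sample Kolmogorov–Smirnov statistic and Cliff's delta, plus class
fractions (benign: score < 0.1; pathogenic: score > 0.9) and the fold
enrichment of pathogenic variants inside vs. outside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io import PathogenicityRow
from .matching import PeptideHit

__all__ = ["OverlapReport", "partition_scores", "cliffs_delta",
           "ks_statistic", "overlap_report",
           "BENIGN_THRESHOLD", "PATHOGENIC_THRESHOLD"]

BENIGN_THRESHOLD = 0.1      # strict: score < 0.1 is likely benign
PATHOGENIC_THRESHOLD = 0.9  # strict: score > 0.9 is highly pathogenic


@dataclass(frozen=True)
class OverlapReport:
    n_inside: int
    n_outside: int
    ks_stat: float
    ks_p: float
    cliffs_delta: float
    frac_pathogenic_inside: float
    frac_pathogenic_outside: float
    frac_benign_inside: float
    frac_benign_outside: float
    fold_pathogenic: float  # NaN when the outside pathogenic fraction is zero


def partition_scores(
    rows: Iterable[PathogenicityRow],
    hits: Iterable[PeptideHit],
) -> tuple[list[float], list[float]]:
    """Split scores into inside-locus and outside-locus samples.

    A row is inside iff its position falls within any hit interval
    [start, end] of the same protein. Rows of proteins with no hit at all are
    excluded: the comparison is within hit-containing proteins only.
    """
    intervals: dict[str, list[tuple[int, int]]] = {}
    for hit in hits:
        intervals.setdefault(hit.protein_id, []).append((hit.start, hit.end))
    inside: list[float] = []
    outside: list[float] = []
    for row in rows:
        spans = intervals.get(row.protein_id)
        if spans is None:
            continue
        if any(start <= row.position <= end for start, end in spans):
            inside.append(row.score)
        else:
            outside.append(row.score)
    return inside, outside


def cliffs_delta(x: Sequence[float], y: Sequence[float]) -> float:
    """Cliff's delta: (#{x_i > y_j} − #{x_i < y_j}) / (|x|·|y|), in [−1, 1]."""
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    xs = np.asarray(x, dtype=float)
    ys = np.sort(np.asarray(y, dtype=float))
    # counts via binary search rather than the O(n·m) pairwise comparison
    greater = np.searchsorted(ys, xs, side="left").sum()   # y_j <  x_i
    not_less = np.searchsorted(ys, xs, side="right").sum()  # y_j <= x_i
    less = xs.size * ys.size - not_less                     # y_j >  x_i
    return float((greater - less) / (xs.size * ys.size))


def ks_statistic(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample KS statistic (sup-norm CDF distance) and asymptotic p-value."""
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    result = stats.ks_2samp(x, y, method="asymp")
    return float(result.statistic), float(result.pvalue)


def _class_fractions(scores: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(scores, dtype=float)
    return (float((arr > PATHOGENIC_THRESHOLD).mean()),
            float((arr < BENIGN_THRESHOLD).mean()))


def overlap_report(inside: Sequence[float], outside: Sequence[float]) -> OverlapReport:
    """Full comparison of the inside- vs outside-locus score distributions."""
    if len(inside) == 0 or len(outside) == 0:
        raise ValueError(
            "both partitions must be non-empty; provide more scored variants "
            "overlapping quasi-prime-containing proteins")
    ks, ks_p = ks_statistic(inside, outside)
    path_in, benign_in = _class_fractions(inside)
    path_out, benign_out = _class_fractions(outside)
    fold = path_in / path_out if path_out > 0 else math.nan
    return OverlapReport(
        n_inside=len(inside), n_outside=len(outside),
        ks_stat=ks, ks_p=ks_p,
        cliffs_delta=cliffs_delta(inside, outside),
        frac_pathogenic_inside=path_in, frac_pathogenic_outside=path_out,
        frac_benign_inside=benign_in, frac_benign_outside=benign_out,
        fold_pathogenic=fold)
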