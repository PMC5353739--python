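"""RPKM normalization and developmental transcription-trend classification.

RPKM = C / ((L/1000) * (N/1e6)) for C reads mapped to a gene model of length
L bp in a library of N mapped reads.
"""
from __future__ import annotations

from .errors import InputError

TREND_UP = "upregulated"
TREND_FLAT = "flat"
TREND_OTHER = "other"


def rpkm(C: float, L: float, N: float) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if L <= 0:
        raise InputError("gene length L must be > 0")
    if N <= 0:
        raise InputError("library size N must be > 0")
    if not 0 <= C <= N:
        raise InputError("read count C must satisfy 0 <= C <= N")
    return C / ((L / 1000.0) * (N / 1_000_000.0))


def trend_class(
    series: list[tuple[float, float]],
    fold_min: float = 2.0,
    tol: float = 0.2,
) -> str:
    """Classify a (timepoint, rpkm) series as upregulated / flat / other.

    upregulated: last/first >= fold_min and the series is non-decreasing
    within a tolerated dip of ``tol`` (each value >= (1-tol) x running max);
    flat: max/min < fold_min; otherwise other.
    """
    if len(series) < 2:
        raise InputError("trend_class needs at least two timepoints")
    times = [t for t, _ in series]
    if times != sorted(times):
        raise InputError("series must be sorted by timepoint")
    values = [v for _, v in series]
    if any(v < 0 for v in values):
        raise InputError("rpkm values must be >= 0")
    first, last = values[0], values[-1]
    vmax, vmin = max(values), min(values)
    fold_up = float("inf") if first == 0 and last > 0 else (last / first if first else 1.0)
    running_max = values[0]
    monotone = True
    for v in values[1:]:
        if v < (1.0 - tol) * running_max:
            monotone = False
        running_max = max(running_max, v)
    if fold_up >= fold_min and monotone:
        return TREND_UP
    spread = float("inf") if vmin == 0 and vmax > 0 else (vmax / vmin if vmin else 1.0)
    if spread < fold_min:
        return TREND_FLAT
    return TREND_OTHER
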