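"""Independent brute-force oracles used to validate the implementation.

These deliberately re-derive each quantity from first principles (exhaustive
scans, naive DP) and share no code with the package internals.
"""
from __future__ import annotations

STOPS = {"TAA", "TAG", "TGA"}

CODON_TABLE = {}


def _codon_table():
    global CODON_TABLE
    if not CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        CODON_TABLE = dict(standard_dna_table.forward_table)
    return CODON_TABLE


def orf_scan(seq: str, min_aa: int) -> list[tuple[int, tuple[int, int], str]]:
    """Every ATG in every forward frame, walked codon by codon to its stop."""
    table = _codon_table()
    out = []
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        protein = []
        j = i
        complete = False
        while j + 3 <= len(seq):
            codon = seq[j : j + 3]
            if codon in STOPS:
                complete = True
                break
            if codon not in table:
                break
            protein.append(table[codon])
            j += 3
        if complete and len(protein) >= min_aa:
            out.append((i % 3, (i + 1, j + 3), "".join(protein)))
    out.sort(key=lambda t: (-len(t[2]), t[1][0]))
    return out


def epitope_scan(seq: str, cores: dict[str, str]) -> set[tuple[str, int]]:
    """Position-by-position comparison: {(name, 1-based start), ...}."""
    hits = set()
    for name, core in cores.items():
        for i in range(len(seq) - len(core) + 1):
            if all(seq[i + k] == core[k] for k in range(len(core))):
                hits.add((name, i + 1))
    return hits


def chymotrypsin_sites(seq: str) -> set[int]:
    return {
        i + 1
        for i in range(len(seq) - 1)
        if seq[i] in "FYWL" and seq[i + 1] != "P"
    }


def thermolysin_sites(seq: str) -> set[int]:
    return {i for i in range(1, len(seq)) if seq[i] in "AFILMV"}


def digest_fragments(
    seq: str,
    sites: set[int],
    max_missed: int,
    mass_of,
    mass_min: float,
    mass_max: float,
    min_len: int,
) -> set[str]:
    """All contiguous fragments whose boundaries are cut sites or termini and
    whose internal cut sites number <= max_missed, after filters."""
    bounds = sorted({0, len(seq)} | sites)
    out = set()
    for i in bounds:
        for j in bounds:
            if j <= i:
                continue
            internal = sum(1 for s in sites if i < s < j)
            if internal > max_missed:
                continue
            frag = seq[i:j]
            if len(frag) < min_len:
                continue
            m = mass_of(frag)
            if mass_min <= m <= mass_max:
                out.add(frag)
    return out


def nw_identity(a: str, b: str) -> float:
    """Percent identity by an independent plain-Python global DP with the same
    scoring convention (match 10, mismatch 0, gap -9 on the x10 integer scale)
    and diag>up>left traceback, trimming terminal-gap columns."""
    if a == b:
        return 100.0
    if b < a:
        a, b = b, a
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        H[0][j] = -9 * j
    for i in range(1, n + 1):
        H[i][0] = -9 * i
        row, prev = H[i], H[i - 1]
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = 10 if ai == b[j - 1] else 0
            row[j] = max(prev[j - 1] + s, prev[j] - 9, row[j - 1] - 9)
    i, j = n, m
    cols = []
    while i > 0 or j > 0:
        if i > 0 and j > 0 and H[i][j] == H[i - 1][j - 1] + (10 if a[i - 1] == b[j - 1] else 0):
            cols.append((a[i - 1], b[j - 1]))
            i, j = i - 1, j - 1
        elif i > 0 and H[i][j] == H[i - 1][j] - 9:
            cols.append((a[i - 1], None))
            i -= 1
        else:
            cols.append((None, b[j - 1]))
            j -= 1
    cols.reverse()
    lo, hi = 0, len(cols)
    while lo < hi and (cols[lo][0] is None or cols[lo][1] is None):
        lo += 1
    while hi > lo and (cols[hi - 1][0] is None or cols[hi - 1][1] is None):
        hi -= 1
    trimmed = cols[lo:hi]
    if not trimmed:
        return 0.0
    ident = sum(1 for x, y in trimmed if x is not None and x == y)
    return 100.0 * ident / len(trimmed)
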