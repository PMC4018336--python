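"""Independent brute-force oracle for Nei–Gojobori counting.

Deliberately avoids the package's code table and counting routines:
translation goes through Biopython, site and pathway enumeration are written
from the definitions, and the Jukes–Cantor correction uses math.log
directly. Used to cross-check codon_sites, codon_diffs and pairwise_ng86.
"""

from __future__ import annotations

import itertools
import math

from Bio.Seq import Seq

BASES = "ACGT"


def aa(codon: str) -> str:
    return str(Seq(codon).translate())


def is_stop(codon: str) -> bool:
    return aa(codon) == "*"


def oracle_sites(codon: str):
    """(S, N): each of the 9 single-base changes contributes 1/3 site;
    changes creating stops contribute nothing."""
    if is_stop(codon):
        return None
    ref = aa(codon)
    s = n = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if is_stop(mut):
                continue
            if aa(mut) == ref:
                s += 1 / 3
            else:
                n += 1 / 3
    return s, n


def oracle_diffs(c1: str, c2: str):
    """Pathway-averaged (Sd, Nd); stop-passing pathways excluded with an
    all-pathways fallback."""
    if is_stop(c1) or is_stop(c2):
        return None
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0

    def walk(order, skip_stops):
        sd = nd = 0
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if skip_stops and is_stop(nxt):
                return None
            if aa(nxt) == aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    paths = [p for order in itertools.permutations(positions)
             if (p := walk(order, True)) is not None]
    if not paths:
        paths = [walk(order, False) for order in itertools.permutations(positions)]
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def oracle_pairwise(row1: str, row2: str):
    """Full NG86 Ka/Ks for two gap-free coding rows; None where undefined."""
    assert len(row1) == len(row2) and len(row1) % 3 == 0
    S = N = Sd = Nd = 0.0
    used = 0
    for i in range(0, len(row1), 3):
        a, b = row1[i : i + 3], row2[i : i + 3]
        if any(ch not in BASES for ch in a + b) or is_stop(a) or is_stop(b):
            continue
        sa = oracle_sites(a)
        sb = oracle_sites(b)
        S += (sa[0] + sb[0]) / 2
        N += (sa[1] + sb[1]) / 2
        d = oracle_diffs(a, b)
        Sd += d[0]
        Nd += d[1]
        used += 1
    if used == 0 or S <= 0 or N <= 0:
        return None
    pS, pN = Sd / S, Nd / N
    if pS >= 0.75 or pN >= 0.75:
        return None
    ks = -0.75 * math.log(1 - 4 * pS / 3)
    ka = -0.75 * math.log(1 - 4 * pN / 3)
    return ka, ks
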