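"""Nei–Gojobori (1986) Ka/Ks and sliding-window selection scans.

Implements the classic counting estimator: fractional synonymous (S) and
nonsynonymous (N) site counts per codon, pathway-averaged synonymous /
nonsynonymous difference counts (Sd, Nd) per codon pair, proportions
pS = Sd/S and pN = Nd/N over the compared codons, and the Jukes–Cantor
multiple-hit correction d = -(3/4)·ln(1 - (4/3)·p) for each. Ka/Ks > 1
indicates positive selection, < 1 purifying selection.

On top of the pairwise estimator sits a sliding-window profile (default 10
amino-acid columns, step 5) of mean pairwise identity and average pairwise
Ka/Ks, and a directional bootstrap test of the window average against 1:
sequences are resampled with replacement, the window average is recomputed
per replicate, a normal distribution is fitted to the replicates, and a
one-sided p-value is read from the fitted normal on the side of 1 opposite
the observed direction.

Stop-codon conventions (the method's common ones): single-base changes that
create a stop codon are excluded from the site counts — each of the 9
possible changes contributes 1/3 of a site to S or N, so S + N falls short
of 3 by the stop-neighbor fraction — and substitution pathways passing
through a stop are dropped from the pathway average (all pathways are kept
if every one hits a stop).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .genetics import BASES, GENETIC_CODE, SENSE_CODONS, is_stop, is_unambiguous, translate_codon
from .repertoire import PrecursorPartition


# ---------------------------------------------------------------------------
# Site and difference counting
# ---------------------------------------------------------------------------

def _enumerate_sites(codon: str) -> tuple[float, float]:
    # Stop-creating changes are excluded from both numerators, so
    # S + N = 3 - (stop-neighbor fraction) for stop-adjacent codons.
    aa = GENETIC_CODE[codon]
    s = n = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if is_stop(mutant):
                continue
            if GENETIC_CODE[mutant] == aa:
                s += 1.0 / 3.0
            else:
                n += 1.0 / 3.0
    return s, n


#: Fractional (S, N) site counts for every sense codon.
_SITE_TABLE: dict[str, tuple[float, float]] = {c: _enumerate_sites(c) for c in SENSE_CODONS}


def codon_sites(codon: str) -> Optional[tuple[float, float]]:
    """Fractional synonymous/nonsynonymous site counts (S, N) of a codon.

    Returns None (undefined) for stop codons and codons with gaps or
    ambiguity codes.
    """
    codon = codon.upper().replace("U", "T")
    return _SITE_TABLE.get(codon)


def _pathway_steps(c1: str, c2: str, order: tuple[int, ...]) -> Optional[tuple[float, float]]:
    """(syn, nonsyn) step counts along one mutational pathway, or None if the
    pathway passes through a stop codon."""
    sd = nd = 0
    cur = c1
    for pos in order:
        nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
        if is_stop(nxt):
            return None
        if translate_codon(nxt) == translate_codon(cur):
            sd += 1
        else:
            nd += 1
        cur = nxt
    return sd, nd


_DIFF_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def codon_diffs(c1: str, c2: str) -> Optional[tuple[float, float]]:
    """Pathway-averaged (Sd, Nd) difference counts between two sense codons.

    All k! single-step pathways between the k differing positions are
    enumerated; pathways through stop codons are excluded (with a fallback to
    all pathways when every one is excluded). Sd + Nd equals the number of
    differing positions. Returns None for stop/ambiguous codons.
    """
    c1 = c1.upper().replace("U", "T")
    c2 = c2.upper().replace("U", "T")
    if not (is_unambiguous(c1) and is_unambiguous(c2)) or is_stop(c1) or is_stop(c2):
        return None
    if c1 == c2:
        return 0.0, 0.0
    key = (c1, c2) if c1 < c2 else (c2, c1)
    cached = _DIFF_CACHE.get(key)
    if cached is not None:
        return cached
    diff_pos = tuple(i for i in range(3) if c1[i] != c2[i])
    paths = [
        p for order in itertools.permutations(diff_pos)
        if (p := _pathway_steps(c1, c2, order)) is not None
    ]
    if not paths:  # every pathway hits a stop: fall back to all of them
        paths = []
        for order in itertools.permutations(diff_pos):
            sd = nd = 0
            cur = c1
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if translate_codon(nxt) == translate_codon(cur):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    _DIFF_CACHE[key] = (sd, nd)
    return sd, nd


def jukes_cantor(p: float) -> Optional[float]:
    """JC69 multiple-hit correction; None where the formula diverges (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# Pairwise rates
# ---------------------------------------------------------------------------

@dataclass
class PairwiseRates:
    """NG86 estimates for one sequence pair (over some codon span)."""

    Ka: float = float("nan")
    Ks: float = float("nan")
    S: float = 0.0
    N: float = 0.0
    Sd: float = 0.0
    Nd: float = 0.0
    n_codons: int = 0
    defined: bool = False
    reason: str = ""

    @property
    def ratio(self) -> float:
        """Ka/Ks; nan when undefined or Ks == 0."""
        if not self.defined or self.Ks <= 0.0:
            return float("nan")
        return self.Ka / self.Ks


def _codon_ok(codon: str) -> bool:
    return is_unambiguous(codon) and not is_stop(codon)


def pairwise_ng86(
    row1: str,
    row2: str,
    columns: Optional[tuple[int, int]] = None,
) -> PairwiseRates:
    """NG86 Ka/Ks between two aligned coding rows.

    ``columns`` is a 1-based inclusive amino-acid column span (the whole
    alignment when omitted). Codons with a gap, ambiguity code or stop in
    either row are skipped (pairwise deletion). The result is symmetric in
    its arguments.
    """
    if len(row1) != len(row2):
        raise ValueError("aligned rows differ in length")
    n_cols = len(row1) // 3
    lo, hi = columns if columns is not None else (1, n_cols)
    if not (1 <= lo <= hi <= n_cols):
        raise ValueError(f"span {lo}-{hi} outside alignment of {n_cols} codon columns")

    S = N = Sd = Nd = 0.0
    used = 0
    for c in range(lo - 1, hi):
        c1 = row1[3 * c : 3 * c + 3].upper()
        c2 = row2[3 * c : 3 * c + 3].upper()
        if not (_codon_ok(c1) and _codon_ok(c2)):
            continue
        s1, n1 = _SITE_TABLE[c1]
        s2, n2 = _SITE_TABLE[c2]
        S += 0.5 * (s1 + s2)
        N += 0.5 * (n1 + n2)
        sd, nd = codon_diffs(c1, c2)
        Sd += sd
        Nd += nd
        used += 1

    out = PairwiseRates(S=S, N=N, Sd=Sd, Nd=Nd, n_codons=used)
    if used == 0:
        out.reason = "no comparable codons"
        return out
    if S <= 0.0 or N <= 0.0:
        out.reason = "no synonymous sites" if S <= 0.0 else "no nonsynonymous sites"
        return out
    ks = jukes_cantor(Sd / S)
    ka = jukes_cantor(Nd / N)
    if ks is None or ka is None:
        out.reason = "proportion of differences >= 3/4; correction diverges"
        return out
    out.Ka, out.Ks, out.defined = ka, ks, True
    return out


# ---------------------------------------------------------------------------
# Alignment container
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """Codon-partitioned aligned sequences.

    Rows must be equal length with column count divisible by 3; amino-acid
    column c (1-based) maps to nucleotide columns 3c-2..3c. Gaps are '-'.
    """

    records: list[tuple[str, str]]
    partition: Optional[PrecursorPartition] = None

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty alignment")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise ValueError("alignment rows differ in length")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError("alignment length not divisible by 3")
        self.records = [(rid, seq.upper()) for rid, seq in self.records]

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    @property
    def n_seqs(self) -> int:
        return len(self.records)

    @property
    def n_aa_columns(self) -> int:
        return len(self.records[0][1]) // 3

    def subset(self, ids: Sequence[str]) -> "CodonAlignment":
        wanted = set(ids)
        rows = [(rid, seq) for rid, seq in self.records if rid in wanted]
        missing = wanted - {rid for rid, _ in rows}
        if missing:
            raise KeyError(f"ids not in alignment: {sorted(missing)}")
        return CodonAlignment(rows, self.partition)


# ---------------------------------------------------------------------------
# Sliding windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in amino-acid columns (defaults 10/5)."""

    size: int = 10
    step: int = 5

    def __post_init__(self) -> None:
        if self.size < 2 or self.step < 1:
            raise ValueError("window size must be >= 2 and step >= 1")

    def windows(self, n_columns: int) -> list[tuple[int, int]]:
        """Full windows 1-based inclusive; trailing short windows dropped."""
        out = []
        start = 1
        while start + self.size - 1 <= n_columns:
            out.append((start, start + self.size - 1))
            start += self.step
        return out


@dataclass(frozen=True)
class BootstrapConfig:
    """Sequence-resampling bootstrap settings for the window test."""

    replicates: int = 1000
    seed: int = 0
    max_redraws: int = 100

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need at least 2 bootstrap replicates")


@dataclass
class WindowStat:
    """One sliding-window row of the selection profile."""

    start: int
    end: int
    identity: float = float("nan")  # mean pairwise % amino-acid identity
    avg_Ka: float = float("nan")
    avg_Ks: float = float("nan")
    avg_KaKs: float = float("nan")
    n_pairs_used: int = 0
    direction: str = ""  # 'greater' | 'less'
    boot_mean: float = float("nan")
    boot_sd: float = float("nan")
    p_value: float = float("nan")


@dataclass
class _PairProfiles:
    """Per-pair, per-amino-acid-column NG86 profiles for fast window sums.

    For every unordered sequence pair, arrays of length n_columns hold the
    codon's averaged site counts (s, n), pathway-averaged differences
    (sd, nd), a validity mask, and amino-acid comparability/match masks.
    Window aggregates are then plain slice sums.
    """

    pairs: list[tuple[int, int]]
    s: np.ndarray   # (n_pairs, n_cols)
    n: np.ndarray
    sd: np.ndarray
    nd: np.ndarray
    valid: np.ndarray       # bool
    aa_comparable: np.ndarray  # bool: both residues non-gap
    aa_match: np.ndarray       # bool: identical residues

    @classmethod
    def build(cls, aln: CodonAlignment) -> "_PairProfiles":
        nseq, ncol = aln.n_seqs, aln.n_aa_columns
        pairs = [(i, j) for i in range(nseq) for j in range(i + 1, nseq)]
        shape = (len(pairs), ncol)
        s = np.zeros(shape)
        n = np.zeros(shape)
        sd = np.zeros(shape)
        nd = np.zeros(shape)
        valid = np.zeros(shape, dtype=bool)
        comparable = np.zeros(shape, dtype=bool)
        match = np.zeros(shape, dtype=bool)
        rows = [seq for _, seq in aln.records]
        codons = [[seq[3 * c : 3 * c + 3] for c in range(ncol)] for seq in rows]
        aas = [[translate_codon(cd) for cd in row] for row in codons]
        for p, (i, j) in enumerate(pairs):
            ci, cj = codons[i], codons[j]
            ai, aj = aas[i], aas[j]
            for c in range(ncol):
                x, y = ci[c], cj[c]
                if _codon_ok(x) and _codon_ok(y):
                    s1, n1 = _SITE_TABLE[x]
                    s2, n2 = _SITE_TABLE[y]
                    s[p, c] = 0.5 * (s1 + s2)
                    n[p, c] = 0.5 * (n1 + n2)
                    d = codon_diffs(x, y)
                    sd[p, c], nd[p, c] = d
                    valid[p, c] = True
                if ai[c] != "-" and aj[c] != "-":
                    comparable[p, c] = True
                    match[p, c] = ai[c] == aj[c]
        return cls(pairs, s, n, sd, nd, valid, comparable, match)

    def window_rates(self, start: int, end: int) -> tuple[np.ndarray, np.ndarray]:
        """(Ka, Ks) arrays over pairs for a 1-based inclusive window; nan
        where undefined."""
        sl = slice(start - 1, end)
        S = np.where(self.valid[:, sl], self.s[:, sl], 0.0).sum(axis=1)
        N = np.where(self.valid[:, sl], self.n[:, sl], 0.0).sum(axis=1)
        Sd = np.where(self.valid[:, sl], self.sd[:, sl], 0.0).sum(axis=1)
        Nd = np.where(self.valid[:, sl], self.nd[:, sl], 0.0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            pS = np.where(S > 0, Sd / np.where(S > 0, S, 1.0), np.nan)
            pN = np.where(N > 0, Nd / np.where(N > 0, N, 1.0), np.nan)
            ks = np.where(pS < 0.75, -0.75 * np.log1p(-4.0 * pS / 3.0), np.nan)
            ka = np.where(pN < 0.75, -0.75 * np.log1p(-4.0 * pN / 3.0), np.nan)
        return ka, ks

    def window_identity(self, start: int, end: int) -> float:
        sl = slice(start - 1, end)
        comp = self.aa_comparable[:, sl].sum(axis=1)
        hits = self.aa_match[:, sl].sum(axis=1)
        with np.errstate(invalid="ignore"):
            pct = np.where(comp > 0, 100.0 * hits / np.maximum(comp, 1), np.nan)
        pct = pct[comp > 0]
        return float(np.mean(pct)) if pct.size else float("nan")


def _pair_ratio_matrix(ka: np.ndarray, ks: np.ndarray, pairs, nseq: int) -> np.ndarray:
    """Symmetric (nseq, nseq) matrix of per-pair Ka/Ks; nan where undefined
    or Ks == 0."""
    mat = np.full((nseq, nseq), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ks > 0, ka / np.where(ks > 0, ks, 1.0), np.nan)
    for p, (i, j) in enumerate(pairs):
        mat[i, j] = mat[j, i] = ratio[p]
    return mat


def bootstrap_test(
    ratio_matrix: np.ndarray,
    observed_avg: float,
    boot: BootstrapConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, str, float, float]:
    """Directional sequence-resampling bootstrap of a window average vs 1.

    ``ratio_matrix`` holds per-pair Ka/Ks for the window (nan = undefined or
    Ks = 0). Each replicate resamples the N sequence labels with replacement
    and averages the ratios over resampled pairs, excluding pairs made of two
    copies of the same original sequence; replicates with no usable pair are
    redrawn (up to ``max_redraws`` extra draws in total) and then dropped.
    A normal is fitted by the replicate mean/SD; the one-sided p-value is the
    fitted tail probability beyond 1 opposite the alternative hypothesis
    (H1: ">1" when the observed average exceeds 1, "<1" otherwise).

    Returns ``(p_value, direction, boot_mean, boot_sd)``; p is nan when every
    replicate was undefined.
    """
    if not np.isfinite(observed_avg):
        raise ValueError("observed average is undefined")
    if rng is None:
        rng = np.random.default_rng(boot.seed)
    nseq = ratio_matrix.shape[0]
    iu, ju = np.triu_indices(nseq, k=1)

    def draw(n_rep: int) -> np.ndarray:
        labels = rng.integers(0, nseq, size=(n_rep, nseq))
        li = labels[:, iu]
        lj = labels[:, ju]
        vals = ratio_matrix[li, lj]
        vals = np.where(li == lj, np.nan, vals)  # self-pairs excluded
        ok = np.isfinite(vals)
        n_ok = ok.sum(axis=1)
        sums = np.where(ok, vals, 0.0).sum(axis=1)
        return np.where(n_ok > 0, sums / np.maximum(n_ok, 1), np.nan)

    reps = draw(boot.replicates)
    redraws_left = boot.max_redraws
    while np.isnan(reps).any() and redraws_left > 0:
        nan_idx = np.flatnonzero(np.isnan(reps))
        take = min(len(nan_idx), redraws_left)
        reps[nan_idx[:take]] = draw(take)
        redraws_left -= take
    reps = reps[np.isfinite(reps)]

    direction = "greater" if observed_avg > 1.0 else "less"
    if reps.size < 2:
        return float("nan"), direction, float("nan"), float("nan")
    m = float(np.mean(reps))
    sd = float(np.std(reps, ddof=1))
    if sd == 0.0:
        if m == 1.0:
            p = 0.5
        elif direction == "greater":
            p = 0.0 if m > 1.0 else 1.0
        else:
            p = 0.0 if m < 1.0 else 1.0
    elif direction == "greater":
        p = float(norm.cdf(1.0, loc=m, scale=sd))  # mass at or below 1
    else:
        p = float(norm.sf(1.0, loc=m, scale=sd))  # mass at or above 1
    return p, direction, m, sd


def window_scan(
    aln: CodonAlignment,
    spec: WindowSpec = WindowSpec(),
    boot: Optional[BootstrapConfig] = None,
    *,
    ratio_of_averages: bool = False,
) -> list[WindowStat]:
    """Sliding-window identity and average pairwise Ka/Ks profile.

    Windows start at columns 1, 1+step, ...; trailing windows shorter than
    ``spec.size`` are dropped. Per window, ``avg_KaKs`` is the mean of
    per-pair ratios over pairs with defined rates and Ks > 0 (or the ratio of
    the average Ka to the average Ks with ``ratio_of_averages=True``);
    ``avg_Ka``/``avg_Ks`` average over all pairs with defined rates. When a
    :class:`BootstrapConfig` is supplied the directional bootstrap fields are
    filled for every window with a defined average.
    """
    if aln.n_seqs < 2:
        raise ValueError("window scan needs at least 2 sequences")
    profiles = _PairProfiles.build(aln)
    rng = np.random.default_rng(boot.seed) if boot is not None else None
    out: list[WindowStat] = []
    for start, end in spec.windows(aln.n_aa_columns):
        ka, ks = profiles.window_rates(start, end)
        stat = WindowStat(start=start, end=end)
        stat.identity = profiles.window_identity(start, end)
        defined = np.isfinite(ka) & np.isfinite(ks)
        if defined.any():
            stat.avg_Ka = float(np.mean(ka[defined]))
            stat.avg_Ks = float(np.mean(ks[defined]))
        usable = defined & (ks > 0)
        stat.n_pairs_used = int(usable.sum())
        if ratio_of_averages:
            if defined.any() and np.mean(ks[defined]) > 0:
                stat.avg_KaKs = float(np.mean(ka[defined]) / np.mean(ks[defined]))
        elif usable.any():
            stat.avg_KaKs = float(np.mean(ka[usable] / ks[usable]))
        if boot is not None and np.isfinite(stat.avg_KaKs):
            mat = _pair_ratio_matrix(ka, ks, profiles.pairs, aln.n_seqs)
            p, direction, bm, bsd = bootstrap_test(mat, stat.avg_KaKs, boot, rng)
            stat.p_value, stat.direction, stat.boot_mean, stat.boot_sd = p, direction, bm, bsd
        out.append(stat)
    return out


def region_means(
    stats: Sequence[WindowStat], partition: PrecursorPartition
) -> dict[str, float]:
    """Mean window avg_KaKs per precursor region (window assigned by its
    midpoint column); nan for regions with no defined window."""
    acc: dict[str, list[float]] = {"signal": [], "prosegment": [], "mature": []}
    for st in stats:
        mid = (st.start + st.end) // 2
        region = partition.region_of(mid)
        if np.isfinite(st.avg_KaKs):
            acc[region].append(st.avg_KaKs)
    return {
        r: (float(np.mean(v)) if v else float("nan")) for r, v in acc.items()
    }
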