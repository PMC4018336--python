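"""Defensin gene-repertoire modelling.

α-defensins are synthesized as a tripartite precursor (signal peptide,
prosegment, mature peptide); the mature peptide carries six conserved
cysteines in a tridisulfide motif. θ-defensins arise from an α-defensin-like
precursor truncated by a nonsense mutation within the mature region: the
twelve residues upstream of that stop end in a nonapeptide-bearing tail, two
nonapeptides are excised (the three C-terminal tail residues, typically RLL
or QLL, are removed) and ligated head-to-tail into a cyclic octadecapeptide
closed by a tridisulfide ladder.

This module classifies coding sequences as functional genes or pseudogenes
(premature stop / frameshift), validates the family's cysteine motifs, and
performs the θ maturation steps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .genetics import translate, validate_dna


class Status(str, Enum):
    FUNCTIONAL = "functional"
    PSEUDOGENE = "pseudogene"


class PseudoReason(str, Enum):
    NONE = "none"
    PREMATURE_STOP = "premature_stop"
    FRAMESHIFT = "frameshift"


@dataclass
class Classification:
    """Outcome of classifying one coding sequence."""

    status: Status
    pseudo_reason: PseudoReason = PseudoReason.NONE
    stop_site: Optional[int] = None  # 1-based codon index of first premature stop
    is_theta_precursor: bool = False

    def __post_init__(self) -> None:
        if (self.status is Status.PSEUDOGENE) != (self.pseudo_reason is not PseudoReason.NONE):
            raise ValueError("status=pseudogene iff pseudo_reason != none")
        if (self.stop_site is not None) != (
            self.pseudo_reason is PseudoReason.PREMATURE_STOP or self.is_theta_precursor
        ):
            raise ValueError("stop_site is set iff a premature stop was observed")


@dataclass
class GeneRecord:
    """One coding sequence with its repertoire annotation."""

    id: str
    species: str
    cluster: str
    cds: str
    status: Status
    pseudo_reason: PseudoReason = PseudoReason.NONE
    stop_site: Optional[int] = None
    is_theta_precursor: bool = False
    motif_flags: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PrecursorPartition:
    """Signal/prosegment/mature spans, 1-based inclusive amino-acid columns.

    Defaults follow the conventional precursor architecture of a ~94-residue
    defensin preproprotein: a 19-residue signal peptide, a prosegment through
    column 64, and the mature peptide from column 65 to the end.
    """

    signal: tuple[int, int] = (1, 19)
    prosegment: tuple[int, int] = (20, 64)
    mature: tuple[int, int] = (65, 94)

    def __post_init__(self) -> None:
        s, p, m = self.signal, self.prosegment, self.mature
        if not (s[0] == 1 and s[1] + 1 == p[0] and p[1] + 1 == m[0] and m[0] <= m[1]):
            raise ValueError(
                "partition spans must be contiguous and ordered signal < prosegment < mature"
            )

    def region_of(self, aa_column: int) -> str:
        """Region name for a 1-based amino-acid column."""
        if self.signal[0] <= aa_column <= self.signal[1]:
            return "signal"
        if self.prosegment[0] <= aa_column <= self.prosegment[1]:
            return "prosegment"
        if aa_column >= self.mature[0]:
            return "mature"
        raise ValueError(f"column {aa_column} outside partition")

    @property
    def regions(self) -> dict[str, tuple[int, int]]:
        return {"signal": self.signal, "prosegment": self.prosegment, "mature": self.mature}


# ---------------------------------------------------------------------------
# Motifs
# ---------------------------------------------------------------------------

# Pattern tokens: "C" is a required cysteine anchor; (lo, hi) is a bounded
# wildcard spacer. 'X' (unknown residue) may occupy a spacer position but can
# never serve as an anchor.
_Token = object  # str "C" or tuple[int, int]

# α-defensin mature motif: six conserved cysteines. The family consensus ends
# in two adjacent cysteines (Cys5-Cys6), giving
#   C-x-C-x(3,4)-C-x(9)-C-x(6,9)-C-C
_ALPHA_TOKENS: tuple = ("C", (1, 1), "C", (3, 4), "C", (9, 9), "C", (6, 9), "C", (0, 0), "C")
# θ-defensin nonapeptide motif: three conserved cysteines, x-C-x-C-x(4)-C.
_THETA_TOKENS: tuple = ((1, 1), "C", (1, 1), "C", (4, 4), "C")
# Colobus 13-mer variant: x-C-x-C-x(8)-C.
_THETA_VARIANT_TOKENS: tuple = ((1, 1), "C", (1, 1), "C", (8, 8), "C")

# Residues a wildcard spacer may match: any amino-acid letter incl. 'X'.
_SPACER_CLASS = "[A-Z]"


@dataclass(frozen=True)
class MotifSpec:
    """A cysteine-anchored wildcard motif with bounded spacers."""

    kind: str
    tokens: tuple

    def __post_init__(self) -> None:
        n = self.n_anchors
        expected = {"alpha_mature": 6, "theta_nonapeptide": 3, "theta_nonapeptide_variant": 3}
        if self.kind in expected and n != expected[self.kind]:
            raise ValueError(f"{self.kind} motif must have {expected[self.kind]} cysteine anchors, got {n}")

    @property
    def n_anchors(self) -> int:
        return sum(1 for t in self.tokens if t == "C")

    @property
    def pattern(self) -> str:
        """Human-readable pattern string, e.g. 'C-x-C-x(3,4)-...'."""
        parts = []
        for t in self.tokens:
            if t == "C":
                parts.append("C")
            else:
                lo, hi = t
                if lo == hi == 0:
                    continue
                if lo == hi == 1:
                    parts.append("x")
                elif lo == hi:
                    parts.append(f"x({lo})")
                else:
                    parts.append(f"x({lo},{hi})")
        return "-".join(parts)

    def _regex(self) -> re.Pattern:
        # Each spacer gets its own group so anchor offsets can be recovered.
        out = []
        for t in self.tokens:
            if t == "C":
                out.append("(C)")
            else:
                lo, hi = t
                out.append(f"({_SPACER_CLASS}{{{lo},{hi}}})")
        return re.compile("".join(out))

    @classmethod
    def alpha_mature(cls) -> "MotifSpec":
        return cls("alpha_mature", _ALPHA_TOKENS)

    @classmethod
    def theta_nonapeptide(cls) -> "MotifSpec":
        return cls("theta_nonapeptide", _THETA_TOKENS)

    @classmethod
    def theta_nonapeptide_variant(cls) -> "MotifSpec":
        return cls("theta_nonapeptide_variant", _THETA_VARIANT_TOKENS)


@dataclass(frozen=True)
class MotifMatch:
    matched: bool
    anchor_positions: tuple[int, ...] = ()  # 1-based positions in the peptide

    def __bool__(self) -> bool:
        return self.matched


def validate_motif(peptide: str, spec: MotifSpec) -> MotifMatch:
    """Search ``peptide`` for the motif; return match flag + anchor positions.

    The match may occur anywhere in the peptide; empty input simply fails.
    Wildcard spacers match any residue letter including 'X', but an 'X' can
    never satisfy a cysteine anchor.
    """
    if not peptide:
        return MotifMatch(False)
    m = spec._regex().search(peptide.upper())
    if m is None:
        return MotifMatch(False)
    anchors = []
    offset = m.start()
    for i, t in enumerate(spec.tokens):
        g = m.group(i + 1)
        if t == "C":
            anchors.append(offset + 1)  # 1-based
        offset += len(g)
    return MotifMatch(True, tuple(anchors))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_coding_sequence(
    cds: str,
    expected_codon_length: int,
    *,
    theta_stop_site: Optional[int] = None,
) -> Classification:
    """Classify a coding sequence as functional or pseudogene.

    A sequence is functional iff its reading frame has no stop codon before
    the terminal position and its length deviates from
    ``expected_codon_length * 3`` by a multiple of 3 (indels judged against
    the family alignment length). Otherwise it is a pseudogene with reason
    ``frameshift`` or ``premature_stop`` (reporting the first offending codon,
    1-based).

    If ``theta_stop_site`` is given (typically the alignment position
    homologous to the θ-defining Q77* nonsense site), a first stop exactly at
    that codon does *not* pseudogenize the gene when the twelve residues
    immediately upstream pass the θ-nonapeptide motif after tail excision: it
    marks a functional θ-defensin precursor. A stop anywhere else (e.g. the
    Q17* signal-peptide nonsense mutation) is always a pseudogene call.
    """
    seq = validate_dna(cds).replace("-", "")
    if not seq:
        raise ValueError("sequence contains only gap characters")

    if (len(seq) - expected_codon_length * 3) % 3 != 0:
        return Classification(Status.PSEUDOGENE, PseudoReason.FRAMESHIFT)

    protein = translate(seq)
    n_codons = len(protein)
    stop_idx = protein.find("*")  # 0-based; -1 if none
    if stop_idx == -1 or stop_idx == n_codons - 1:
        return Classification(Status.FUNCTIONAL)

    stop_site = stop_idx + 1
    if theta_stop_site is not None and stop_site == theta_stop_site and stop_site > 12:
        tail = protein[stop_idx - 12 : stop_idx]
        nona, _removed = excise_nonapeptide(tail)
        if validate_motif(nona, MotifSpec.theta_nonapeptide()):
            return Classification(
                Status.FUNCTIONAL, stop_site=stop_site, is_theta_precursor=True
            )
    return Classification(Status.PSEUDOGENE, PseudoReason.PREMATURE_STOP, stop_site=stop_site)


def build_gene_record(
    id: str,
    species: str,
    cluster: str,
    cds: str,
    expected_codon_length: int,
    *,
    theta_stop_site: Optional[int] = None,
    partition: Optional[PrecursorPartition] = None,
) -> GeneRecord:
    """Classify one sequence and annotate its motif flags for reporting."""
    cls = classify_coding_sequence(
        cds, expected_codon_length, theta_stop_site=theta_stop_site
    )
    protein = translate(validate_dna(cds).replace("-", ""))
    if partition is not None and cls.status is Status.FUNCTIONAL:
        mature = protein[partition.mature[0] - 1 :]
    else:
        mature = protein
    flags = {
        "alpha_mature": bool(validate_motif(mature, MotifSpec.alpha_mature())),
        "theta_nonapeptide": bool(validate_motif(mature, MotifSpec.theta_nonapeptide())),
    }
    return GeneRecord(
        id=id,
        species=species,
        cluster=cluster,
        cds=cds,
        status=cls.status,
        pseudo_reason=cls.pseudo_reason,
        stop_site=cls.stop_site,
        is_theta_precursor=cls.is_theta_precursor,
        motif_flags=flags,
    )


# ---------------------------------------------------------------------------
# θ maturation
# ---------------------------------------------------------------------------

def excise_nonapeptide(translated_theta_tail: str) -> tuple[str, str]:
    """Trim the 12-residue θ precursor tail to its nonapeptide.

    Maturation removes the three C-terminal residues (typically RLL or QLL)
    of the 12-residue segment upstream of the θ-defining stop; the first nine
    residues are the nonapeptide that enters cyclization. Returns
    ``(nonapeptide, removed_tail)``.
    """
    tail = translated_theta_tail.upper()
    if len(tail) != 12:
        raise ValueError(f"θ tail must be 12 residues, got {len(tail)}")
    return tail[:9], tail[9:]


#: Disulfide ladder connectivities for mature_theta, as index pairs into the
#: three cysteine anchors of each nonapeptide (0-based anchor ranks).
_LADDERS = {
    "antiparallel": ((0, 2), (1, 1), (2, 0)),
    "parallel": ((0, 0), (1, 1), (2, 2)),
}


@dataclass(frozen=True)
class CyclicPeptide:
    """A head-to-tail cyclic peptide with an intersubunit disulfide ladder.

    ``sequence`` is read around the cycle from a canonical start (position 1
    of the first nonapeptide); ``disulfides`` are 1-based position pairs in
    that coordinate system.
    """

    sequence: str
    disulfides: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for i, j in self.disulfides:
            if self.sequence[i - 1] != "C" or self.sequence[j - 1] != "C":
                raise ValueError("disulfides must connect cysteines")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def rotations(self) -> list[str]:
        s = self.sequence
        return [s[k:] + s[:k] for k in range(len(s))]

    def contains(self, sub: str) -> bool:
        """True if ``sub`` occurs contiguously somewhere around the cycle."""
        doubled = self.sequence + self.sequence
        return sub.upper() in doubled


def mature_theta(
    nonaA: str,
    nonaB: str,
    *,
    connectivity: str = "antiparallel",
) -> CyclicPeptide:
    """Ligate two nonapeptides head-to-tail into a cyclic octadecapeptide.

    Both subunits must pass the θ-nonapeptide motif; the pair may be
    homodimeric (identical subunits) or heterodimeric. The tridisulfide
    ladder pairs the three cysteines of subunit A with those of subunit B;
    the default ``antiparallel`` connectivity links A-Cys1–B-Cys3,
    A-Cys2–B-Cys2, A-Cys3–B-Cys1.
    """
    spec = MotifSpec.theta_nonapeptide()
    mA = validate_motif(nonaA, spec)
    mB = validate_motif(nonaB, spec)
    if not (mA and mB):
        bad = [name for name, m in (("A", mA), ("B", mB)) if not m]
        raise ValueError(f"nonapeptide(s) {','.join(bad)} fail θ-motif validation")
    if connectivity not in _LADDERS:
        raise ValueError(f"unknown connectivity {connectivity!r}; options: {sorted(_LADDERS)}")
    seq = (nonaA + nonaB).upper()
    offset = len(nonaA)
    pairs = tuple(
        (mA.anchor_positions[ia], mB.anchor_positions[ib] + offset)
        for ia, ib in _LADDERS[connectivity]
    )
    return CyclicPeptide(seq, pairs)


def classify_records(
    records: Sequence[tuple[str, str]],
    expected_codon_length: int,
    *,
    theta_stop_site: Optional[int] = None,
    partition: Optional[PrecursorPartition] = None,
    species: str = "NA",
    cluster: str = "NA",
) -> list[GeneRecord]:
    """Classify a batch of ``(id, cds)`` records with shared settings."""
    return [
        build_gene_record(
            rid, species, cluster, seq, expected_codon_length,
            theta_stop_site=theta_stop_site, partition=partition,
        )
        for rid, seq in records
    ]
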