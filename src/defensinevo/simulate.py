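"""Synthetic defensin families and dimer trajectories.

The family generator evolves a defensin-like ancestral coding sequence along
a known tree with region-specific selection intensity ω (dN/dS): per branch
and codon site, candidate single-nucleotide substitutions arrive with
expected count equal to the branch length; stop-creating proposals are
rejected, synonymous proposals fix with probability min(1, 1/ω) and
nonsynonymous ones with probability min(1, ω), so the realized Ka/Ks tracks
ω in both the purifying (ω < 1) and positive-selection (ω > 1) regimes.
This accept/reject scheme is a generator convention chosen for transparency
and recoverability by counting estimators, not a full codon-model matrix;
codon frequencies, transition/transversion bias and indel evolution along
the tree are deliberately not modelled.

Defaults mirror the study conditions the package is exercised under: a
94-codon precursor (signal 19 + prosegment 45 + mature 30 residues) with
ω = 0.2 / 0.5 / 2.0 for signal / prosegment / mature, reproducing the
conserved-signal vs divergent-mature contrast of real defensin alignments.
Pseudogenization events (premature stops, 1-2 nt deletions) and the
θ-deriving nonsense mutation at the position homologous to Q77 can be
injected per leaf. The trajectory generator jitters a reference dimer with
larger Gaussian noise on loop residues than on the core, emulating the
flexible-loop / rigid-sheet contrast of dimer dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import dendropy
import numpy as np

from .genetics import (
    BASES,
    GENETIC_CODE,
    PREFERRED_CODON,
    is_stop,
    translate,
)
from .geometry import DimerStructure
from .rates import CodonAlignment
from .repertoire import PrecursorPartition

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_REGION_OMEGAS = {"signal": 0.2, "prosegment": 0.5, "mature": 2.0}

#: Template precursor protein (94 aa = 19 signal + 45 prosegment + 30 mature).
#: The mature segment is HNP-like: six cysteines in the α motif, with the
#: N-terminal nine residues also satisfying the θ-nonapeptide motif so that a
#: nonsense mutation at column 77 yields a valid θ precursor.
TEMPLATE_SIGNAL = "MRTLAILAAILLVALQAQA"
TEMPLATE_PROSEGMENT = "EPLQARADEVAAAPEQIAADIPEVVVSLAWDESLAPKHPGSRKNM"
TEMPLATE_MATURE = "ACYCRIPACIAGERRYGTCIYQGRLWAFCC"
TEMPLATE_PROTEIN = TEMPLATE_SIGNAL + TEMPLATE_PROSEGMENT + TEMPLATE_MATURE


@dataclass(frozen=True)
class Lesion:
    """A pseudogenizing (or θ-deriving) event injected into one leaf.

    kind: 'stop' replaces the codon with TAA; 'indel' deletes 1 or 2 nt at
    the codon; 'theta_stop' places a stop at the θ-defining position leaving
    the upstream 12-residue tail intact.
    """

    leaf: str
    kind: str  # 'stop' | 'indel' | 'theta_stop'
    codon: int  # 1-based codon position
    indel_length: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("stop", "indel", "theta_stop"):
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if self.kind == "indel" and self.indel_length not in (1, 2):
            raise ValueError("indels delete 1 or 2 nucleotides")


@dataclass
class SimConfig:
    """Settings for one simulated codon family."""

    seed: int
    tree: Optional[dendropy.Tree] = None
    preset: str = "star"  # used when tree is None: 'star' | 'balanced'
    n_leaves: int = 12
    branch_length: float = 0.3  # expected substitution events per codon site
    region_omegas: dict = field(default_factory=lambda: dict(DEFAULT_REGION_OMEGAS))
    codon_length: int = 94
    partition: PrecursorPartition = field(default_factory=PrecursorPartition)
    lesions: tuple[Lesion, ...] = ()
    ancestor_protein: Optional[str] = None

    def __post_init__(self) -> None:
        for region in ("signal", "prosegment", "mature"):
            if region not in self.region_omegas:
                raise ValueError(f"region_omegas missing region {region!r}")
            if self.region_omegas[region] < 0:
                raise ValueError("ω must be non-negative")
        for les in self.lesions:
            if not (1 <= les.codon <= self.codon_length):
                raise ValueError(f"lesion position {les.codon} outside sequence")


@dataclass
class FamilyHistory:
    """True per-region substitution record of a simulated family."""

    config_summary: dict
    events: dict  # region -> {'synonymous': int, 'nonsynonymous': int}
    lesions: list[dict]

    def as_dict(self) -> dict:
        return {
            "config": self.config_summary,
            "events": self.events,
            "lesions": self.lesions,
        }


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def preset_tree(kind: str, n_leaves: int, branch_length: float) -> dendropy.Tree:
    """Build a star or balanced-binary tree with uniform branch lengths."""
    taxa = dendropy.TaxonNamespace([f"t{i+1}" for i in range(n_leaves)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    if kind == "star":
        for taxon in taxa:
            child = tree.seed_node.new_child(edge_length=branch_length)
            child.taxon = taxon
    elif kind == "balanced":
        nodes = [tree.seed_node]
        while len(nodes) < n_leaves:
            node = nodes.pop(0)
            for _ in range(2):
                nodes.append(node.new_child(edge_length=branch_length))
            if len(nodes) >= n_leaves:
                break
        for taxon, node in zip(taxa, nodes):
            node.taxon = taxon
        if len(nodes) != n_leaves:
            raise ValueError("balanced preset needs a leaf count reachable by halving")
    else:
        raise ValueError(f"unknown preset {kind!r}")
    return tree


# ---------------------------------------------------------------------------
# Ancestral sequence
# ---------------------------------------------------------------------------

def _back_translate(protein: str) -> list[str]:
    return [PREFERRED_CODON[aa] for aa in protein]


def default_ancestor_codons(cfg: SimConfig) -> list[str]:
    """Ancestral codon list for a config; template-based for the default
    geometry, otherwise random sense codons in non-template regions."""
    protein = cfg.ancestor_protein
    if protein is None:
        if cfg.codon_length == len(TEMPLATE_PROTEIN) and cfg.partition == PrecursorPartition():
            protein = TEMPLATE_PROTEIN
        else:
            # repeat the template to the requested length
            reps = (cfg.codon_length // len(TEMPLATE_PROTEIN)) + 1
            protein = (TEMPLATE_PROTEIN * reps)[: cfg.codon_length]
    if len(protein) != cfg.codon_length:
        raise ValueError("ancestor protein length does not match codon_length")
    return _back_translate(protein)


# ---------------------------------------------------------------------------
# Evolution
# ---------------------------------------------------------------------------

def _evolve_branch(
    codons: list[str],
    branch_length: float,
    cfg: SimConfig,
    rng: np.random.Generator,
    events: dict,
) -> list[str]:
    out = list(codons)
    n_events = rng.poisson(branch_length, size=len(out))
    for site in np.flatnonzero(n_events):
        region = cfg.partition.region_of(site + 1)
        omega = cfg.region_omegas[region]
        for _ in range(int(n_events[site])):
            codon = out[site]
            pos = int(rng.integers(3))
            alternatives = [b for b in BASES if b != codon[pos]]
            base = alternatives[int(rng.integers(3))]
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if is_stop(mutant):
                continue  # stop-creating proposals rejected
            synonymous = GENETIC_CODE[mutant] == GENETIC_CODE[codon]
            if synonymous:
                accept = omega <= 1.0 or rng.random() < 1.0 / omega
            else:
                accept = omega >= 1.0 or rng.random() < omega
            if accept:
                out[site] = mutant
                key = "synonymous" if synonymous else "nonsynonymous"
                events[region][key] += 1
    return out


def inject_lesion(seq: str, lesion: Lesion) -> str:
    """Apply one lesion to an ungapped coding sequence."""
    n_codons = len(seq) // 3
    if not (1 <= lesion.codon <= n_codons):
        raise ValueError(f"lesion position {lesion.codon} out of range (1..{n_codons})")
    start = 3 * (lesion.codon - 1)
    if lesion.kind in ("stop", "theta_stop"):
        return seq[:start] + "TAA" + seq[start + 3 :]
    return seq[:start] + seq[start + lesion.indel_length :]


def simulate_family(cfg: SimConfig) -> tuple[CodonAlignment, FamilyHistory]:
    """Evolve a codon family on the configured tree.

    Returns a gap-free, codon-aligned family (aligned by construction since
    no indels evolve along the tree) plus the true per-region substitution
    history. Lesioned leaves are returned inside the alignment only when the
    lesion preserves codon structure ('stop'/'theta_stop'); 'indel' lesions
    are recorded in the history with the raw sequence, since a frameshifted
    row has no codon alignment.
    """
    rng = np.random.default_rng(cfg.seed)
    tree = cfg.tree if cfg.tree is not None else preset_tree(
        cfg.preset, cfg.n_leaves, cfg.branch_length
    )
    ancestor = default_ancestor_codons(cfg)
    events = {r: {"synonymous": 0, "nonsynonymous": 0} for r in ("signal", "prosegment", "mature")}

    leaf_seqs: dict[str, str] = {}

    def descend(node, codons):
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            child_codons = _evolve_branch(codons, bl, cfg, rng, events)
            if child.is_leaf():
                leaf_seqs[child.taxon.label] = "".join(child_codons)
            else:
                descend(child, child_codons)

    descend(tree.seed_node, ancestor)

    lesion_log = []
    lesioned: dict[str, str] = {}
    for les in cfg.lesions:
        if les.leaf not in leaf_seqs:
            raise ValueError(f"lesion leaf {les.leaf!r} not in tree")
        base = lesioned.get(les.leaf, leaf_seqs[les.leaf])
        mutated = inject_lesion(base, les)
        lesioned[les.leaf] = mutated
        lesion_log.append(
            {"leaf": les.leaf, "kind": les.kind, "codon": les.codon,
             "sequence": mutated}
        )

    records = []
    for label in sorted(leaf_seqs, key=lambda s: (len(s), s)):
        seq = lesioned.get(label, leaf_seqs[label])
        if label in lesioned and len(seq) % 3 != 0:
            continue  # frameshifted rows live in the history, not the alignment
        records.append((label, seq))

    aln = CodonAlignment(records, cfg.partition)
    history = FamilyHistory(
        config_summary={
            "seed": cfg.seed,
            "preset": cfg.preset if cfg.tree is None else "custom",
            "n_leaves": len(leaf_seqs),
            "branch_length": cfg.branch_length,
            "region_omegas": dict(cfg.region_omegas),
            "codon_length": cfg.codon_length,
        },
        events=events,
        lesions=lesion_log,
    )
    return aln, history


# ---------------------------------------------------------------------------
# Dimer reference and trajectories
# ---------------------------------------------------------------------------

DEFAULT_LOOP_RESIDUES = frozenset(range(9, 15))  # loop tip around residue 11


def make_synthetic_dimer(
    n_residues: int = 30,
    loop_residues: frozenset[int] = DEFAULT_LOOP_RESIDUES,
) -> DimerStructure:
    """Idealized two-chain reference dimer (synthetic stand-in geometry).

    Chains A and B are smooth backbone curves arranged so the interface
    residues 18/20 of the two chains face each other while the loop residues
    around 11 point outward; backbone atoms are placed at fixed offsets from
    each Cα. The geometry is regular rather than physical — it exists so the
    metric and superposition machinery can be exercised without experimental
    coordinates.
    """
    offsets = {
        "N": np.array([-0.8, 0.6, 0.3]),
        "CA": np.zeros(3),
        "C": np.array([0.9, 0.5, -0.2]),
        "O": np.array([1.1, 1.6, -0.4]),
    }

    def chain_coords(flip: bool) -> dict[int, dict[str, np.ndarray]]:
        residues = {}
        for i in range(1, n_residues + 1):
            t = (i - 1) / (n_residues - 1)
            # arc: x runs along the chain, y bulges out at the loop tip
            ca = np.array([
                3.2 * (i - 1) * 0.45,
                14.0 * np.sin(np.pi * min(t * 2.2, 1.0)) if i <= 15 else 3.0 * np.sin(0.6 * i),
                1.8 * np.cos(0.5 * i),
            ])
            if flip:
                ca = np.array([ca[0], -ca[1] - 9.6, ca[2] + 1.2])
            residues[i] = {name: ca + off for name, off in offsets.items()}
        return residues

    chains = {"A": chain_coords(False), "B": chain_coords(True)}
    return DimerStructure(chains, ("A", "B"))


@dataclass
class TrajectoryConfig:
    """Settings for a jittered near-rigid dimer trajectory."""

    seed: int
    reference: Optional[DimerStructure] = None
    loop_sigma: float = 1.0   # Å jitter for loop residues
    core_sigma: float = 0.1   # Å jitter elsewhere
    n_frames: int = 20
    loop_residues: frozenset[int] = DEFAULT_LOOP_RESIDUES

    def __post_init__(self) -> None:
        if self.loop_sigma < 0 or self.core_sigma < 0:
            raise ValueError("jitter sigmas must be non-negative")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


def simulate_trajectory(cfg: TrajectoryConfig) -> list[DimerStructure]:
    """Multi-frame trajectory: frame 1 is the unperturbed reference, later
    frames add independent Gaussian coordinate jitter (loop residues get
    ``loop_sigma``, everything else ``core_sigma``)."""
    rng = np.random.default_rng(cfg.seed)
    reference = cfg.reference if cfg.reference is not None else make_synthetic_dimer()
    # fail early if the metric residues are unresolvable
    reference.selection_coords(residues=(11, 18, 20, 22), atoms=("CA",))

    def sigma_of(chain_id: str, resnum: int) -> float:
        return cfg.loop_sigma if resnum in cfg.loop_residues else cfg.core_sigma

    frames = [replace_frame(reference, 1)]
    for k in range(2, cfg.n_frames + 1):
        frames.append(reference.with_jitter(rng, sigma_of, k))
    return frames


def replace_frame(structure: DimerStructure, frame: int) -> DimerStructure:
    return DimerStructure(structure.chains, structure.chain_order,
                          structure.numbering_map, frame)
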