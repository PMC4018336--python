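# Methods

## Scope and data model

The package operates downstream of gene discovery and alignment: coding
sequences arrive as FASTA, codon alignments as aligned FASTA (columns
divisible by 3, amino-acid column *c* owning nucleotide columns
3c−2..3c), pairwise type-I divergence coefficients as a TSV, and
structures/trajectories as fixed-column ATOM-record files (one MODEL per
frame). Estimation of θ_ij itself (probabilistic models of rate-shift after
duplication), codon-model maximum likelihood (M0–M8a site models), tree
inference and molecular-dynamics engines are explicitly out of scope; their
outputs are inputs here. All interface coordinates are 1-based inclusive.

## Repertoire classification

A coding sequence is **functional** iff (a) its length deviates from the
expected codon length × 3 by a multiple of 3 — indels are judged against
the family alignment, so whole-codon indels do not pseudogenize — and
(b) the reading frame contains no stop codon before the terminal position.
Otherwise it is a **pseudogene** with reason `frameshift` or
`premature_stop` (first offending codon reported, 1-based). Translation
uses the standard nuclear code; codons containing ambiguity symbols (or the
'?' placeholders genome translations produce at SNPs) translate to 'X'.

One stop is special: θ-defensins are *created* by a nonsense mutation in
the mature peptide. When a θ stop site is configured (the alignment codon
homologous to the classic Q77* event; default 77), a first stop exactly
there is treated as a functional θ precursor **iff** the twelve residues
immediately upstream, after excision of their three C-terminal residues
(the RLL/QLL tail removed during maturation), satisfy the θ-nonapeptide
motif. A stop anywhere else — e.g. the Q17* signal-peptide nonsense
mutation — always pseudogenizes.

Motifs are cysteine-anchored wildcard patterns with bounded spacers:

* α mature peptide: `C-x-C-x(3,4)-C-x(9)-C-x(6,9)-C-C` — six cysteine
  anchors. The family consensus ends in two adjacent cysteines
  (Cys5–Cys6); the pattern is sometimes quoted without the terminal C, but
  six conserved cysteines define the α mature peptide and the validator
  enforces all six.
* θ nonapeptide: `x-C-x-C-x(4)-C`; a 13-residue variant `x-C-x-C-x(8)-C`
  covers the colobus θ-defensin.

Wildcard positions match any residue letter including 'X'; an 'X' never
satisfies an anchor. Matching is positional (regex with per-token groups),
so anchor positions are returned and flanking residues can never break a
match.

θ maturation: `excise_nonapeptide` trims a 12-residue precursor tail to its
first nine residues; `mature_theta` ligates two motif-valid nonapeptides
head-to-tail into a cyclic octadecapeptide. The tridisulfide ladder is
reported as position pairs; connectivity defaults to antiparallel
(A-Cys1–B-Cys3, A-Cys2–B-Cys2, A-Cys3–B-Cys1) and is configurable to
parallel, since the ladder is described in the literature without explicit
pairings.

## Nei–Gojobori Ka/Ks

Site counts: each of a codon's nine single-base changes contributes 1/3 of
a site to S (synonymous) or N (nonsynonymous); changes creating stop codons
contribute to neither, so S + N = 3 − (stop-neighbor count)/3. This
convention (rather than renormalizing each position by its non-stop
changes) is chosen deliberately: under a mutation process that proposes
single-base changes uniformly and discards stop-creating ones — the
process the synthetic generator implements — it makes pS and pN equal at
every codon to first order under neutrality, i.e. the estimator is
unbiased against the generator's own null. Pair sites are the average of
the two codons' counts; codons with a gap, ambiguity code or stop in either
row are skipped (pairwise deletion).

Differences: for k differing positions, Sd and Nd average the synonymous /
nonsynonymous step counts over all k! single-step pathways, excluding
pathways that pass through a stop codon (if every pathway does, all are
kept — the standard fallback). Sd + Nd = k exactly.

Rates: pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected,
d = −(3/4)·ln(1 − (4/3)p). A pair is undefined when no codons are
comparable, when S or N is zero, or when either proportion reaches 3/4
(the correction diverges). Pairwise results are exactly symmetric.

### Sliding windows

Windows are full spans of `size` amino-acid columns (default 10) starting
at 1, 1+step, ... (default step 5); trailing short windows are dropped, so
a 100-column alignment yields 19 windows 1–10 … 91–100. Per window:

* `identity_pct` — mean pairwise amino-acid identity, comparing only
  columns where both residues are non-gap.
* `avg_Ka`, `avg_Ks` — means over pairs with defined rates.
* `avg_KaKs` — mean of per-pair ratios over pairs with defined rates and
  Ks > 0. The alternative ratio-of-averages (avg Ka / avg Ks) is available
  behind a flag; the per-pair-ratio mean is the default because the three
  averages are reported as separate columns by convention in this
  literature. Note the per-pair-ratio mean carries a Jensen-type upward
  bias at low divergence (measured ≈ +10% on 10-codon windows under a
  neutral generator at the default simulation depth) because Ks enters the
  denominator with few events; the ratio of averages is unbiased (≈ 1.01
  under the same null) and should be preferred when absolute calibration
  of the average matters more than comparability.

Internally the scan builds per-pair, per-column count profiles once and
aggregates windows by slice sums, so full scans and bootstrap replicates
reuse the same codon-level work.

### Directional bootstrap test

For each window with a defined average, the N sequence labels are resampled
with replacement `replicates` times (default 1000; the desk-scale
experiments below use 200). Each replicate recomputes the window average
over resampled pairs, excluding pairs formed by two copies of the same
original sequence (their ratio is 0/0); replicates whose average is
undefined are redrawn up to `max_redraws` (default 100) extra draws, then
dropped. A normal distribution is fitted by the replicate mean and SD and
the one-sided p-value is the fitted tail beyond 1 opposite the alternative:
direction `greater` (H1: Ka/Ks > 1, p = Φ((1−m)/s)) when the observed
average exceeds 1, otherwise direction `less` (p = 1 − Φ((1−m)/s)). A
degenerate fit (s = 0) yields p ∈ {0, ½, 1} by the sign of m − 1. The
normal fit rather than the empirical quantile is used deliberately, and the
RNG seed is mandatory and recorded in output headers.

Because the procedure runs **one** directional test per window, chosen by
the observed direction, a perfectly calibrated implementation rejects in
*either* direction at ~2α total under a boundary null; the calibration
experiment therefore measures the false **positive-selection** rate
(direction `greater` with p < α) — the inference the scan reports. Under a
neutral generator (ω ≡ 1, star tree, 12 leaves, branch length 0.3, window
41–50, 200 families × 200 replicates) this rate is 0.035–0.06 across master
seeds at α = 0.05.

## Functional distances

d_F = −ln(1 − θ) maps rate-shift coefficients θ ∈ [0, 1) to additive
distances; θ ≥ 1 is a domain error (infinite distance). On a star topology
d_F(A,B) = b_F(A) + b_F(B); with k ≥ 3 clusters, b_F minimizes
Σ_{i<j} (d_F,ij − b_F,i − b_F,j)², solved by least squares (for k = 3 this
equals the closed form b_i = (d_ij + d_ik − d_jk)/2 and the residuals
vanish). Negative solutions are reported with a warning rather than
constrained — nonnegativity is implied but not guaranteed by the model.
A known 0.01 rounding discrepancy exists in the published enteric example:
additivity from the printed branch lengths (3.41, 0.53, 0.17) yields a
range 0.70–3.94 whereas the printed range is 0.69–3.93; the package reports
the additively computed values and the tests assert only to the rounding
width.

## Dimer geometry

Structures are two chains of residues with backbone atoms; a per-chain
numbering map can translate structure numbering onto the HNP4 reference
numbering in which the metric residues are defined (maps must be
user-supplied; no published correspondence table exists for the homologs).
Superposition fits the backbone N/CA/C/O of residues 18 and 20 in both
chains — the residues forming the four intermolecular hydrogen bonds of
the α-defensin dimer interface — by orthogonal Procrustes (SVD with proper
rotation enforced). Whether the original interface fit used donor/acceptor
atoms only is unrecorded; whole backbone is the default and the selection
is overridable.

Per frame: d22 = |A22Cα − B22Cα|, d11 = |A11Cα − B11Cα| and the signed
torsion A11Cα–A22Cα–B22Cα–B11Cα in (−180°, 180°]. Residues 11 and 22 are
the distal tips of the two flexible loops, so d11 reports loop flexibility
while d22 reports dimer integrity. Trajectory summaries give mean, sample
SD (ddof = 1; defined as 0 for a single frame), min and max per metric;
the dihedral is summarized on |dihedral| because published ranges are
positive without a sign convention, while signed values stay in the
per-frame table.

## Synthetic-data generator

**Families.** An ancestral 94-codon precursor (signal 19 + prosegment 45 +
mature 30; the mature template carries the six α-motif cysteines and its
first nine residues satisfy the θ motif, so the θ-stop lesion at column 77
produces a valid precursor) evolves along a star or balanced tree (or any
supplied tree). Per branch and codon site, proposal events arrive with
expected count = branch length; each proposes a uniform single-base change;
stop-creating proposals are discarded; synonymous proposals fix with
probability min(1, 1/ω) and nonsynonymous with min(1, ω), with ω taken
from the site's region (defaults: signal 0.2, prosegment 0.5, mature 2.0 —
the conserved-signal/divergent-mature contrast of real defensin
alignments; branch length 0.3 and 12 leaves by default). The scheme is
chosen over a full codon-rate matrix for transparency and recoverability
by counting estimators. True per-region synonymous/nonsynonymous event
counts are recorded. Lesions (premature stop → TAA, 1–2 nt deletion,
θ-stop) are injected after evolution; frameshifted rows are reported in
the history sidecar but excluded from the codon alignment, which is
gap-free by construction.

What the generator does **not** emulate: codon-frequency and
transition/transversion bias, site-to-site rate variation within a region,
invariant cysteine positions (at depth 0.3 the motif cysteines themselves
drift), indel evolution along the tree, recombination/gene conversion, and
alignment error. Passing recovery tests therefore demonstrates estimator
correctness against a known-truth process of the same qualitative shape as
the real data, not robustness to those real-data complications.

**Trajectories.** A synthetic reference dimer (regular curved backbones
with interface residues 18/20 facing each other and loop tips at 11; the
geometry is a labelled synthetic stand-in, not a model of any real
structure) is jittered with isotropic Gaussian noise — `loop_sigma`
(default 1.0 Å) on loop residues (default 9–14), `core_sigma` (default
0.1 Å) elsewhere; frame 1 is the unperturbed reference. This reproduces
the flexible-loop/rigid-core contrast (SD(d11) ≫ SD(d22)) but not the
absolute distance or dihedral ranges of real dimer dynamics, which depend
on true tertiary structure and forces.

## Numerical and interface conventions

* Degenerate inputs: empty sequences, non-IUPAC symbols, mismatched row
  lengths, underdetermined solves (k < 3) and empty trajectories raise
  `ValueError`; missing atoms raise an error listing every absence.
* Undefined statistics propagate as NaN internally and print as `NA`;
  no silent zeros.
* TSV and JSON outputs begin with a comment header (tool version,
  subcommand, parameters, seed). FASTA and coordinate outputs are
  header-free for interoperability; their parameters go to a JSON sidecar.
* All RNGs are numpy `default_rng` seeded explicitly; identical config +
  seed reproduces outputs byte-for-byte.
* Desk-scale experiment sizes (chosen to keep the full suite fast while
  leaving binomial error well inside the asserted bands): calibration
  200 families × 200 bootstrap replicates; regional recovery 50 families;
  trajectory properties 10–60 frames × 5–10 seeds.

## Design choices where the design was open

* Exact signal/prosegment/mature column boundaries are not published;
  defaults (1–19 / 20–64 / 65–end) are inferred from fragment labels and
  configurable everywhere.
* Whether published scans excluded Ks = 0 pairs is unrecorded; they are
  excluded from the ratio mean here (a pseudo-count alternative was
  rejected as less transparent), and reported pair counts make the
  exclusion visible.
* Whether the colobus 13-mer variant undergoes the same 3-residue trim is
  unrecorded; `excise_nonapeptide` is strict about 12-residue input and the
  variant motif is validated independently.
* The k = 3 star solve uses the generic least-squares route (identical to
  the closed form at machine precision), keeping one code path for all k.
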