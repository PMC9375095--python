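# Methods

This note documents the models implemented in `molboolean`, their
assumptions, the default parameters and the reasoning behind the design
choices that were genuinely open.

## 1. Sequence model of the assay DNA logic

**Coordinates.** All intervals are 0-based and half-open. Circle positions
are taken modulo the circle length with the first base of circle part 1 as
origin; a nick at inter-base position *p* severs the backbone between bases
*p−1* and *p*.

**Circle assembly.** The two 5′-phosphorylated circle parts (114 + 79 nt)
are ligated head-to-tail into a sealed 193-nt circle. The ligation template
that juxtaposes the parts' ends is not modeled: assembly trusts the role and
phosphate flags. Sealed circles survive the simulated exonuclease clean-up;
linear oligos and open circles do not.

**Hybridization.** `find_complement_match` returns the longest exact
reverse-complement match between a query and a target, optionally anchored
at the query's 5′ or 3′ terminal base. Thermodynamics, mismatches and
melting temperatures are out of scope — matches are exact string
complementarity, which is the level at which the design logic operates.

**Arm footprints and nicking.** Each arm binds the circle in *two* exact
complementary segments flanking the arm's tag-complement loop; the duplex
footprint is therefore computed as the union of all maximal exact
reverse-complement matches of at least 10 nt (the threshold excludes
spurious short matches such as poly-A tails, and is configurable). On the
packaged design the footprints are circle[62, 102) for arm A and
circle[12, 53) for arm B. The nickase is modeled purely as motif logic:
a nick is emitted wherever a footprint contains `GTCTC` read on the circle
strand, cut one nucleotide 3′ of the motif — so the cut always falls on the
circle, never the arm. The motif occurs exactly twice on the circle
(positions 27 and 72), yielding one nick per arm: inter-base 33 (arm B) and
78 (arm A). The enzyme's published recognition geometry fills the gap left
open by the schematic description of the nick position; motif and offset are
exposed as parameters.

**Tag incorporation.** Each nick remembers the arm that templated it. A tag
can seal a nick only when (i) it is offered, (ii) it carries a 5′ phosphate,
and (iii) its reverse complement lies in that arm's loop region (cognacy).
Sealing inserts the literal tag sequence at the nick — the tag strand has
the same sense as the circle strand — so downstream sequence-level checks
(tag copy number in the concatemer, detection-oligo hybridization) hold
exactly. A circle left with any open nick is non-amplifiable. The
strand-displacement chemistry of the invasion is deliberately not modeled
beyond this bookkeeping; read-out only needs tag content.

**Amplification.** RCA of a sealed circle yields `n_repeats` tandem copies
of the circle's reverse complement read once around from the origin; the
concatemer then contains one reverse-complement copy of each incorporated
tag per repeat, which is exactly what the fluorophore-labeled detection
oligos (DNA body identical to the tag, 3-base U tail recorded as metadata)
hybridize to.

**Padlock control.** A padlock circularizes iff both terminal footprints on
the arm are stable duplexes (≥ 10 nt) and the arm bases pairing the
padlock's two terminal bases are immediately adjacent — no gap, no overlap.
The resulting circle is the padlock's own 99 nt and contains the full tag
sequence reconstituted across the ligation junction; it can only ever carry
one tag, which is what makes it a single-reporter null control.

**Padlock footprint arithmetic.** The published design describes 25-nt (5′)
and 24-nt (3′) arm-complementary ends joined by a 50-nt linker. Recomputing
from the printed sequences, the *longest* 5′-anchored match of padlock A on
arm A is **26 nt**: the first linker base happens to complement the arm base
adjacent to the designed footprint (and symmetrically, padlock B's longest
3′-anchored match is 25 nt). The designed statement remains true — the first
25 nt *are* complementary — it is just not maximal. Both padlocks' two
footprints tile exactly 50 adjacent arm bases, and the longest-match linker
is 49 nt. The package reports the computed longest-match values and the test
suite records both readings explicitly.

## 2. Stochastic assay simulator

The simulator turns a ground-truth molecule population into rendered
microscopy fields through an explicit molecular cascade; every stage is a
Bernoulli draw with its own named random substream (placement, binding,
efficiency, rendering) derived from one master seed.

**Geometry.** Cells are ellipses on a jittered grid (guaranteed
non-overlapping or an error), each with a nucleus, a cytoplasm and a
membrane band (the outer ring of the cytoplasm, default 4 px). Defaults:
100 nm pixels, nucleus semi-axes 28–34 px (5.6–6.8 µm diameter), cytoplasm
2.8–3.2× the nucleus (cell diameter ~15–22 µm) — a typical adherent cell at
a magnification where RCPs are countable dots. Simulation is 2-D (a single
focal plane); z is ignored.

**Population.** Default 15 free A + 15 free B + 20 complexes per cell
(complex fraction 0.4, ~50 signals/cell — a countable density typical of
the per-cell RCP counts the assay produces), all cytosolic; a
junction-forming pair is emulated by directing complexes to the membrane
band. Per-cell counts are either exact or Poisson-distributed around the
means (cell-to-cell biological variability).

**Molecular cascade (mode `molboolean`).** Writing pA, pB for the epitope
occupancies, en = e_circle·e_nick, et = e_tag, el = e_ligate·e_rca, and q
for the probability that the epitope separation (uniform on [0, s_max],
default s_max = 20 nm) is within the proximity threshold (default 40 nm,
secondary probes; 30 nm for primary):

- free molecule → singleton event with probability `occ · en·et·el`;
- complex, both probes bound and proximal (`pA·pB·q`): each arm's nick forms
  with probability en; each formed nick seals with probability et; **a
  formed but unsealed nick voids the circle** (no event), exactly mirroring
  the sequence model's sealing semantics. Dual event: `(en·et)²·el`;
  single-A event: `en·et·(1−en)·el`;
- complex with exactly one engaged probe (one bound, or both bound but
  distal — the circle then engages either arm with probability ½): the
  single-arm path `en·et·el`. This choice keeps every molecule contributing
  at most one event; which arm the circle engages first is not specified by
  the assay description.

All efficiencies default to 1 (the enzymatic steps are highly efficient;
each is an explicit knob). `expected_fractions` evaluates these expressions
in closed form and is the oracle for the Monte-Carlo agreement tests; at
pA = pB = 0.8 and unit efficiencies the dual probability is 0.64.

**Modes `pla` and `padlock`.** In situ PLA emits an event only for
dual-bound proximal pairs (probability `pA·pB·q·e_circle·e_ligate·e_rca`),
rendered in a single reporter channel — free proteins are invisible. In
padlock mode every bound probe independently emits its own singleton with
probability `e_circle·e_ligate·e_rca`; a complex can therefore emit two
spatially distinct singletons but never a dual.

**Rendering.** Channels are (nuclear, detection A, detection B). Each RCP
is an isotropic Gaussian spot (PSF σ default 120 nm, emulating the
sharpened effective PSF of the deconvolved images this class of pipeline
consumes). Spot brightness is `amplitude_mean · size_factor ·
channel_factor` with lognormal factors: the size factor (σ 0.35) is the
RCP ball size and is **shared** between the two channels of a dual-tag RCP
(one concatemer carries equal numbers of A and B tag copies, so its two
colors are tightly coupled), while the per-channel label factor (σ 0.10)
models dye/labeling variability. Every RCP is displaced from its source
molecule by isotropic Gaussian jitter (σ 150 nm — the ~0.5–1 µm product
ball settles around its anchor); when two RCPs share one source molecule
(padlock mode) the balls exclude each other sterically and are placed
back-to-back at a truncated-normal separation (mean 600 nm, σ 150 nm,
≥ 0) — this is what physically separates the padlock control's two colors.
Noise is Poisson shot on signal + background (default 10/50/50 counts per
channel) plus Gaussian read noise (σ 3), giving peak SNR well above 10 at
the default amplitude (600 counts).

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: tissue morphology, autofluorescence and
structured background, optical sectioning and aberrations, photobleaching,
antibody cross-reactivity patterns beyond a flat occupancy, RCP size/shape
irregularity beyond a lognormal brightness, and 3-D spot overlap. Recovery
results on simulated fields bound the pipeline's algorithmic error, not its
robustness to those real-world effects.

## 3. Quantification pipeline

A faithful re-implementation of the CellProfiler-style analysis:

1. **Nuclei** from the nuclear channel: Gaussian smoothing (σ 3 px),
   two-class Otsu (three-class for the PLA variant, middle+high classes as
   foreground), hole filling, declumping by watershed seeded at intensity
   maxima at least one minimum nucleus diameter apart, then a diameter gate
   (default 40–110 px). Labels are renumbered in raster order of their
   centroids so output is deterministic.
2. **Cells** by expanding each nucleus up to N px (default 90), contested
   pixels to the Euclidean-nearest nucleus, ties resolved deterministically.
3. **Speckle enhancement** per detection channel: white top-hat with a disk
   of radius `feature_size` (default 5 px) — image minus its opening —
   removing slowly varying background while preserving spots.
4. **Spot detection**: threshold (default `robust_background` = trimmed
   background mean + k·sd with k = 4; global Otsu is unstable when the
   foreground fraction is tiny, so the noise-floor estimate is the default,
   as in single-molecule FISH practice; two-class Otsu and manual levels
   remain options), watershed declumping seeded at maxima ≥ min spot
   diameter apart, then the spot diameter gate (default 1.5–10 px).
5. **Consolidation**: each spot shrinks to its centroid and regrows to a
   disk of radius B (default 1 px, comparable to the PSF σ so that
   co-centered dual spots always merge while neighbours resolved by ≥ 2 px
   do not); overlapping disks across (or within) channels merge into one
   RCP object carrying channel provenance.
6. **Masking and assignment**: objects whose centroid lies outside every
   cell are removed; the rest take the cell label under their centroid.
7. **Classification**: per-object mean intensity over the object mask in
   each raw channel; background cutoffs default to the per-channel Otsu
   level over non-spot pixels (manual cutoffs available); in the
   background-subtracted plane clipped at zero, the polar angle
   φ = atan2(I_B′, I_A′) bins objects with angle bounds (30°, 60°). The
   angled rule — two half-lines through the background-offset origin — is
   the simplest geometry consistent with binning all three signal classes
   by their two-channel intensities; both angles are knobs. Objects at the
   origin are discarded as background.
8. **Per-cell summaries**: class counts, totals, and fractions normalized
   by the total signal per cell (zero-spot cells flagged with undefined
   fractions); frame-level pooled percentages for tissue-style reporting.

The single-channel PLA variant runs steps 1–4 and 6 on one signal channel
and reports per-cell counts only.

**Known limitation.** Two RCPs closer than the effective resolution
(~2–3 px ≈ 200–300 nm) merge into one object; an A and a B singleton that
merge are miscalled as a complex. This chance-colocalization inflation
grows with spot density (the test suite measures it on all-singleton
simulations and asserts its monotonicity) and is the reason the default
study conditions keep ~50 RCPs per ~17 µm cell. At that density the
pipeline recovers the complex fraction to ~1 pp and per-cell class counts
at r ≈ 0.96 (100 cells); both margins degrade at higher density.

## 4. Statistics

- **Rank-sum test**: two-sided Wilcoxon–Mann–Whitney with mid-ranks for
  ties. Below 20 observations per group (configurable) the exact
  permutation distribution of the rank sum is computed by a
  generating-function dynamic program over doubled mid-ranks (exact under
  ties; counts stay below 2⁵³ so float64 arithmetic is exact), with
  two-sided p = 2·min(tails) capped at 1. At larger n, the normal
  approximation with tie correction and an optional 0.5 continuity
  correction (on by default; whether the original analysis used it is not
  stated, hence the flag).
- **Kruskal–Wallis + Dunn**: tie-corrected H against a χ² reference
  (scipy), Dunn pairwise z from pooled mid-ranks with tie correction, and
  Bonferroni adjustment p_adj = min(1, p·m) over all m pairwise
  comparisons.
- **Box summaries**: quartiles by linear interpolation between order
  statistics (one of several textbook conventions; fixed and documented),
  whiskers at the most extreme observations within 1.5 IQR of the
  quartiles, outliers beyond.

## 5. Problem sizes used in the test suite

The recovery study runs four 1120×1120 px fields of 25 cells each
(100 cells, ~50 RCPs/cell, Poisson per-cell counts); Monte-Carlo agreement
checks use 10⁵–10⁶ molecules; the statistics calibration uses 1000 null
replicates at n = 50 per group. These sizes give 3-SE Monte-Carlo margins
and stable correlation estimates while keeping the full suite in the
minutes range on one CPU.
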