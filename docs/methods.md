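# Methods

This note records the models, parameter choices and numerical decisions
behind repeatspan, and what the synthetic-data tests do and do not show
about real sequencing data.

## Coordinates and domain types

All reference coordinates are 0-based half-open; configs may declare
`coordinate_system: 1-based` and are converted on load. A locus consists
of a motif (e.g. GGGGCC), a reference repeat span, and two flanks
(default 100 nt) immediately adjacent to the repeat. Flanks must not
contain two consecutive motif copies — anchoring correctness depends on
the flanks being unambiguous against the repeat, so this is a hard
validation. Reads may contain N; motifs and flanks may not.

## Alignment primitives

Local (Smith–Waterman), global (Needleman–Wunsch) and Levenshtein DP
with linear gaps, implemented with a per-row running-maximum scan so a
row costs a handful of vectorized operations. Scoring defaults are
match +2, mismatch −3, gap −4. These only rank alignments: the
accept/reject decision for anchors is an identity threshold, so the
scheme is not load-bearing beyond determinism. Linear rather than
affine gaps keeps the brute-force oracles (exhaustive substring-pair
enumeration for local, plain-python recursion for global) tractable;
the test suite checks score equality on 1000+ random pairs.

Tie-breaking is deterministic: among equal-score local end points the
alignment with the smallest query start (then target start) is
reported, and traceback prefers diagonal over deletion over insertion
moves. `identity` is matches / total alignment columns, gap columns
included — the strict reading of a "percent similarity" threshold.

## Flank anchoring

Both flanks are locally aligned against the read in both orientations;
the orientation with the larger total passing-anchor score wins (ties
go to forward). An anchor **passes when at least `min_identity`
(default 0.85) of the flank's bases are matched** (n_match /
flank_length). Measuring against the full flank length, not the local
alignment's column count, is deliberate: a local alignment trimmed to a
clean sub-island always has island identity ~1.0, which would make any
threshold on island identity vacuous. Under the 85% rule, mutating 20
of 100 flank bases reliably kills the anchor.

Local alignments also trim low-scoring ends, so an error just inside a
flank would leave a few flank bases inside the measured region. The
repeat-region boundary therefore projects the trimmed inner flank bases
back onto the read: `up_edge = query_end + (flank_len − target_end)`
and symmetrically for the downstream anchor. On error-free reads this
is a no-op; at a ~7% error rate it removes a +5–15 nt bias on short
alleles that would otherwise push wild-type reads past the near-window.

Spanning calls measure the region exactly; single-anchor calls report
the distance from the anchor's inner edge to the read end facing the
repeat, a lower bound on the true repeat length. Anchors in the wrong
order reject the read as off-target; overlapping anchors (possible for
0–2 unit alleles under deletion errors) clamp the region to 0 nt with a
diagnostic flag rather than rejecting the read.

Unit conversion is round-half-up: `units = floor(nt/m + 0.5)`, computed
in integer arithmetic. Allele classes for spanning calls: exact
(repeat_nt equals wildtype), near (within 6 nt), expanded (longer than
wildtype + 6 nt). Backbone binning reuses the local aligner with a
lower default threshold (0.75 of tag bases matched) and assigns by best
score, leaving ties unassigned.

## Composition

SSR scanning reports maximal perfect tandem tracts (primitive units
only, canonical = lexicographically smallest rotation, default minimum
tract 12 nt); overlaps are resolved longest-first with trimming, so an
interruption splits the surrounding tract rather than swallowing it.
Motif counting is per unit and non-overlapping: a tract of k
uninterrupted units contributes k occurrences. The left-to-right scan
first matches the motif exactly, then — so single-edit interruptions
(a lone GGGCC between GGGGCC tracts) are counted rather than skipped —
substrings within edit distance 1 of the primary motif. When no motif
list is supplied, the primary motif is discovered from tract coverage
and spelled in its dominant rotation (GGGGCC, not CCGGGG), which keeps
distance-1 collapsing meaningful.

Collapsing pools every motif within Levenshtein distance k (default 1)
of the canonical motif; the occurrence total is preserved, everything
else pools into "other".

Per-read error rates: the extracted region is compared against an
idealized repeat of the same nucleotide length, tiled from the motif at
whichever of the m phases maximizes ungapped matches (cheap and
deterministic; a full alignment per phase would be 6× the cost for no
observed difference), then globally aligned; the error rate is
(mismatches + insertions + deletions) / columns.

The phase consensus folds each region into motif-phase columns. Rather
than slicing consecutive m-nt frames — which loses phase at the first
indel and converges every column to a G/C blur — each region is
globally aligned to its idealized repeat and every aligned base is
assigned the motif column of its ideal position (indel
re-synchronization). On indel-free input this reduces exactly to
consecutive-frame folding. A column's IUPAC code covers the bases at
frequency ≥ 0.2: chosen so a systematic ~40% miscall produces ambiguity
codes while sporadic <20% noise does not. In `consensus_accuracy`,
ambiguity codes count as errors unless the symbol literally equals the
truth base — a consensus that can only say "G or A" has not called the
base; this is why a systematically miscalled consensus scores near
1/6 per unit rather than near 1.

## Distributions and assay conversions

Expanded-class repeat-unit counts are density-estimated with a Gaussian
KDE, Silverman bandwidth. Modes are local maxima above 5% of the peak
density (suppresses noise modes; no principled criterion exists for
"how many modes", so the floor is documented rather than hidden).
"PDF percentiles" are quantiles of that KDE via trapezoidal CDF
inversion on a 4096-point grid. A degenerate (single-valued) expanded
class returns that value as mode and all percentiles, flagged.

Southern and fragment conversions subtract a fixed flanking
contribution and divide by the motif length. The shipped constants
(2302 bp for the Southern restriction fragment, 117 bp for the
fluorescent-PCR amplicon) are the documented defaults for the C9orf72
G₄C₂ assay designs, derived once from the assay geometry and always
overridable; on integral unit counts `fragment_to_repeats` and
`repeats_to_fragment` are exact inverses.

## Simulator

Reads are built as flank_up + motif×units + flank_down and then
distorted. Per base: deletion with p_del; otherwise a G/C is miscalled
as A with `gc_to_a_bias`, else substituted uniformly with p_mismatch;
after each emitted base an insertion (uniform base) occurs with p_ins.
Strand flips with probability 1/2. Truncation is a geometric per-unit
hazard — the simplest mechanism consistent with a polymerase that
fails, per unit, with constant probability — so read-through
probability is (1−h)^units; a truncated read keeps its completed units
and loses the downstream flank. Loading bias reweights allele draws by
(fragment length)^−β via rejection sampling.

Platform presets (these are the study conditions, fixed once):

| preset | p_mismatch | p_ins | p_del | gc→a | hazard h |
|---|---|---|---|---|---|
| PacBio RS II-like | 0.014 | 0.04 | 0.02 | 0 | 1 − 0.438^(1/774) |
| ONT MinION-like | 0.02 | 0.05 | 0.05 | 0.42 | 1 − 0.835^(1/774) |

The error rates were calibrated once so the *measured* NW median over
simulated expanded repeats reproduces the platform medians (7.4% and
47.3%); note the measured rate differs from the naive sum of the
generative probabilities because indels in a periodic sequence
partially cancel in the optimal alignment. Hazards solve the
read-through fractions observed for a 774-unit construct (43.8% and
83.5%). A single geometric hazard cannot match read-through at every
length simultaneously (it gives ~63.7% at 423 units where ~66.8% was
observed); the residual is an accepted limit of the one-parameter
truncation law. The targeted-enrichment preset (`noamp_config`) uses
allele weights 0.13 / 0.06 / 0.81 over {2 units, N(110,15), N(870,80)}
with β=1, solved so that after loading bias and truncation the spanning
read mix is ~84% wild type / ~16% expanded with both expansion modes
populated. Quality strings are constant placeholders; nothing consumes
them.

At the ~47% ONT-like error rate the 85% anchor rule rejects everything
(as it should — that rule belongs to high-accuracy consensus reads);
analyses of ONT-preset data anchor at `min_identity = 0.5`.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the pipeline relies
on: mosaic allele mixtures, indel-dominated vs miscall-dominated error
profiles, length-dependent truncation, loading bias, strand symmetry.
It does not model signal-level artifacts, basecaller-specific error
correlations (errors here are i.i.d. per base), homopolymer-length
biases, chimeras, or methylation. Passing tests therefore demonstrate
the correctness of the measurement and summary machinery under
realistic noise magnitudes, not platform fidelity. Two systematic
effects worth knowing: the PacBio-like preset's net insertion excess
(+2% length) inflates measured repeat sizes by the same factor, so mode
locations through the error-bearing pipeline sit ~2% above the true
allele; and KDE mode estimates carry the usual smoothing-plus-sampling
noise (a few units at n≈500).

## Problem sizes

Defaults used by the test suite and `scripts/acceptance.py`: alignment
oracle equivalence on 1000 random pairs of length ≤12; error-rate
medians over 20–30 reads of 150–774 units; read-through fractions over
300–800 reads per unit count; class recovery and mode estimation on 500
reads; consensus checks on 15–20 reads of 80–100 units. These sizes put
every binomial or KDE check comfortably inside its sampling tolerance
while keeping a full run to a couple of minutes.
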