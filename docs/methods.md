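# Methods

This note documents the models behind `domyseq`: what the simulator
assumes, which parameters matter and why they default the way they do,
how the analysis stages are defined numerically, and what simulated
results do and do not say about real screens.

## Coordinate conventions

Nucleotide intervals are 0-based half-open and circular: positions are
normalized mod plasmid length and substrings are taken from the doubled
sequence, so the origin needs no special cases. All user-facing residue
intervals are 1-based inclusive ("aa 58 to 128"), and the width of an
inclusive interval is `end − start + 1`. The reading-frame rule, the
residue-span rule and SAM's 1-based POS each have a single implementation
point to prevent off-by-one drift.

## The fragment-library model

**Shearing.** Fragment start positions are uniform on the circle;
lengths are truncated-normal with mean equal to the shear-fraction centre
(200/350/500/700/1000 bp presets) and SD = 25% of the mean, floored at
100 bp. The broad SD reflects acoustic shearing: a nominally 350-bp
library carries real mass down to ~200 bp, and that short tail is what
lets fragment *ends* approach a binding-domain boundary closely. A tight
(±10%) spread would make sharp-edged domains irrecoverable even at
saturation. Cloning orientation is uniform on {+, −}.

**Frame classes.** A fragment's class is determined by the offset of its
leftmost base on the ORF codon grid, `(start − cds_start) mod 3`, and its
strand; the native-frame offset carries the label `+2` by convention
(the label map is configurable bookkeeping; negative labels mean reverse
strand). On plasmids whose length is not a multiple of 3, a fragment
whose path from cloning junction to the motif crosses the origin shifts
frame along the way; the selection model treats such fusions as
untranslatable, which is the physically correct behaviour.

**Selection.** A fragment is selected *by binding* iff it is in the
coding class, its translation from the junction reaches the last residue
of the true binding interval without a stop codon (backbone sequence
upstream of the CDS can contribute stops), its residue span — complete
codons only — contains the whole true interval, and it does not touch the
forbidden interval (if any). This full-coverage rule is the
high-stringency (LTHA-like) default; `coverage_stringency` > 0 admits
partially covering fragments with that probability, emulating leakier
(LTH-like) selection. Self-activation: an in-frame, stop-free fragment
containing a transactivating interval is selected with probability
`tad_penetrance` regardless of the bait. Background: any fragment is
selected with probability `background_rate` (default 0). Growth skew can
be emulated with geometric per-clone copy counts (default off; duplicate
removal cancels it downstream anyway).

**Sequencing.** One 2×`read_len` (default 150 bp) pair per clone copy;
R1 is the cloned strand's 5' end, R2 the reverse complement of its 3'
end; reads truncate to short fragments. Errors are independent per-base
substitutions (no indels — at plasmid scale gapped alignment adds nothing
and substitutions already exercise mismatch tolerance). Qualities are
constant Q37 and never used analytically. Truth (fragment id, interval,
strand) travels in the read name.

## The analysis model

**Mapping.** Exact k-mer (default k = 21) seeding over the doubled
reference with up to four non-overlapping seed offsets per strand, then
full-length verification counting mismatches; hits with more than
`max_mismatches` (default 3) are discarded and ties for best are dropped
as ambiguous rather than placed randomly. A proper pair requires opposite
strands and a modular insert within `[min_insert, max_insert]` (default
`[20, mean + 6·SD]`); the fragment interval spans leftmost read start to
rightmost read end on the shorter arc. Same-strand and out-of-bounds
pairs count as singletons. External aligners are supported through SAM
import; export writes a minimal valid SAM dialect (1-based POS, NM tags,
pair/strand flags).

**Strata.** `All` = proper pairs including duplicates; `UniquePE` = one
representative per (start, end, strand), singletons excluded; `InFrame` =
UniquePE fragments in the coding class that overlap the CDS. Coverage
adds 1 per covered base (nt space) or per fully covered codon (aa space);
partial codons encode no residue and never count.

**Plateau calling.** With `max` the maximum of the InFrame aa track, the
primary call is the longest run of residues with depth ≥ τ·max (τ default
0.99; ties broken by higher mean depth, then leftmost). At saturation
the depth just outside a true plateau drops by roughly one clone per
fragment-end per position, so τ = 0.99 excludes the first flanking
residue once a few hundred clones are selected while tolerating small
mapping losses; at τ = 1.0 the call equals the exact intersection of all
selected spans (property-tested). Secondary calls are other plateau-tier
runs plus disjoint runs of ≥ 10 residues above `secondary_floor`·max
(default 0.5). Flank slopes are the residue distances from each plateau
edge outward to the first position at or below half of the plateau depth;
edges at the ORF boundary are reported boundary-censored. Calls are
advisory-annotated (never suppressed) as `possible_self_activation` when
they overlap a transactivation-motif hit.

**9aaTAD scanning.** Every 9-residue window of the ORF translation and of
all six frame translations of the whole plasmid is tested against a
position-class pattern (per position: an allowed or disallowed residue
set). The shipped default encodes an acidic anchor, a
hydrophobic/aromatic core and polar spacers; it is calibrated to match
the known transactivating peptide EVYQVTVYQ and to reject featureless
windows, and it *approximates* — it does not replicate — the published
9aaTAD web predictor, whose exact rules and stringency tiers are not
public. Vector-frame hits are annotated with overlapping backbone
features and back-projected to nucleotide intervals.

## Packaged scenarios

Each scenario synthesizes a ~9-kb circular plasmid (CDS at offset 2000)
with a random, in-frame stop-free ORF and plants the published mapping
interval as simulation truth; real nucleotide sequences are deliberately
not bundled, so nothing requires downloads.

| scenario | ORF (aa) | truth | extras |
|---|---|---|---|
| `craf_kras` | 700 | 58–128 | — |
| `craf_mek1` | 700 | 310–375 | forbidden interval 378–389 |
| `rgl3_rit1` | 750 | 614–695 | replicate seed emulates the second reporter system |
| `mdm2_p53` | 491 | 28–107 | EVYQVTVYQ planted at 274–282, `tad_penetrance` 0.15, secondary floor 0.4 |
| `unselected_control` | 700 | none | pre-selection library |

Two scenario-level calibrations deserve explanation. First, the MEK1-style
forbidden interval starts two residues beyond the binding edge: with ends
constrained to a 3·(gap+1)-nt window, a gap of 2 places half-maximal
coverage strictly between residues, making the sharp-3'-edge read-out
(right slope ≤ 2 aa) robust instead of a rounding coin-flip. Second,
deterministic self-activation by a 9-residue motif would admit ~3× more
clones than an 80-residue binding domain and the transactivation peak
would dominate the track; `tad_penetrance` models the evident fact that
weak transactivators fire the reporter only sometimes, and 0.15 keeps the
expected transactivation peak at ~60% of the binding plateau — visible
above the secondary floor but structurally below the primary.

## Randomness and reproducibility

One master seed per run; per-stage child streams (shear, selection,
growth, reads) are spawned deterministically from it, so stages are
individually re-runnable and identical config+seed gives byte-identical
artifacts (gzip members are written with zeroed mtimes; provenance
headers carry the seed and a path-independent config hash).

## What desk-scale simulations can and cannot resolve

The packaged runs use 50,000-fragment libraries, which select on the
order of 10²(free-ended domains) down to ~10 (forbidden-flank domains)
clones — about four orders of magnitude below a real saturating screen,
where ~10⁶ transformants put ~100 fragment ends on every position. Two
consequences, both visible in the test suite:

* **Edge granularity.** Exclusion of the first flanking residue at
  τ = 0.99 hinges on a handful of clones ending exactly at the domain
  boundary (a Poisson(~3) count at this scale), so a called edge can
  overshoot truth by one residue on an unlucky seed. The recovery tests
  pin exact intervals at the packaged seeds; across seeds the edges are
  exact-to-±1.
* **Order-statistic creep at forbidden flanks.** When a forbidden flank
  pins all fragment ends to a few positions, the opposite plateau edge is
  set by the *shortest* selected clone, and with ~10 clones that edge
  sits several to tens of residues beyond truth. Exact width recovery for
  such domains genuinely requires saturating library sizes; the simulated
  sharp-edge scenario therefore recovers the 3' boundary and the slope
  geometry but overshoots the 5' edge, and its width test documents this
  as a saturation limit rather than an algorithmic defect.

Similarly, at a 0.5% substitution rate a 150-bp read exceeds 3 mismatches
with probability 0.7% (binomial), so ~1.4% of pairs are unmappable under
the mismatch contract; exact-interval recovery of mapped pairs is
complete, but whole-library recovery tops out near 98.6%.

## What the simulator does not model

Mating efficiency, 3-AT titration and colony counting; reporter-chemistry
differences between Gal4- and LexA-based systems (represented only as
replicate seeds); PCR chimeras, index hopping, adapter read-through and
quality-score structure; indel sequencing errors; translational slippage
as a source of out-of-frame background (background is content-independent
noise). Passing recovery tests therefore validate the analytical chain
and the selection logic, not these wet-lab failure modes.
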