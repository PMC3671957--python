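# Methods

This note records the models, defaults and numerical choices behind each
stage, what the synthetic generators do and do not emulate, and the known
limitations.

## Coordinates and the binding map

All intervals are 0-based half-open internally.  External promoter tables
default to genome-browser style 1-based inclusive coordinates (`dialect=
"1based"`); true BED input is selected with `dialect="bed0"` / `--bed0`.
The conversion is exact and round-trips; rows whose external end does not
exceed their external start are rejected as empty in either dialect.

A cluster binds a promoter when their intervals share at least
`min_overlap_bp` bases (default 1 — no minimum-overlap fraction is imposed,
since binding-site calls and promoter boundaries are both coarse).  A
cluster overlapping two promoters counts for both; strand is carried but
ignored (ChIP-seq clusters are unstranded).  Per-promoter summaries report
`n_sites`, and the median / min / max of the overlapping cluster scores;
the median of an even number of scores is the mean of the two central
values.  Intersection runs on an interval tree; the test suite checks it
against an all-pairs scan on random instances.

## Differential expression

Intensities are non-negative linear-scale values.  The stage:

1. **Quantile-normalizes** columns: every sample receives the vector of
   cross-sample rank means; ties within a column get the mean of the
   reference values they span.  The operation is idempotent and makes all
   column distributions identical.
2. **log2-transforms** with a pseudocount (default +1).  The scale choice is
   a package default: array intensities are approximately log-normal and
   symmetric fold changes require a log scale.
3. **Collapses probes to genes** by the median of a gene's probes (default;
   per-probe testing is available).  With the generator's two probes per
   gene this is the probe mean.
4. **Tests each gene** with Welch's unequal-variance t-test,
   t = (x̄₁ − x̄₂)/√(s₁²/n₁ + s₂²/n₂), df by Welch–Satterthwaite, two-sided
   p.  Zero variance in both groups yields p = 1 for equal means and p = 0
   otherwise, by convention.  The default call uses the raw p ≤ 0.05 cutoff;
   Benjamini–Hochberg adjustment is an optional, clearly flagged extension.
5. Labels each significant gene `down_in_kd` or `up_in_kd` by the sign of
   the knockdown-minus-control log2 fold change.

Hierarchical clustering for heat-map ordering uses correlation distance
d = 1 − r and average linkage by default (single/complete configurable);
zero-variance items are rejected by name since their correlation is
undefined.  Leaf order is deterministic given the input order.

Small-sample behaviour worth knowing: with 3 replicates per condition the
Welch–Satterthwaite approximation is conservative — on ideal Gaussian nulls
the realized type-I rate at the 0.05 cutoff sits near 0.035–0.04 rather
than 0.05 (the calibration tests compute exactly this fraction).  This is a
property of the test itself at n = 3, not of the implementation, and it
vanishes as replicates grow.

The comparative-Ct helper returns 2^−ΔΔCt with
ΔΔCt = (Ct_target − Ct_reference) in condition A minus the same difference
in condition B; ΔΔCt = 3 is an 8-fold reduction.

## Enrichment

The 2×2 overlap (universe N, bound K, selected n, selected∩bound k) is
tested one-sided for over-representation: p = P(X ≥ k) with
X ~ Hypergeometric(N, K, n), evaluated through a log-gamma-stable survival
function (safe for counts up to ~10⁶).  The default universe is
promoter-level, since promoters are the units the binding scan produces;
a gene-level universe is available by flag.  A permutation cross-check
draws n-subsets uniformly (by ranking i.i.d. random keys — deliberately not
a hypergeometric sampler) and reports the add-one-smoothed empirical tail.
In the pipeline, the DE→binding join key is the gene name and genes absent
from the binding table count as unbound; the report states this.

## Sponge simulation

The model asks how much duplex free energy an abundant transcript can
release by hybridizing a panel of miRs, relative to chance.

**Site discovery.** Candidate windows are positions where the transcript is
exactly antiparallel-complementary to the miR seed (positions 2–7 by
default, Watson–Crick only unless G·U is enabled for the seed).  Each
window extends the seed match to the full miR length plus a bulge margin
(default 4 nt) on both sides, clipped at the transcript ends and capped at
40 nt.

**Energy model.** A duplex structure is a set of non-crossing intermolecular
pairs (transcript index ascending while miR index descends).  Its energy is
one initiation penalty plus, for each consecutive pair of pairs: a
nearest-neighbor stacking energy when adjacent on both strands, or an
affine penalty — `bulge_open + bulge_extend·(L−1)` for a one-sided gap of
length L, `internal_open + internal_extend·(a+b−2)` for a two-sided gap —
with each strand's gap capped at `max_loop` (default 10).  The empty
structure (ΔG = 0) is always admissible.  A dynamic program over (last
transcript index, last miR index) returns the minimum; ties prefer more
paired bases, then the 5'-most first paired base.  Intramolecular structure,
dangling ends, terminal-AU corrections and target-site accessibility are
deliberately outside the model.  The test suite validates the DP against
exhaustive enumeration of all non-crossing pairings for short sequences.

The shipped parameter file uses the published Watson–Crick nearest-neighbor
stacking free energies (Xia et al. 1998 ΔG°37, e.g. 5'GC/3'CG = −3.42
kcal/mol) with duplex initiation +4.09 kcal/mol; G·U wobble stacks carry
representative mild values.  All tests asserting exact energies use a
uniform toy parameter set (every stack −1, init 0) so no external constant
is load-bearing.

**Scoring and null.** "Energy released" per miR is −ΔG of its best site,
clipped at 0; a transcript's sponge score is the sum over the miR panel.
The null re-scores `n_shuffles` (default 100) uniform permutations of the
region's bases — exact mononucleotide composition preserved; an
Altschul–Erickson dinucleotide-preserving shuffle is available as a
stricter option — and reports empirical p = (1 + #{null ≥ true}) /
(1 + n_shuffles) plus z = (true − null mean)/null sd.  The full transcript
and, when given, the 3'UTR slice are scored and shuffled independently.
MiRs are scored as given; a `--both-orientations` flag adds each miR's
reverse complement to the panel (sense vs antisense contrasts).

## Synthetic generators

All generators are pure functions of their config (seed included); each
uses its own deterministic substream, so bundles are byte-identical across
runs.  Defaults are set at the study's scale: 781 promoters with bound
fraction 160/781, 17.5% of promoters driving 2–6-gene clusters, cluster
scores uniform on [100, 1000]; a 72-gene DE fraction split 63 down : 9 up,
log2 effect 2.0, noise sd 0.5, 3 replicates per condition, 2 probes per
gene; a 4300-nt transcript with one planted reverse-complement site per miR
for a 9-miR panel, 70% of sites biased into the final 30% (the "3'UTR").

`gen_coupled_study` links binding truth to expression truth: 60% (38/63) of
planted-down genes are drawn from bound promoters, so the pipeline's
end-to-end enrichment is of known strength.  `gen_expression` alone keeps
binding and expression independent, which is what a null calibration needs.

What the generators do **not** emulate: read-level ChIP-seq signal and peak
calling, array scanner artifacts and batch effects, probe-specific affinity
(both probes of a gene are exchangeable), correlated noise across genes,
secondary structure in the transcript background (bases are i.i.d.), and
miR families with shared seeds.  Passing tests therefore demonstrate the
correctness and calibration of the computations, not robustness to those
real-data complications.

## Problem sizes used in the tests

The suite exercises the stages at reduced but statistically meaningful
sizes: intersection vs the all-pairs oracle on ≥100 random instances of up
to ~40 promoters × 120 clusters; hypergeometric tails vs enumeration for
every universe ≤ 12; the duplex DP vs enumeration on 200+ random pairs of
length ≤ 8 under three parameter sets; type-I calibration on 2000-gene null
matrices; sponge nulls on 400–700-nt transcripts with 2–3 miRs and 20–100
shuffles; the coupled end-to-end study at the full 781-promoter scale.

## Known limitations

* The duplex energy model is intermolecular-only and loop-capped; absolute
  ΔG values are not comparable to full secondary-structure folders, only
  the true-vs-shuffle contrast is interpreted.
* The permutation enrichment test materializes random keys per iteration;
  for very large universes (≫10⁴) prefer the analytic tail.
* Welch calls at 3 replicates are conservative (see above); direction
  labels near the cutoff are correspondingly cautious.
* The quantile-normalization compensation effect — with many genes planted
  down, null genes drift slightly up after normalization — is visible in
  the end-to-end demo's up-regulated count and is inherent to the method,
  not a defect of the generator.
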