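# tfmir

Tools for asking how a constitutively active transcription factor shapes
microRNA expression, modelled on the STAT3/CLL setting: STAT3 is
constitutively phosphorylated in chronic lymphocytic leukemia cells, and its
knockdown perturbs the levels of dozens of miRs. `tfmir` reimplements the
computational side of that analysis as a tested, reusable pipeline over four
stages, each usable as a library module or a CLI subcommand:

1. **Promoter binding map** (`tfmir.promoter_binding`) — intersect putative
   miR promoters (H3K4me3-defined intervals, possibly driving 2–6-gene
   pre-miR clusters) with ChIP-seq binding clusters scored 0–1000, and
   aggregate per-promoter `median (min–max)` score summaries.
2. **Differential expression** (`tfmir.diff_expression`) — quantile
   normalization, log2 transform, probe→gene collapse, per-gene Welch
   unequal-variance t-tests at a raw p ≤ 0.05 cutoff, correlation-distance
   hierarchical clustering, and a comparative-Ct (2^−ΔΔCt) qPCR helper.
3. **Enrichment** (`tfmir.enrichment`) — is binding over-represented among
   downregulated miRs?  For a universe of N promoters with K bound, n
   selected and k selected∩bound, the analytic tail is
   P(X ≥ k), X ~ Hypergeometric(N, K, n), cross-checked by a seeded
   permutation test.
4. **Sponge simulation** (`tfmir.sponge`) — can an abundant transcript
   sequester ("sponge") the miRs it is complementary to?  Candidate sites
   are found by antiparallel complementarity to the miR seed (positions
   2–7), scored with an intermolecular-only nearest-neighbor
   minimum-free-energy dynamic program, and the summed energy released
   (−ΔG of each miR's best site) is compared against base-composition-matched
   shuffled transcripts: empirical p = (1 + #{null ≥ true}) / (1 + n_shuffles).

A synthetic-data module (`tfmir.synthetic`) generates every input with known
ground truth — promoter maps with a controlled bound fraction, two-condition
expression matrices with planted log2 effects, transcripts with planted
miR-complementary sites — so the whole pipeline is testable without any
external download.

## Worked example

Reproduce the enrichment arithmetic from published-style counts — 781 miR
promoters, 160 with binding sites, 63 downregulated miRs of which 38 are
binding-positive:

```sh
$ tfmir enrich --universe 781 --bound 160 --selected 63 --selected-bound 38 \
      --iters 1000000 --seed 1
{
  "p_analytic": 4.179508999178116e-13,
  "p_empirical": 9.99999000001e-07,
  "fraction_pct": 60.317460317460316,
  "fraction_pct_rounded": 60
}
```

60% of the downregulated miRs carry a binding site, and the chance of an
overlap that large under random selection is ~4×10⁻¹³ analytically (the
permutation estimate is its resolution floor, 1/(10⁶+1)): binding and
knockdown response co-occur far beyond chance.

End-to-end on a synthetic study (781 promoters, planted 63-down/9-up truth
with ~60% of down genes on bound promoters, a 4.3-kb transcript with planted
sites for 9 miRs):

```sh
$ tfmir simulate --seed 1 --out bundle/
$ tfmir run-all --config config.yaml     # paths to the bundle + n_shuffles, seed
```

The run writes `report.json`; with seed 1 the key fields are

```
"binding_counts": {"bound_single": 145, "bound_cluster": 21, "unbound": 615}
"de_counts":      {"down_in_kd": 68, "up_in_kd": 41, "ns": 672}
"enrichment":     {"counts": {"n_universe": 781, "n_bound": 166,
                              "n_selected": 68, "n_selected_bound": 39},
                   "p_analytic": 7.5e-12, "bound_fraction_pct": 57.4}
"sponge":         {"full": {"true_score": 367.3, "null_mean": 52.6,
                            "empirical_p": 0.0476, "z_score": 17.2}}
```

The pipeline recovers the planted structure: ~21% of promoters bound, the
called-down list dominated by the 63 planted effects, 57% of called-down
genes on bound promoters (planted: 60%), and a transcript that releases
seven times more duplex energy against its 9 miRs than any of its
composition-matched shuffles.

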