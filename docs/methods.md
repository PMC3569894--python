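# Methods

## The ranking procedure

A candidate is one, two, or three compounds (unordered; identified by the
sorted, "+"-joined compound ids). Two annotated target profiles are built
per candidate:

1. **Knowledgebase-side profile** — the union of (a) knowledgebase and
   bioassay predictions for the candidate's compounds that pass the
   confidence filter (high/medium/low; all three included by default — the
   confidence labels never weight the score, they only gate inclusion) and
   (b) docking records with inhibition constant Ki strictly below the
   10 μM cutoff. Mixture profiles are set-unions of member profiles: a
   protein bound by two constituents appears once. The overlap itself is
   captured separately as *comm*, the number of proteins shared by at
   least two constituents.
2. **Docking-side profile** — the Ki-screened docking hits restricted to
   the forward-docking panel of N proteins (default N = 59).

Counts over each profile — Ac (cancer-related), Am (AML-related), Ah
(hub) — feed

    Cscore     = w_c·(Ac − (Am + Ah)) + w_a·Am + w_h·Ah − w_m·comm + sp
    Dscore     = [w_c·(Ac − (Am + Ah)) + w_a·Am + w_h·Ah − w_m·comm] / N
    Combiscore = w_C·Cscore + w_D·Dscore

with defaults w_c = 0.2, w_a = 0.4, w_h = 0.3, w_m = 0.1, w_C = 0.6,
w_D = 0.4. The parenthesisation is kept exactly as published: the Am + Ah
counts are subtracted from Ac inside the cancer term (the residual may go
negative — e.g. an AML-flagged protein not flagged as cancer is subtracted
without ever having been added, and a protein that is both AML-related and
a hub is subtracted twice), then re-added at their own weights. sp enters
the Cscore once, outside the comm penalty; the Dscore has no sp term.
comm is computed per side: knowledgebase-side comm in the Cscore,
docking-side comm in the Dscore; the knowledgebase-side value is the one
reported on the score record.

**Selection** proceeds in tiers. All singlets are scored; candidates with
Combiscore greater than or *equal* to the tier threshold survive
(inclusive, deliberately: the published singlet cut kept a compound whose
score equalled the cutoff to printed precision). The threshold is the
tier's arithmetic mean Combiscore by default (`threshold_mode: mean`);
the published fixed cutoffs (1.36 / 4.25 / 6.15) are available as
`threshold_mode: fixed` for replication. Pairs are then enumerated under
the seed constraint and the process repeats, then triples.

The default seed constraint admits a pair/triple when **at least one**
constituent appeared in the previous tier's selection. The stricter "all
constituents selected" mode exists but contradicts the published results:
compounds that failed the singlet cut (limonene) still surfaced inside
selected pairs, which only the weaker rule permits. Ties in ranking are
broken lexicographically by candidate id, so output order is canonical and
runs are byte-reproducible.

## The Dscore divisor

The Dscore formula is sometimes quoted with divisor N−1. All thirteen
published singlet Dscores, however, are exact multiples of 0.1/59
(0.027118644 = 1.6/59, 0.054237288 = 3.2/59, ...), and no nonzero one
lies on the 0.1/58 grid — every Dscore numerator is a sum of integer
counts times weights that are themselves multiples of 0.1, so the product
dscore × divisor must land on that grid. `select_divisor_mode` implements
this consistency check; the package therefore defaults to divisor N, with
`n_minus_1` available as an explicit configuration mode.

Two published singlet Cscores (−10 twice, −1 once) are not derivable from
the formula with any plausible counts and sp ∈ [−1, 1]; they are carried
in the fixture as printed and flagged as an anomaly, not emulated, and no
sentinel or floor is injected by default. Likewise the mean of the 13
printed singlet Combiscores is ≈1.068, not the published 1.36 cutoff; the
pipeline always reports its own recomputed means, and fixed-threshold mode
is the surface for replaying the published cuts.

## Similarity clustering

The similarity threshold between two molecules is ST = |shared functional
groups| / max(group count), treating functional groups as a flat
presence/absence set (distinct labels, not occurrence counts; the original
hierarchical group schema is not public). Compounds cluster by single-link
transitive closure of the pairwise rule, which the published procedure
states as ST **≤** 0.7 — a low-similarity grouping rule, unusual for a
quantity called similarity. It is implemented as stated, with the
comparison direction configurable (`le` default, `ge` for conventional
clustering). Clusters whose member sets are subsets of another's are
merged to a fixpoint (equivalently: only maximal member sets are kept).
An empty fingerprint makes similarity undefined; such compounds are
excluded and reported, never silently clustered. Clustering is a
descriptive stage — its output does not feed the scoring formulas, which
the source never connects numerically.

## Pathway overrepresentation

For a target set of size n from a background of M proteins and a pathway
with K members overlapping the set in k, the one-sided p-value is the
hypergeometric upper tail P(X ≥ k) (Fisher's exact test for
overrepresentation; depletion is not tested). The background defaults to
the dataset's full protein universe. Raw p-values are always reported;
Benjamini–Hochberg adjusted values accompany them because many pathways
are tested, with no published adjustment to defer to. Candidate profiles
pool all confidence levels by default; per-level sub-profiles can be
tested by narrowing the screen's confidence filter.

## Synthetic data

The generators emulate the *statistical shape* of the original inputs,
which are proprietary (curated knowledgebases, a ~1,100-protein docking
database) or external (expression-derived hub calls). Defaults, chosen
once as field-plausible values:

| parameter | default | rationale |
|---|---|---|
| n_compounds | 13 | reference panel size |
| n_proteins | 800 | order of the curated target universes (~500–1,500) |
| targets_per_compound | 20–50 | ≈618 predictions across 13 compounds |
| confidence high/med/low | 0.25/0.15/0.60 | ≈ the reported 157/91/370 split |
| knowledgebase : bioassay | 0.73 : 0.27 | ≈ the 1,346 : 493 record counts |
| frac_cancer | 0.3 | a curated drug-target universe is cancer-enriched |
| frac_aml_given_cancer | 0.4 | AML annotations as a subset of cancer |
| frac_hub | 0.1 | hubs are by construction a small minority |
| ki_log10_range (μM) | (−2, 2) | docking Ki spans orders of magnitude, centred on the 10 μM cutoff (75% below it) |
| n_forward | 59 | published forward-docking panel size |

Ki is log-uniform because docking-predicted affinities span orders of
magnitude and no distribution is published; docking scores are a binding
free-energy proxy RT·ln(Ki) plus Gaussian noise (σ = 0.5 kcal/mol), so
score tracks −log10(Ki) monotonically in expectation. Inter-compound
target overlap is controlled by `overlap_rate`: each target draw comes
from a shared pool with that probability and otherwise from per-compound
private pools that are disjoint by construction (so overlap 0 ⇒ comm 0
for every pair). AML flags are generated only among cancer-flagged
proteins as a biologically coherent default, although the data model and
scorer deliberately do not assume that containment. All generators are
pure functions of the configuration; one global seed spawns an
independent deterministic sub-stream per generator.

`gen_scenario_planted` adds, for one or more chosen compounds, a block of
AML-related and hub cancer targets (defaults +10 AML, +6 hub) that no
other compound binds, as both high-confidence predictions and sub-μM
docking hits inside the forward panel. The planted compound's profile then
strictly dominates in Am and Ah, giving a known answer for recovery tests.

What the synthetic data does **not** emulate: real functional-group
chemistry (fingerprints are random label sets), correlated
protein–compound structure (draws are independent given the pools),
pathway biology (memberships are random), and the curation biases of real
knowledgebases. Passing recovery tests therefore demonstrates that the
pipeline's machinery is correct and monotone in the intended signals —
not that the scoring weights are biologically optimal.

## Numerical and degenerate-input choices

- sp of an empty profile is 0 (not an error): an empty candidate scores 0
  throughout rather than poisoning a tier.
- Ki screens are strict (<); a record at exactly the cutoff is excluded.
- Tier means are plain arithmetic means of the tier's Combiscores;
  selection is inclusive at the threshold.
- An empty tier enumeration (possible under the strict seed constraint)
  yields an empty tier result with NaN mean, and the cascade continues.
- JSON outputs serialise floats at 9 decimal places, the printed precision
  of the reference table; reruns with identical config and seed are
  byte-identical (timestamps live only in the manifest, and machine
  outputs embed a deterministic digest of config + seed + input hashes).
- Fixture comparisons use 5e-9 (printed values carry 9–10 significant
  digits, so blend round-off is bounded by ~2–3e-9).

## Problem sizes used in the shipped checks

The test suite and acceptance script run at the reference scale (13
compounds; 78 + 286 candidates) or smaller: property sweeps use universes
of ≤ 60 proteins for exact-enumeration Fisher oracles, ≤ 6 compounds for
the clustering oracle, and 20 seeds of the planted-recovery scenario at
the default 800-protein universe — sizes at which exact oracles are
computable and the whole suite completes in seconds.

## Known limitations

- The 92→95 merge of docking-derived and knowledgebase targets in the
  original study follows an ambiguous rule; this package uses plain set
  union, documented as an approximation.
- The published per-compound Ac/Am/Ah counts are not recoverable (the
  underlying knowledgebases are proprietary), so end-to-end replication of
  the published Cscores is out of reach; the packaged printed score table
  is the verification surface instead.
- Dose, pharmacokinetics (ADME) and toxicity are outside the scoring
  model; arities above 3 are unsupported by design.
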