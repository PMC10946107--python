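# Methods

This note documents the model behind `qnetdiff`, its tunable parameters,
the synthetic data used to validate it, and the numerical and design
choices that were genuinely open.

## Model and assumptions

The method treats each sample group as generating a *bacterial correlation
network*: taxa are nodes, and supra-threshold co-occurrence correlations are
edge weights. Three assumptions matter:

1. **Compositionality.** Relative abundances sum to 1 per sample, so naive
   correlations are biased. The default backend infers *basis* correlations
   (correlations of the unobserved absolute abundances) from pairwise
   log-ratio variances, assuming the true correlation structure is sparse —
   most taxon pairs uncorrelated. With few taxa (< ~20) or dense true
   correlation the sparsity approximation degrades; the backend is refused
   below 3 taxa, where the log-ratio system is degenerate.
2. **False correlations are taxonomically local.** Reads multi-mapped among
   close relatives inflate correlations only between taxa sharing a parent
   taxonomic category; that is why unification requires the shared
   `sup_category` *and* shared network cluster in both groups. A genuine
   ecological association between two same-family taxa that also co-cluster
   in both groups will be (wrongly) contracted — this is the price of the
   cleanup, and `--skip-contraction` plus the unified-group listing exist so
   users can audit it.
3. **Rewiring is informative.** The per-node score is the L1 distance
   between the node's weighted adjacency rows (equivalently weighted-union
   minus weighted-intersection). It deliberately conflates "edge appears/
   disappears" with "edge weight changes"; both are rewiring in this sense.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `edge_threshold` | 0.4 | correlation strictly above this becomes an edge weight (dimensionless correlation); lower keeps more, noisier edges |
| `p_threshold` | 0.005 | strict significance level for core selection; a conventional level, no multiplicity correction is applied (deliberate: the method screens candidates, it does not certify markers) |
| sparcc `iterations` | 20 | Dirichlet resamplings aggregated per correlation matrix |
| sparcc `exclusion_threshold` / `exclusion_rounds` | 0.1 / 10 | strongest-pair exclusion from the sparsity solve |
| sparcc `pseudo_count` | 1.0 | added to every count before resampling (zeros otherwise break log-ratios) |
| `contract_mean` | `edges` | contracted weight = mean of *existing* inter-group edges; `all-pairs` averages in zeros |
| `focus` | Y | group in which core taxa must be increased |
| `seed` | 0 | drives the Dirichlet resampling (group X uses `seed`, group Y `seed+1`) and Louvain tie-breaking |

Negative correlations are always dropped: they cannot exceed a non-negative
threshold, and no absolute-value option is offered.

## Numerical choices

* **Thresholding is strict** (`>`): an entry exactly at 0.4 is not an edge.
* **Basis-variance degeneracy**: a non-positive solved basis variance is
  replaced by the smallest positive one in that solve (it would otherwise
  poison the denominator of every correlation involving that taxon).
* **Aggregation across resamplings** is the element-wise median (robust to
  a single bad Dirichlet draw); the mean is available via `SparccOptions`.
* **Rank test**: exact permutation null when the smaller sample has ≤ 8
  observations and the pooled values are tie-free; tie-corrected normal
  approximation (with continuity correction) otherwise. The switch point
  only affects borderline taxa at small n.
* **Ties**: representative selection breaks mean-abundance ties
  lexicographically by taxon name; Louvain cluster ids are canonicalised by
  each community's smallest member; the score table breaks score ties by
  name. All three make runs bit-reproducible for a fixed seed.
* **Degenerate inputs**: all-zero sample columns and all-zero taxon rows
  (under the compositional backend) are errors naming the offender rather
  than silent drops; an empty core set is a *valid* outcome that yields
  empty networks and an empty score table with a warning.
* **Community detection** uses networkx's seeded Louvain implementation.

Contracted-edge averaging over existing edges only (the default) was chosen
because averaging in zeros would let sub-threshold pairs dilute genuine
correlations, and it preserves the invariant that every contracted weight
stays above `edge_threshold`. Similar-group membership is defined purely by
the equivalence key (parent category, cluster in X, cluster in Y); no
pairwise-edge requirement is imposed within a group, since co-membership in
a Louvain community already implies dense connectivity in practice.
Representative mean abundance pools the samples of both groups, which keeps
the choice symmetric between X and Y.

## Synthetic data

`qnetdiff.synthetic` generates paired count tables from log-normal latent
abundances (per-taxon mean log abundance ~ N(0, 1), per-sample log SD 1.0),
turned into counts by a multinomial draw at a uniform random depth of
20k–50k reads per sample. Planted structure, with defaults chosen so a
default run takes seconds and planted effects clear the 0.4/0.005 defaults
with margin:

* **one rewiring taxon**, sharing a latent factor (log-scale correlation
  0.9) with 4 partner taxa in group X and a disjoint 4 in group Y, and
  itself increased 4× in Y so it enters the core set;
* **two purely differential taxa** (4× in Y), each with two stably
  correlated partner taxa present in both groups — without any partner a
  differential taxon would be removed with the jointly isolated nodes in
  step 1 and could never become core, so stable partners are part of the
  planted design, not a convenience;
* **one sibling trio**: a single latent taxon's counts split multinomially
  (shares 0.40/0.33/0.27) among three genera assigned one family — the
  multi-mapping artefact the contraction step exists to remove;
* 40 taxa and 60 samples per group in total, the remainder independent.

What the generator does **not** emulate: 16S amplification or sequencing
error, chimeras, batch effects, overdispersion beyond the multinomial,
phylogenetically structured correlation, or uneven group sizes. Passing
recovery tests therefore shows the pipeline is correct and well-calibrated
under its own model assumptions — not that those assumptions hold for any
particular real dataset.

## Validation problem sizes

The acceptance checks use: 200 random weighted graph pairs (≤ 30 nodes) for
the scoring identity, 100 random 0/1 pairs for the unweighted equivalence,
100 random draws with n, m ≤ 6 against exhaustive permutation for the rank
test, 20 replicates of 20 taxa × 200 samples for correlation-backend
calibration, and 50 seeded default fixtures for end-to-end recovery. These
sizes give stable Monte-Carlo estimates while keeping a full validation run
in well under a minute on one CPU.

## Known limitations

* The contraction can merge genuinely co-occurring relatives (see above).
* `edge_threshold` is a blunt instrument: results can be sensitive near the
  default, and users comparing thresholds should expect edge counts to be
  monotone but cluster structure to shift.
* No multiple-testing correction on the core-selection p-values.
* Scores are only computed for core taxa and their neighbours; a strongly
  rewired taxon that is neither increased in the focus group nor adjacent to
  one that is will not appear in the output table.
* Exactly two groups; no longitudinal or multi-group designs.
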