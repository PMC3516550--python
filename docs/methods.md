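# Methods

This note documents the models, parameter choices and numerical conventions
behind `tiescore`, and what the synthetic experiments do and do not show.

## QTL and eQTL mapping

Scans use **marker regression**: at each marker the trait is regressed on
the genotype as a 3-level factor (2 df) on the mice complete for that
marker, and LOD = (n/2)·log₁₀(RSS_null/RSS_full). We deliberately do not
implement hidden-Markov interval mapping: with a dense marker set the
downstream logic consumes only peak markers and support intervals, and
marker regression vectorizes across thousands of expression traits and
permutations in a handful of matrix products. This is a documented
limitation for sparse maps or heavy genotype missingness, where interval
mapping would recover information between markers.

* **Missing genotypes** drop the mouse at that marker (complete-case per
  marker); they are never imputed. Markers with fewer than 10 complete
  observations, and monomorphic markers, get LOD 0.
* **Conditional scans** include a per-mouse covariate (e.g. a candidate
  mediator's expression) in both the null and full models.
* **Genome-wide thresholds** permute the trait across mice; the threshold is
  the ⌊α·(P+1)⌋-th largest of the P per-permutation maximum LODs, the
  conservative order-statistic quantile that gives exact finite-P validity.
  A single master seed drives all permutation streams.
* **Support intervals** are 1.5-LOD drops: the outermost markers within 1.5
  LOD of the chromosome peak. The interval rule is a declared convention,
  not an estimate of any published rule.
* The **pipeline selects the top two chromosome peaks** of the trait scan as
  the two study loci (with the genome-wide threshold recorded alongside),
  mirroring the design of focusing on a trait's strongest locus pair; the
  threshold-gated `call_intervals` is available when strict significance
  gating is wanted. At the default synthetic effect sizes (locus R² of
  0.08–0.10, n = 250), strict gating would drop the weaker locus in a
  nontrivial fraction of realizations purely by sampling noise.
* eQTL peaks are recorded per chromosome with LOD ≥ `lod_min`; the default
  `lod_min` is the clinical trait's genome-wide 0.05 threshold, applied to
  all genes for speed. The 10 Mb cis window and all interval endpoints are
  boundary-inclusive.
* The per-locus **count FDR** permutes mouse labels jointly across the whole
  expression matrix — preserving gene–gene correlation while breaking
  genotype linkage — and reports mean permuted count / observed count.

## Causal / reactive / independent classification

For locus L, gene G, trait T, three Gaussian models are fit by maximum
likelihood and scored by BIC = k·ln n − 2·ll:

| model | factorization | parameters (k genotype levels) |
|---|---|---|
| causal | ll(G\|L) + ll(T\|G) | (k+1) + 3 |
| reactive | ll(T\|L) + ll(G\|T) | (k+1) + 3 |
| independent | bivariate Gaussian of (G, T) given L | 2k + 3 |

The independent model carries a residual-correlation parameter, i.e. it is
the saturated model: pleiotropy without mediation is not misread as
causation, and BIC's consistency drives the correct submodel's selection
when a conditional-independence constraint truly holds. Ties below 1e-9 are
labeled independent (conservative). Labels are invariant to affine
rescaling of G and T, and swapping G with T exchanges causal and reactive by
construction. Genes labeled independent are removed from the locus groups
before network construction.

## Cross-group network and counting

Groups are restricted to interactome-present genes; an edge qualifies when
one endpoint is in group 1 and the other in group 2. Genes linked to both
loci belong to both groups, and an edge between two such genes counts as a
cross edge. The frequency denominator is |G₁|·|G₂| verbatim — it
double-counts shared-gene pairs, matching the counting convention of the
tissue tables this statistic reproduces; fidelity was preferred over
elegance and is noted here.

## IP, TIPC and TIE

The IP and TIE functional forms are declared surrogates chosen to satisfy
the method's stated contracts, and both are config-switchable:

* **IP = Ẽᵢ·Ẽⱼ** (product of min–max-normalized expressions). The product is
  the simplest form proportional to the relative levels of both partners
  and consistent with diffusion-limited mass action; `min` and geometric
  mean are selectable alternatives. A consequence worth knowing: an edge's
  TIPC is approximately an average of its two genes' trait correlations, so
  edges joining opposite-sign genes have IP profiles that partially cancel.
* **TIE = mean |TIPC| over incident edges**, zero below degree 5. The
  absolute value lets strong negative regulators score highly; the mean
  (rather than the sum) keeps TIE within [0, 1] and allows a low-degree
  gene with uniformly strong edges to outrank a high-degree gene with weak
  ones. The exponent on |TIPC| is configurable (default 1).
* Correlations use pairwise-complete observations (minimum 3); constant-IP
  edges contribute TIPC = 0 rather than being dropped, so degrees are
  stable. Constant genes are excluded from scoring with a flag.
* **Permutation p-values** shuffle each gene's expression row independently
  (destroying gene–gene and gene–trait structure, preserving marginals and
  hence normalization), recompute all TIE scores, and report the add-one
  estimate (1 + #{TIE_perm ≥ TIE_obs})/(P+1); per-gene nulls, not pooled.
  Genes below the degree rule get p = 1.

TIE is invariant to positive-affine transforms of raw expression (min–max
normalization absorbs them) and to affine transforms of the trait (Pearson
absorbs them; a sign flip only flips TIPC signs, which |·| absorbs).

## Synthetic study conditions

The generator emulates an obese F2 cross profiled for a clinical trait
(think plasma insulin) with a two-locus architecture. Defaults, chosen once
as the package's study conditions:

* 250 mice; 5 chromosomes × 90 cM × 30 evenly spaced markers (500 kb/cM).
  The genome is a scaled-down stand-in: more markers add nothing at this
  panel size, and problem sizes were chosen so the full release-gate
  experiment suite runs in minutes on one CPU.
* Meiosis: Haldane map function (no interference), two independent gametes
  per chromosome; genotype = gamete sum, so marginals are 1:2:1. Kosambi
  (interference) could be swapped in via `haldane_r`'s single call site.
  Sex is not modeled (the emulated design analyzes a single sex).
* Trait architecture: `T = β₁x₁ + β₂x₂ + γ·E_hub + ε` with loci targeting
  R² of 10% and 8% and hub coefficient γ = −0.6; by default β₁ = β₂ = 0, so
  both trait QTLs are entirely hub-mediated and conditioning the trait scan
  on hub expression abolishes them — the mediation signature the pipeline's
  conditional scan is designed to detect. A `reactive-hub` mode inverts the
  causal direction to exercise the classifier's discrimination.
* Hub expression is driven by both loci (higher for the second strain's
  alleles) with coefficients derived from the locus R² targets; the
  realized hub–trait correlation lands near −0.6.
* Gene roster: cis genes (driven by a random local marker), trans genes per
  locus and a both-locus band (driven by locus genotype, independent of the
  trait — the classifier should discard them), reactive genes (driven by
  the trait, hence weakly linked to both loci through it), and pure-noise
  genes. Reactive genes couple to the trait with **negative** sign by
  default so the hub's partner group shares the hub's correlation sign —
  matching the emulated tissue, where most top-ranked partners correlate
  negatively with the trait — since opposite-sign partners would cancel in
  the product IP (see above).
* Planted PPI: the hub is wired to 10 reactive genes per locus group
  (degree 20) plus 300 background edges sampled uniformly over non-hub
  pairs. Neighbors are drawn from the reactive pool because only causal or
  reactive genes survive the filter; a partner independent of the trait
  would (correctly) be filtered out and the edge lost.
* Everything is a pure function of (config, seed).

**What passing synthetic tests does not show:** the generator draws
Gaussian, homoscedastic expression with a single planted hub and no
co-expression modules beyond the trait- and locus-driven structure; real
panels have heavier tails, batch structure, correlated co-expression and
incomplete interactomes. Recovery rates here certify the pipeline's logic
and calibration, not field performance.

## Numerical conventions and edge cases

* Genotype codes 0/1/2 (first-strain homozygote / het / second-strain
  homozygote), missing = NaN in memory, `NA` in files; per-marker
  missingness capped at 20% on input.
* LOD computations guard zero residual sums (clipped at 1e-300) and clip
  LOD at 0; ranking ties break by degree descending, then gene id.
* Degenerate inputs raise typed `ValidationError`s (zero-variance trait or
  gene, monomorphic locus, constant covariate, < 30 triplet observations,
  < 10 complete mice per marker) rather than propagating NaNs.
* Enrichment: upper-tail hypergeometric with Benjamini–Hochberg adjustment
  (statsmodels); the universe defaults to the genes present in the
  annotation.

## Known limitations

Marker regression only (no pseudomarkers/interval mapping); no epistasis,
dominance-specific, or sex-interaction models; single-tissue analysis (no
cross-tissue edges or multi-step paths); the interactome is taken as given,
not assembled; the causality test is the likelihood/BIC three-model variant,
not a Bayesian-network scorer.
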