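# Methods

This note documents the statistical procedures the package implements, the
generative model behind its synthetic surveys, and the numerical and design
choices that were genuinely open.

## Community filtering

The pre-analysis chain is, in order: (1) remove taxa whose lineage contains
an excluded rank (defaults: eukaryota/eukaryote, archaea, chloroplast,
mitochondria); (2) remove taxa with fewer than `min_total = 100` counts
summed across samples (strictly fewer; a total of exactly 100 is kept);
(3) remove the host lineage (default rank term `Cyanobacteria`);
(4) rarefy every sample, by a single multivariate-hypergeometric draw, to
the minimum sample total; (5) pool replicates per site by summation (an
averaging option exists behind `pool_mode: mean`).

Choices worth stating:

* Lineage matching is per whole rank and case-insensitive, never substring,
  so excluding "bacteria" cannot remove *Melainabacteria*. Rank prefixes of
  the `d__` form are stripped before comparison.
* The 100-count rule is applied to the post-exclusion table, and the order
  exclusions → count floor → host removal → rarefaction → pooling follows
  the order in which the steps are conventionally reported. Rarefaction
  before pooling keeps replicate depths comparable; pooled-site totals are
  then exactly `n_replicates × depth`.
* Rarefaction is one draw, not an average over draws; its seed is recorded
  in the run manifest.

## Dissimilarity and distance–decay

Bray–Curtis is computed on counts (or real-valued KO abundances) via the
standard `Σ|x−y| / Σ(x+y)` form. Weighted UniFrac weights every branch by
its length times the absolute difference in the two samples' proportional
abundance descending through it; the default is the normalized variant
(bounded in [0, 1]); `normalized=False` gives the raw variant. A
multifurcating root is resolved with zero-length edges before evaluation,
which leaves all branch sums unchanged.

Great-circle distances use the haversine form on a sphere of radius
6371 km (configurable) — haversine rather than the spherical law of
cosines for numerical stability at small angles.

The distance–decay model is a Gaussian identity-link GLM of the
`n(n−1)/2` upper-triangle dissimilarities on pairwise distances, fitted by
ordinary least squares (the identical estimator), with deviance explained
`1 − residual/null deviance` (= R²) and the slope's t-based p-value. Two
caveats are deliberate properties of this design, not bugs:

* The pairs are not independent (each site appears in `n−1` pairs). With
  nine sites the parametric p-value is anti-conservative when sites are
  heterogeneous — in calibration runs on spatially unstructured synthetic
  surveys its type-I rate was ~0.25 at α = 0.05. The package therefore
  also offers a Mantel-style label-permutation p (`n_permutations > 0`),
  which is exactly calibrated under site exchangeability; the recovery
  tests use it. The parametric fit remains the headline number because it
  is what the field reports.
* A constant response returns slope 0, deviance explained 0, p = 1.

## Nearest-taxon statistics and null models

Patristic distances are tip-to-tip branch-length sums. MNTD averages each
present taxon's distance to its nearest co-occurring taxon; the
abundance-weighted variant weights by relative abundance. βMNTD follows
the reference implementation (picante `comdistnt`): the unweighted form
pools all `|A| + |B|` directed nearest-taxon distances into one mean; the
weighted form averages the two relative-abundance-weighted directed means
(for equal richness, or any weighted case, the two conventions coincide).
Both statistics are pinned against the R implementation in the test suite.

Null models shuffle taxa labels across all tips of the supplied phylogeny:

* αNTI: per sample, each replicate applies an independent random tip
  permutation to the distance matrix and recomputes MNTD;
  `αNTI = −(obs − mean)/sd` with the sample (n−1) standard deviation.
* βNTI: each replicate draws one permutation shared by all sample pairs
  (so all pairs see the same randomized tree) and recomputes βMNTD;
  `βNTI = (obs − mean)/sd`.

The default is 999 replicates. Classification uses strict inequalities at
±2; an index whose null has zero variance (e.g. a community spanning every
tip, or a star tree) is reported as missing with an explicit reason, never
coerced to 0; "zero variance" means at or below floating-point noise
(10⁻¹² relative). Indices are invariant under uniform branch-length
rescaling, and bit-reproducible given the seed. Group-level significance
uses Welch two-sample t-tests of the observed indices against the pooled
standardized null indices (a pooled-variance option exists).

The phylogeny handed to the null models defines the regional taxon pool.
The pipeline prunes the input tree only of lineage-excluded taxa
(organelles, eukaryotes, the host clade) before the null models, and prunes
to the analyzed table only for UniFrac. When the input tree contains
exactly the analyzed OTUs — the usual situation with real data, where the
tree is built from the filtered sequences — the two prunings coincide.

## Functional profiles

Module definitions are pre-flattened to ordered blocks of alternative KOs
(`module_id<TAB>block block ...`, alternatives comma-separated); the full
KEGG boolean grammar is out of scope because the analysis only needs
complete/incomplete calls. A block is missing when none of its
alternatives is present; a module is complete when at most one block is
missing. KO presence is abundance > 0 after pooling across sites
(threshold configurable). Completeness is monotone in the KO set, and the
host/microbiome Venn partition is a plain two-set partition of the
complete-module id sets.

## The synthetic survey generator

The generator emulates the structure of a nine-lake triplicate bloom
survey. Defaults: 300-tip regional pool, 9 sites × 3 replicates, richness
60 per site, expected depth 20 000 reads per sample (a desk-scale depth;
the statistics involved are depth-stable well below real survey depths).

* **Phylogeny** — a pure-birth (Yule, rate 1) tree with an exponential
  terminal wait so every branch length is strictly positive. Expected tip
  depth is `H_n − 1`, checked against simulation.
* **Niche trait** — diffusion along branches from root value 0. With
  `rate_decay = 0` this is plain Brownian motion (tip variance
  σ²·depth). The survey default (`trait_conservatism = 2`) is an
  early-burst process whose rate decays with relative depth,
  concentrating variance on deep branches. The reason is structural:
  under plain BM, similar trait values arise by convergence in distant
  clades, so a trait filter assembles communities whose site-specific
  members have no close relatives in partner communities, and between-
  community relatedness (βNTI) cannot express the shared filter. Deep
  conservatism makes trait similarity imply shared deep clades, which is
  the regime the between-community statistics are designed to detect.
* **Site optima** — anchored to the realized trait distribution: the
  shared-optimum mode places every site at the centre of the densest
  trait window (the regional pool's dominant niche — a fixed abstract
  optimum can fall in a trait gap, collapsing the eligible pool to the
  per-site richness and making all sites identical, which degenerates the
  null models); the autocorrelated mode sweeps the 10th–90th trait
  percentile along a smooth function of the coordinates, planting a
  distance–decay ground truth. Coordinates are uniform on the sphere.
* **Assembly** — `filtered`: Gaussian-kernel selection probabilities of
  half-width `filter_width` (default 0.15) around the site optimum, mixed
  with a uniform immigration component (`immigration_rate`, default 0),
  drawn without replacement via Gumbel top-k; `neutral`: uniform draw;
  `overdispersed`: greedy max–min patristic spacing, anchored at the
  taxon nearest the optimum. Ties break by taxon label everywhere.
* **Abundances** — expected abundance = survey-wide lognormal carrying
  capacity (σ = 1.5) × the trait-filter kernel (floored at 0.05 so
  marginal members stay above the 100-count horizon in expectation) ×
  per-site lognormal jitter (σ = 1). Replicates share the site profile
  and redraw multinomial counts at a Poisson depth. This produces the
  survey regime of interest: abundant, mutually related taxa shared
  across sites plus a rare, partly site-specific tail — high Bray–Curtis
  with markedly lower weighted UniFrac.
* **Contaminants** (optional, on by default in the pipeline) — an
  abundant in-tree cyanobacterial clade, off-tree chloroplast /
  mitochondria / eukaryote taxa, and rare tips planted below the
  100-count floor, all recorded as ground truth; the recorded low-count
  list covers every taxon whose realized total fell below the floor, so
  the filter chain's output is exactly predictable.
* **KO tables** — host-only, shared, and microbiome-only module lists
  (disjoint KO ids, ≥3 blocks per module so the two gene pools stay
  identifiable under the ≤1-missing-block rule), positive lognormal
  abundances, independent per-KO/per-site dropout at rate `noise`.

What the generator does *not* emulate: sequencing error, chimeras, OTU
clustering artifacts, compositional biases of extraction/PCR, within-site
environmental gradients, and taxonomically realistic module content.
Passing recovery tests therefore demonstrate that the statistics detect
the processes they target under their own assumptions — not that real
surveys meet those assumptions.

## Calibration properties (checked by the test suite)

On neutral synthetic communities the fraction of |αNTI| > 2 stays near the
nominal rate (the MNTD null is right-skewed, so the two-sided rate runs
below 5%), and the Welch t-test holds its type-I error. Under filtered
assembly with a shared optimum the recovery tests require pooled mean
αNTI > 2 and pooled mean βNTI < −2 over five survey seeds, with no
significant distance–decay by the permutation test; under autocorrelated
optima the planted positive slope must be detected in at least four of
five seeds. With only nine sites, individual surveys occasionally show a
chance alignment of community structure with geography — the same
fragility real nine-site surveys carry.

## Pipeline and reproducibility

The pipeline expands its single mandatory seed into independent per-stage
seeds (simulation, rarefaction, αNTI, βNTI) via `SeedSequence` spawning,
records them in `manifest.json` together with every parameter and
per-stage record counts, and is bit-reproducible: identical config ⇒
byte-identical outputs. Any stage failure aborts with the stage name and
the offending input.
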