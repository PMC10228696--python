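# Methods

## Bootstrap resampling of sequencing reads

At each genomic position of each tumor sample, the observed reads form a
two-class pool: reads carrying the variant (`alt`) and reads without it
(`ref`). A bootstrap replicate redraws `alt + ref` reads from this pool
with replacement, keeping the total fixed. Drawing `n` items with
replacement from a two-class pool is exactly one binomial variate with
`n` trials and success probability `alt / n`, so the implementation is a
single `Binomial(n, alt/n)` draw per cell rather than literal read-list
resampling — mathematically identical and O(1) per cell. Consequences
the workflow relies on: per-cell depth is conserved exactly; the VAF of
a deeply covered cell barely moves while a shallow cell's VAF wobbles
with standard deviation √(p(1−p)/n); and a variant covered by few alt
reads can vanish from a replicate entirely.

Samples of one patient are resampled with independent streams and
bundled, per replicate index, into a pseudo-multi-tumor dataset.
Replicate `r`'s seed is derived deterministically from the master seed
via `SeedSequence.spawn`, so replicates are reproducible individually
and order-independent. The default replicate count is 30; in our
benchmarks (as in published bootstrap practice for this problem) more
replicates sharpen support estimates only marginally.

## Clone deconvolution engine

The central relation is, per sample, `½ f M = V`: `M` is the binary
clones × SNVs genotype matrix, `f` the clone-frequency row vector, `V`
the expected VAF vector under a diploid genome without copy-number
alteration. Variants affected by CNAs should be excluded beforehand, or
their VAFs replaced by CCF/2 (a supported pre-scaling; no CNA estimation
is performed here).

**Per-sample VAF clustering.** SNVs with at least one variant read are
clustered by a one-dimensional binomial mixture over their read counts
(component = a VAF centre + mixing weight), fitted by EM from a
deterministic quantile initialisation, with the component count chosen
by BIC over 1..8. Tumor purity is not required. Clusters are ordered by
descending mean VAF into a root-to-tip chain; a cluster is attached as a
descendant of the nearest preceding cluster whose remaining CCF capacity
(CCF = 2 × VAF, minus already-attached children) accommodates it, and as
a sibling otherwise, with a 0.05 CCF tolerance. Frequency data from one
sample cannot distinguish a chain from a sibling split whenever both are
arithmetically feasible, so chains dominate in practice; the downstream
ancestral and hybrid searches are the mechanism that corrects wrongly
merged genotypes. Candidate clones accumulate all SNVs from the root
cluster to each target cluster.

**Pooling and quality filtering.** Candidates from all samples are
pooled and deduplicated. Quality assessment uses only SNVs with at
least 50 reference and 2 variant reads in some sample (configurable); a
candidate with no quality-passing SNV unique to it is dropped unless its
genotype is a subset of another candidate's (ancestral prefixes
legitimately share every SNV with their descendants). If everything is
filtered, the single clone carrying all SNVs is the fallback.

**Tree, ancestors, frequencies, pruning, hybrids.** The engine iterates
to a fixpoint (capped at 10 rounds):

1. *Tree*: neighbor joining on pairwise Hamming distances between
   genotype rows, with an all-zero germline genotype appended and used
   as the root. Rows are put in canonical lexicographic order first, so
   the topology is independent of input order.
2. *Ancestral clones*: Fitch parsimony genotypes at internal nodes, root
   constrained to the germline state, ties resolved toward absence
   (favouring later gains, which avoids manufacturing early mutations);
   reconstructed genotypes not already in `M` are appended.
3. *Frequencies*: per sample, minimise ‖½ f M − V‖ subject to f ≥ 0 and
   Σf ≤ 1 (bounded NNLS). Plain NNLS is tried first; the sum bound is
   enforced with a slack variable plus penalty row only when violated,
   so exactly recoverable instances are recovered exactly (error <1e−6
   on noise-free full-rank inputs). Rank-deficient `M` yields a warning
   and a least-norm choice among minimisers.
4. *Pruning*: frequencies strictly below 1% are zeroed; clones absent
   everywhere are removed and frequencies re-estimated. A clone at
   exactly the threshold is retained.
5. *Hybrid decomposition*: SNVs sharing a carrying-clone set have
   identical expected VAFs; their observed-VAF residual profiles across
   samples are split by 2-means, and for each carrying clone both
   half-genotypes are offered as alternates, kept when they attract ≥1%
   frequency somewhere. A split is attempted only when the two residual
   centroids are ≥0.1 apart (Euclidean over samples) — read-sampling
   noise alone produces VAF scatter of order √(p(1−p)/depth) ≈ 0.05 per
   sample at depth 100, and splitting inside that scatter manufactures
   spurious clones.

Finalisation prunes once more, then assigns any SNV carried by no clone
to the clone whose carrier-set expected-VAF profile (the clone plus its
genotype-containment descendants, which is what `½ f M` implies for a
gain-only tree) is nearest in least squares to the SNV's observed VAFs;
ties go to the higher-mean-frequency clone. Clones are renamed C1..Cn in
canonical genotype order and the tree rebuilt.

## Consensus clones and bootstrap support

Clones from all replicates are pooled; distinct genotypes, in descending
order of exact-copy frequency (ties lexicographic), either found a group
or join the first existing group whose seed genotype is within the
Hamming cutoff (default 1). Grouping against the fixed seed — not an
evolving consensus — keeps the procedure deterministic and
order-independent. Support is the percentage of replicates contributing
at least one member; a replicate counts once per group. The consensus
genotype calls state 1 where strictly more than 90% of members carry the
SNV, state 0 where strictly more than 90% lack it, and ambiguous
otherwise; the symmetric treatment of state 0 is our choice (the
grouping rule only dictates selection of a called base).

## Migration histories

Given a clone phylogeny, the tumor sites each clone occupies (samples
where its frequency exceeds the 5% reporting threshold), and the primary
site, the history is the minimum-migration site labeling of the tree:
Sankoff dynamic programming with unit cost per site change, root fixed
to the primary. A clone occupying k > 1 sites is expanded into k
co-located leaf copies (its own node becomes free), so a clone shared
between two sites yields a migration with no associated mutations — a
real phenomenon when a clone seeds a new site and keeps growing
unchanged. Top-down ties prefer the parent's label, biasing toward
fewer distinct source sites (configurable in principle; the alternative
"toward primary" bias was not needed in benchmarks). Optimality is
verified in tests against brute-force enumeration on small trees.

Mutations are mapped to branches as parent-absent → child-present gains
of the Fitch-reconstructed genotypes; a migrating branch's gains (and
their driver subset, from user-supplied per-SNV labels) annotate the
emitted path. Paths without mapped mutations are excluded from driver
*rate* computations (rate = drivers / total per path) but retained in
counts.

The consensus history pools per-replicate paths: support is the
percentage of replicates containing a path; paths at or above the
support threshold (default 60%) are solid, and lower-support paths are
added greedily in descending support only while some observed site
remains unreachable from the primary — those are flagged tentative.

## Accuracy metrics

Genotype error (GE) pairs each simulated clone with its most similar
inferred clone (an inferred clone may serve several simulated ones),
averages the mismatch count over ties, and divides by sequence length.
For support-versus-accuracy summaries the direction reverses: each
consensus clone is scored against its nearest simulated clone, since the
support belongs to the inferred clone. Ambiguous consensus states are
scored under three modes: `half` (0.5 mismatch, the neutral default),
`strict` (full mismatch), and `ignore` (pairwise deletion — mismatches
over resolved sites only, the convention of sequence-distance software
when comparing against an N). The benchmark and acceptance script use
`ignore` for consensus clones, because charging ambiguity as error
conflates "uncertain" with "wrong": a clone whose every called base is
correct is a correct clone with incomplete resolution.

Migration paths are classified as TP/FP/FN by set comparison of
(source, destination) pairs with multiplicity collapsed; polyclonal
multiplicities are not well-defined for comparison.

## The simulator

The generator emulates multi-tumor metastasis simulations: a uniform-
attachment random clone tree; SNVs distributed over branches with at
least one per branch (hence `n_snvs ≥ n_clones`, so every genotype is
distinct and gain-only — a perfect phylogeny); metastatic sites seeded
by founder clones drawn from the tree (one per site under monoclonal
seeding, 2–3 under polyclonal), with founders of one site never on one
lineage (otherwise a migration's source would equal its destination) and
sources arising from wherever the founder's parent lineage lives —
producing both primary-to-metastasis and metastasis-to-metastasis
migrations. With probability 0.1 a founder also remains detectable in
its source site, creating shared clones and mutation-free migrations.
Clone frequencies within a site are symmetric-Dirichlet over the clones
present (rows sum to 1); per-cell depth is negative binomial (mean 100,
dispersion 5 — overdispersed like exome data) or uniform over a given
range; variant counts are `Binomial(depth, ½ · purity · Σ carrier
frequencies)`. Driver flags are Bernoulli per SNV at rate 0.1, enriched
threefold on founding branches so driver-rate analyses have signal with
known ground truth.

What the simulator does *not* emulate: copy-number alterations,
sequencing error (no false variant reads), spatial growth, clone
frequencies correlated with tree structure, or purity below 1 by
default. Passing benchmarks therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to CNAs or
caller artefacts in real exome data.

## Benchmark problem sizes

The support-accuracy benchmark (`cloneboot.benchmark`, also driven by
`scripts/acceptance.py` and the acceptance test) uses ten datasets with
5 tumor sites, 9–12 clones, 30–60 SNVs, mean depth 100 and 30 bootstrap
replicates each — the scale at which the full workflow characterises
support-versus-error behaviour in a few CPU-minutes. Larger clone
counts (up to 26) and deeper designs are exercised structurally in the
test suite.

## Known limitations

* Per-sample clustering cannot resolve chain-versus-sibling topologies
  from one sample's frequencies; multi-sample joint clustering is out of
  scope.
* The hybrid-search residual threshold (0.1) is calibrated to depths
  near 100; much deeper data would tolerate a smaller threshold.
* Mutation losses (violating the gain-only model) are logged, never
  modelled.
* Consensus supports attach to genotypes, not to frequencies; no
  consensus frequency estimate is produced.
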