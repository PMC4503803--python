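# Methods

`cortexreg` implements a pipeline for finding an age-dependent co-expression
module in postmortem cortex transcriptomes and identifying the transcription
factors (TFs) that act as its master regulators (MRs), with three
corroboration stages (cell-type markers, ChIP-peak/regulatory-domain
overlap, protein-interaction connectivity) and a synthetic-study generator
that plants all of these signals with known ground truth.  This note
documents the models, the defaults and why they are set where they are, the
numerical choices, and what the synthetic tests do and do not demonstrate.

## 1. Co-expression network and the age module (`coexpr`)

**Model.**  Genes are nodes; the similarity is the all-pairs Pearson
correlation of expression across samples.  The unsigned adjacency is
`a_ij = |r_ij|^beta`, with the soft power `beta` chosen as the smallest
integer whose connectivity distribution reaches a scale-free topology fit
index of 0.85 (falling back to the argmax-fit power, with a warning, when
no power reaches it).  The adjacency is transformed to the topological
overlap matrix

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_u a_iu a_uj,   k_i = sum_u a_iu,

which credits shared neighborhoods and damps spurious pairwise hits.
Modules are branches of the average-linkage tree on `1 - TOM`; clusters
smaller than `min_size` (default 10 genes) are left unassigned (module 0);
modules whose eigengenes correlate above 0.75 (dissimilarity below the
merge height 0.25) are merged iteratively, recomputing eigengenes after
every merge.

**Eigengene.**  The module eigengene is the first principal component over
samples of the gene-standardized member submatrix, unit norm, with its sign
chosen so that the mean correlation with member genes is non-negative (the
conventional disambiguation; any PC is defined only up to sign).

**Scale-free fit index.**  R^2 of the regression of log10 bin frequency on
log10 mean connectivity over 10 equal-width connectivity bins, set to 0
when the slope is positive.  Equal-width binning is the standard histogram
form; we found that equal-count binning is actively misleading on planted
data: a tight background bulk plus a structured module tail reads as a
steep two-point power law and passes the fit target at powers as low as 2,
where background correlation noise (|r| ~ n^-1/2) is not yet suppressed and
average-linkage chaining absorbs hundreds of background genes into every
branch.  With equal-width bins the first 0.85 crossing lands at beta = 6-7
on genome-scale studies, in line with unsigned-WGCNA practice.

**Branch cut.**  The full Dynamic Tree Cut procedure is adaptive and
under-determined by a short description; we implement a static height cut
at `0.995 x (maximum merge height)`.  The anchor to the tree height rather
than to a quantile of merge heights is deliberate: in a TOM tree most
merges ARE background merges and they concentrate in a narrow band just
below the top (on a default synthetic study the 0.8 quantile of merge
heights already sits at 0.9996), so any quantile rule lands inside the
background band.  Branch joins sit well below the band (~0.9), making a
height-anchored cut robust.  The cut height is exposed (`cut_height`,
`cut_fraction`).

**Power selection needs genome scale.**  The connectivity histogram over a
few hundred genes is too noisy for the fit index to behave; on studies of
that size (our small test configurations) the power is fixed at the
conventional unsigned default beta = 6 via the `powers` parameter.
Automatic selection is exercised at the 2000-gene scale.

**Age rule.**  For every module the eigengene is correlated (Pearson;
Spearman available) with age and with each recorded confounder (RIN, pH,
PMI).  A module is *selected* when its age p-value is below alpha (0.05)
AND below the p-value for every confounder.  Selected modules get a
matched-sample validation: the eigengene-age correlation recomputed within
strata of samples sharing the same recorded confounder value (minimum
stratum size 5).  Note the selection rule is per-module and uncorrected;
with many modules and alpha = 0.05 the family-wise false-selection
probability is appreciable (~5% per background module), which is why the
replication across datasets — not the single-dataset call — carries the
evidential weight.

## 2. Mutual-information network and regulons (`minet`)

**MI estimators.**  The reference estimator applies a normal-scores
(copula) transform to each vector and a product Gaussian kernel with the
Silverman two-dimensional bandwidth `h = sigma * n^(-1/6)`, evaluated
leave-one-out at the sample points; the MI is the plug-in average of the
log density ratio, clipped at 0.  Leave-one-out evaluation matters: the
self-term inflates the joint density more than the marginals and biases the
plain plug-in upward, while LOO with the d=2 bandwidth is within ~0.02 nats
of the bivariate-Gaussian closed form `-0.5 ln(1-rho^2)` at n = 5000 across
rho in [0, 0.8].  A fast equal-frequency binned estimator (default
`floor(sqrt(n/5))` bins, so expected cell counts stay ~5) is used for
all-pairs network construction; all entry points accept either.

**Threshold.**  The stated edge p-value (1e-7) is far beyond what
permutation counting can reach, so the threshold is obtained by fitting an
exponential to the right tail (exceedances over the 90th percentile) of a
null distribution of `n_null >= 1000` permuted gene pairs and inverting the
fitted survival function.  For p >= 0.1 the empirical quantile is used
directly.  The exponential family is the standard peaks-over-threshold
approximation for light-tailed statistics; calibration on independent data
retains ~1% of pairs at p = 0.01.

**DPI pruning.**  In every triangle (i, j, k) the edge (i, j) is marked for
removal when `MI_ij < min(MI_ik, MI_jk) * (1 - epsilon)` (tolerance
epsilon = 0.1; epsilon = 1 preserves everything).  All removals are applied
simultaneously after scanning all triangles, so the output does not depend
on edge order, and the operation is idempotent and monotone in epsilon.

**TF protection.**  A marked edge incident to a TF is exempt when either
alternative edge of the triangle joins two non-TFs — equivalently, only a
triangle whose third node is itself a TF can eliminate a TF-target edge.
The narrower reading ("exempt only when the minimum-defining alternative
joins two non-TFs") lets a tightly co-expressed non-TF sibling explain away
most TF-target edges, which is precisely the elimination the protection
exists to forbid; under that reading planted regulons collapsed to their
2-5 strongest targets.

**Bootstrap consensus.**  The network is rebuilt on each of `rounds`
(default 100) bootstrap resamples of the samples; an edge enters the
consensus when its support count is significantly above the per-round mean
edge rate under a binomial null, Benjamini-Hochberg corrected at 0.05; the
consensus MI is the mean over supporting rounds.  Edges present in every
round always survive this test.

**Regulons.**  A TF's regulon is its adjacency list in the final network.
TFs absent from the study are ignored (logged); TFs with empty regulons are
reported.

## 3. Master regulators (`mrscan`)

For each TF the module/regulon intersection is tested with the one-sided
(greater) Fisher's exact test — the upper hypergeometric tail
`P(X >= overlap)` — against the universe of genes in the network.
Bonferroni correction uses the number of TFs with nonempty regulons in that
network (TFs that cannot be tested do not spend multiplicity).  The
replication report across datasets records per-TF replication counts, the
union and the full intersection.  The universe choice (network genes vs all
expressed genes) is exposed; network genes is the default since the
multiplicity is network-scoped too.

## 4. Marker enrichment and age trends (`markers`)

Enrichment of a marker panel in a module is assessed against B (default
1000) uniform draws of module-sized gene sets from the universe.  The
empirical p carries the add-one correction `(#{null >= obs} + 1)/(B + 1)`,
so its floor is 1/(B+1) and p = 0 is impossible; fold enrichment is
observed over the null MEDIAN (with 0/0 defined as 1 and x/0 as infinity).
"Expressed" means present in the study's gene universe; no abundance cutoff
is applied.  Because the overlap count is integer-valued, the empirical p
is exactly uniform only when ties are rare; calibration checks therefore
run at counts large enough (universe 5000, module 300, panel 500) that the
statistic is quasi-continuous — the lumpiness of p at toy scales is a
property of any discrete test statistic, not an estimator bias.

Marker age trends: per-gene Pearson r versus age, summarized by the panel
mean r with a two-sided one-sample t-test of the per-gene correlations
against zero; an optional minimum-age restriction re-tests whether a trend
persists late in life.  `regression_slope` provides the OLS fit used for
eigengene-versus-age summaries.

## 5. Regulatory-domain overlap (`regdom`)

Basal regulatory domains are strand-aware TSS windows: 5 kb upstream to
1 kb downstream (`[TSS-5000, TSS+1000)` on +, mirrored on -), clipped to
the chromosome; all coordinates are 0-based half-open (BED native).  The
association between a peak set and a target set is tested by randomization
within a workspace: peaks and targets are clipped to the workspace, the
observed statistic is the total nucleotide overlap (a count-of-overlapping-
peaks statistic is exposed as an option), and each of `n_sim` simulations
re-places every peak uniformly at random within the workspace segments,
length preserved and never crossing a gap.  Empirical p uses the add-one
correction; fold is observed over the null mean; BH q-values across
multiple tests.  The workspace in the pipeline is the union of the basal
domains of all genes, i.e. the regulatory territory of the expressed
genome.  Composition conditioning (G+C, isochores) is not modelled: it
would require external genome composition tracks, and the synthetic genome
is compositionally homogeneous by construction.  Saturated configurations
(targets covering the whole workspace) are flagged: there the observed
overlap is maximal by construction and p is 1.

## 6. PPI connectivity (`ppinet`)

Given a protein-interaction graph and a seed set, the direct network is the
induced subgraph on the seeds.  Statistics: number of induced edges; mean
direct degree `2E / V_connected` over seeds with at least one direct edge;
indirect connectivity of a seed = the number of its non-seed neighbors
shared with at least one other seed (length-2 paths through a non-seed).
Significance comes from node-label permutations restricted to classes of
equal degree, which preserve the degree multiset exactly; per-seed p
compares the permuted image's direct degree with the observed one, network
p does the same per aggregate statistic, all with the add-one correction
(the floor 1/(B+1) replaces the p = 0 the uncorrected formula would
permit).  Exact-degree bins are the default; log2 bins are available for
sparse degree spectra.  A seed in a singleton degree bin cannot be
relabelled — its contribution is then necessarily null-conservative
(p = 1) and the situation is logged.

## 7. Synthetic studies (`synthio`)

The generator emulates the statistical structure the analysis assumes, not
microarray physics.  One latent factor ("the planted eigengene") drives an
`n_module_genes` block (default 100 genes in a 2000-gene, 150-sample
study).  Ages are uniform over 13-80 years — roughly the adult span of
postmortem cohorts, and the trend-friendliest choice; the eigengene is
`e = c*z_age + sqrt(1-c^2)*w` with `w` orthogonalized against standardized
age, so the *sample* correlation with age equals the target
`module_age_corr` (default -0.4) exactly.

Module gene: `x = e + gamma * u_d + noise_sd * sigma_m * eps`, where `u_d`
is the private factor of the driver TF regulating that gene (driver TFs ARE
the factors: `t_d = u_d`), `gamma = tf_target_loading` (default 1.15), and
`sigma_m` makes the correlation of two module genes from different regulons
hit `within_module_corr` (default 0.41; the config validates feasibility
and rejects impossible combinations).  Driver regulons partition the module
when they fit (default: 5 drivers x 10 genes of the 100); non-driver TFs
drive disjoint background regulons with matched target correlation;
remaining genes are i.i.d. standard normal.

The coupling defaults come from a power calculation against the stated
network threshold: at n = 150 and edge p = 1e-7 the binned-MI threshold is
~0.27 nats while 5-bin discretization retains only ~75% of the continuous
Gaussian MI, so a TF-target correlation of ~0.74 (the value implied by
gamma = 1.15) is needed to keep planted regulatory edges ~0.10 nats above
threshold; and the regulon footprint is kept at 10% of the module so that
the driver factors perturb the module's first principal component only
mildly (realized module-eigengene/age correlation -0.37 to -0.39 against
the -0.4 target).  Larger regulons or weaker coupling are legitimate
configurations — they model studies where the method should partially fail.

Confounders (RIN-, pH-, PMI-like; distributions configurable, recorded
values rounded as postmortem metadata is) are resampled until their age
correlation is at most 0.15 — independence by rejection, keeping marginals
natural.  The adversarial option `dominant_confounder` instead couples one
confounder to the planted eigengene (r = 0.8), the scenario in which the
selection rule must refuse the module.

Marker panels: one target-cell panel of configurable size and in-module
overlap (defaults 162 and 40), plus off-cell panels disjoint from the
module.  Genome: one synthetic chromosome, genes at fixed spacing with
jitter, random strands; peaks with log-normal lengths, a configurable
fraction placed inside basal domains of the module genes and the rest
placed by the same uniform-within-workspace null the test uses (so zero
enrichment is exactly null-calibrated).  PPI: a preferential-attachment
graph (attachment order shuffled — otherwise early nodes are hubs and the
planted TFs would all get unique, unpermutable degrees) with the driver
TFs plus top module genes additionally wired into a clique.

Everything is byte-deterministic given the config seed; independent
substreams are derived per artifact so adding one generator never shifts
another's draws.

**What passing tests do NOT show.**  The generator is linear, Gaussian,
single-latent-factor, batch-free and composition-free.  Recovery on it
demonstrates the statistical machinery (thresholds, nulls, corrections,
pruning rules) under the model the methods assume — not robustness to
nonlinear age trajectories, batch structure, cell-composition drift or
probe-level artifacts of real postmortem data.

## 8. Pipeline (`cli` / `pipeline`)

Stages run in order (simulate -> coexpr -> minet -> mrscan -> markers ->
regdom -> ppinet), each persisting its artifacts (TSV for matrices and
tables, BED for intervals, JSON for structured results) and consuming only
earlier artifacts or config inputs.  Per-stage seeds derive from the global
seed by a SHA-256 hash of the stage name, so stages can be rerun
independently.  The report (JSON + Markdown) embeds every parameter
actually used and every derived seed, and excludes wall-clock data and
machine-local paths, so one seed yields byte-identical reports.  The age
module passed downstream is the selected module with the most significant
age p-value; a run in which no module passes the rule aborts with a stage
error — silently analyzing an unselected module would misrepresent the
method.  The paper-scale defaults (merge height 0.25, min module size 10,
MI p 1e-7, DPI 0.1, 100 bootstrap rounds, 1000 marker draws / interval
simulations / PPI permutations, alpha 0.05) sit in `PipelineConfig`.

## 9. Problem sizes in the shipped tests

Unit tests run on 250-500-gene studies; recovery and calibration checks
use 2000-gene studies for module recovery (10 seeds), 600 genes for MR
sensitivity (10 seeds), 400 genes for the 100-seed MR null, 500 replicates
for interval type-I error, 200 replicates for marker-p uniformity, 50
seeds for the Markov-chain property, and 1000-node graphs for PPI
significance.  These sizes keep the full suite within a few minutes while
leaving every statistical claim testable at its stated tolerance; the
module counts per study are an order of magnitude below real cortex
microarray panels, which only widens per-test confidence bands, not the
logic being checked.

## 10. Known limitations

* The branch cutter is a static approximation of Dynamic Tree Cut; deeply
  nested module structure (modules inside modules) will be cut at one
  height only.
* The MI threshold extrapolates four orders of magnitude beyond the
  permutation null; its absolute calibration at p = 1e-7 is a modelling
  assumption (exponential tail), validated only at reachable p.
* The interval null places peaks independently; clustered peak processes
  (real ChIP libraries) violate this and make the test anti-conservative
  for bp-overlap statistics on clumped peaks.
* Exact-value confounder matching produces usable strata only for coarsely
  recorded covariates; continuous confounders need prior rounding or the
  log2 binning of values upstream.
* The FET universe, the MI estimator, the DPI protection reading and the
  indirect-connectivity statistic are documented interpretations where the
  underlying tools admit several; each is exposed as configuration or
  stated here.
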