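# Methods

This note documents the statistical procedures implemented in `connodiff`,
the synthetic data model used to validate them, the defaults and the design
choices made where the procedure admitted more than one reasonable reading.

## Data model and quality control

A cohort is a set of subjects on one shared parcellation (atlas), each
carrying up to two symmetric zero-diagonal connectivity matrices: a
streamline-count matrix (diffusion MRI, non-negative) and a Pearson
correlation matrix (resting-state fMRI). Node ids are 1-based in all
tables and outputs; matrices are 0-indexed internally.

Quality control, in order:

1. **Symmetrization** (`symmetrize`, default mean): probabilistic
   tractography counts are directional, but the analysis treats node pairs
   as undirected; the mean of the two directions is taken before anything
   else. Min and max reductions are available.
2. **Count threshold** (`apply_dmri_threshold`, default 10): entries below
   10 streamlines are zeroed; an entry equal to the threshold is kept
   ("thresholded at 10 counts" is read as 10 being the minimum retained
   value). Idempotent.
3. **Correlation threshold** (`apply_rsfmri_threshold`, default 0.05):
   entries with |r| ≤ 0.05 are zeroed; strictly larger magnitudes keep
   their sign.
4. **Fisher z** (`fisher_z_transform`): retained correlations are
   variance-stabilised with z = atanh(r); structural zeros stay zero. The
   transform is applied after thresholding. It is monotone, so it does not
   change any rank statistic computed later; it matters for the clinical
   correlations, which use the values linearly.
5. **Motion exclusion** (`motion_exclude`): a subject is excluded from a
   modality when its scalar motion summary (mm) exceeds mean + 1 SD
   (sample SD, n−1) of the cohort. Two ambiguities are exposed as
   configuration rather than silently resolved: the reference sample
   (pooled cohort by default, per-group optional) and the sidedness
   (one-sided "high movers only" by default, two-sided optional). The
   pooled one-sided rule is the default because low motion is not an
   artefact and per-group cut-offs let a high-motion group keep high
   movers. A subject excluded in one modality keeps the other.

File formats are plain text: dense TSV or MatrixMarket coordinate matrices
with a JSON sidecar ({subject_id, modality, units, n_parcels}), an atlas
TSV (node_id, hemisphere, network_label, region_label) and a cohort
manifest CSV. The manifest's group column is selectable, so a secondary
contrast (e.g. symptom-persistent vs non-persistent cases) re-runs the
identical pipeline with no new code.

## Edge-wise contrast

For each edge, the two groups' weight vectors are compared with a
Mann–Whitney–Wilcoxon test. The statistic U counts pairs won by group A
(ties ½, computed from midranks); the normal approximation uses the
tie-corrected variance

    Var(U) = nA·nB/12 · [ (n+1) − Σ(t³−t)/(n(n−1)) ]

and a ±0.5 continuity correction; when every pooled value is tied, z = 0
and p = 1. Edges that are zero in every subject of both groups carry no
data (connections removed by thresholding or absent from tractography) and
are skipped — they are never candidates, rather than being treated as
fully tied data.

The approximation is accurate at the group sizes the scan is designed for
(n ≥ ~8 per group: within 0.05 of the exact permutation p; verified in the
test suite), but not at 2–4 subjects per group, where the exact p is a
step function with increments as large as 1/6. U itself is exact at every
size. Use the permutation stage, not the parametric p, when groups are
tiny.

Candidates are edges with parametric p < α (default 0.001, two-sided — the
scan reports both hyper- and hypo-connectivity). The permutation stage
draws G relabelings (default 10,000) preserving group sizes. One schedule
is shared across all edges: the null needs each edge's statistic under
random labels, and sharing the relabelings is statistically standard and
removes a factor of 55,278 from the cost. Because pooled ranks, the tie
structure and Var(U) are invariant under relabeling, iteration g only
re-sums fixed per-subject ranks over the g-th group-A subset — the whole
null is one (G × subjects) · (subjects × edges) matrix product.

The permutation p is the plain proportion #{|z_null| ≥ |z_obs|}/G; the
(count+1)/(G+1) estimator, which cannot return exactly zero, is available
behind `add_one`. Nulls are computed for candidate edges only by default
(`all_edges=True` computes every edge; the significant set is identical
since significance requires candidacy first). Edges with permutation
p ≤ p_crit (default 0.05, configurable — no canonical value exists for
this stage) are "significant". Effect size is Rosenthal's r = |z|/√N with
N the total analysed subject count; r is reported as a magnitude, with
direction carried separately.

## Subnetworks and hubs

Significant edges form an undirected simple graph. Its connected
components are the reported subnetworks, sorted by node count, then edge
count, then smallest member id (so "the largest subnetwork" is defined
under ties). Within a component, eigenvector centrality is computed on
the **binary** adjacency — the analysis reports which nodes are central in
the difference topology, not effect-size-weighted importance; a weighted
variant would change hub identities and is intentionally not the default.
The implementation is power iteration on A + I from the uniform vector
(the identity shift leaves eigenvectors unchanged and damps the period-2
oscillation of bipartite components), converged to 1e-10 and normalised to
Euclidean norm 1 — this normalisation gives per-component centralities in
the 0.3–0.7 range typical of reported hub tables, whereas max-norm would
force a 1.0 in every component. Hubs are nodes with centrality strictly
greater than the component mean + 1 sample SD (n−1); components whose
centralities are all equal (e.g. cliques, single edges) have no hubs.

## Structure–function overlap

The observed statistic is the intersection of the node sets of the largest
structural and the largest functional subnetwork. Its null: per iteration,
relabel groups within each modality (sizes preserved), re-run the
candidate scan at α, take each modality's largest component and record the
members of the intersection. A node's p is its appearance count divided by
G; BH correction is applied over the observed intersect nodes (the family
actually tested — correcting over all atlas nodes would mix tested with
untested hypotheses). Three design points:

* The inner analyses use the α-candidate graph without the nested
  per-edge permutation stage. Nesting two 10,000-iteration layers is
  computationally prohibitive (10⁸ scans), and the inner stage can only
  prune candidates, which the null intersect does not require.
* Relabelings are drawn independently per modality, because after QC the
  analysed subject sets generally differ between modalities; a
  shared-relabeling mode exists for cohorts with identical subjects.
* The literal count/G rule means an unobserved identity gets p = 0; the
  add-one variant is available.

## Clinical correlations

Pearson correlations between clinical scores (e.g. positive-symptom
severity, basic-symptom severity, global functioning, cognitive battery
total) and the connectivity of tested edges, within the case group only
(the contrast's group A): case–control pooling would manufacture
correlations from any group difference in both variables. The tested edge
family is the significant contrast edges with at least one endpoint in
the overlap intersect; the broader family (every pair touching an
intersect node) is available via `scope="all-incident"`. Missing scores
are dropped pairwise; df = n − 2 over complete pairs.

Significance: the score vector is permuted across subjects (1,000
iterations by default) and |r| recomputed for every tested edge; each
edge's p is the fraction of its own null at or above |r_obs| (a
max-statistic null giving familywise control is available), followed by BH
per score over the tested family — permutation FDR control and BH are
applied in sequence, not as alternatives. Subjects are internally sorted
by score before the Monte-Carlo loop, which makes the permutation
p-values exactly invariant to the order subjects are supplied in (for
distinct score values).

## Cohort statistics

`cohort_stats` pairs each test with its customary effect size: Welch's
t with pooled-SD Cohen's d

    d = |m₁ − m₂| / sqrt(((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2)),

Mann–Whitney U with Rosenthal's r, and chi-squared / Fisher's exact
(two-sided by the point-probability criterion) with the phi coefficient
φ = |ad − bc|/√((a+b)(c+d)(a+c)(b+d)) = √(χ²/N). `cohens_d_pooled` and
`phi_2x2` consume printed summaries (mean, SD, n; cell counts) directly,
so published table rows can be reproduced without raw data; pairing the
pooled-SD d with Welch's test mirrors common reporting practice even
though Welch's test itself does not assume a pooled variance.

## Synthetic cohorts

The generator emulates the *outputs* of an imaging pipeline, with ground
truth recorded for recovery tests.

* **Structural counts.** A random connected backbone (uniform spanning
  tree plus uniform extra edges to a target density, default 0.2) carries
  negative-binomial counts, mean 30 and dispersion k = 8 (variance
  μ + μ²/k) — streamline counts are overdispersed relative to Poisson, and
  the mean/threshold ratio of 3 leaves realistic headroom above the
  10-count cut. Planted edges multiply group A's mean by (1+δ) (hyper) or
  its inverse (hypo).
* **Functional correlations.** Each subject contributes the sample Pearson
  matrix of T = 150 multivariate normal volumes (a 5-minute acquisition at
  a 2 s repetition time) drawn from a block-structured latent correlation
  (6 blocks, within-block r = 0.3 by default). Group A's latent
  correlation is shifted by ±δ on planted edges and projected to the
  nearest positive-definite correlation matrix (eigenvalue clipping at
  1e-4, rescaled to unit diagonal). Planting on the latent covariance,
  not on sample matrices, makes finite-T sampling noise realistic; the
  projection can slightly perturb correlations adjacent to planted edges,
  occasionally producing extra true differences inside the planted node
  set (visible in the README example).
* **Separate effect scales.** The structural effect is multiplicative on
  a count mean while the functional effect is additive on a correlation;
  one shared δ cannot express both usefully, so the config carries
  `effect_delta_dmri` and `effect_delta_rsfmri`.
* **Clinical scores** are β · (mean connectivity over a designated
  planted-edge subset) + N(0, σ²); which subset feeds which score is
  recorded in the truth object. β = 0 gives pure-noise scores for
  calibration.
* **Motion** is lognormal around 0.2 mm with an optional planted fraction
  of 10× outliers. One global seed spawns independent child streams per
  stage (numpy `SeedSequence`), so any stage can be re-simulated alone.

What the simulator does **not** model: fibre geometry, haemodynamics,
spatial autocorrelation of parcels, site/scanner effects, non-Gaussian
BOLD noise, or any dependence between motion and connectivity. Passing
recovery tests therefore demonstrates the statistical machinery is
correct and calibrated under the stated generative model — not that the
pipeline is robust to the full artefact structure of real MRI data.

## Validation scale and numerical choices

Test and acceptance runs use 60 parcels (1,770 edges) and 30 + 30
subjects — large enough for the normal approximation and for stable
permutation nulls, small enough that full multi-stage permutation runs
finish in seconds; 333 parcels (55,278 edges) is supported and merely
scales the same matrix products. Type-I calibration cohorts use zero
within- and between-block correlation so edge tests are independent and a
binomial error band applies to the observed rejection rate; calibration
against the 3-SD binomial band at α = 0.001 uses ≥ 20,000 pooled edge
tests. Planted-recovery scenarios use δ_dmri = 4 and δ_rsfmri = 0.55,
chosen so every planted edge's parametric p is below 1e-6 and recovery is
deterministic up to negligible Monte-Carlo failure probability.

Degenerate inputs are errors, not silent results: groups smaller than 2,
|r| ≥ 1 entries reaching the Fisher transform, zero-variance vectors in a
correlation, zero margins in a 2×2 table, permutation schedules whose
group sizes mismatch the cohort. BH adjustment is the exact step-up
(q_(i) = min_{j≥i} p_(j)·m/j, capped at 1), implemented directly so it is
bit-identical to the definition.

## Known limitations

* The parametric candidate scan is anti-conservative/erratic below ~8
  subjects per group (see above); the permutation stage does not share
  this limitation.
* The overlap null conditions on the α-candidate graph; if the final
  per-edge permutation stage prunes many candidates, the null intersect is
  computed on slightly denser graphs than the observed one, which is
  conservative for the node-identity p.
* p = 0 is reportable from plain-proportion permutation p-values; use
  `add_one` where downstream consumers cannot handle exact zeros.
* Clinical correlations are plain Pearson r — no covariate adjustment,
  no partial correlations, no robustness to outliers beyond what the
  permutation null provides.
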