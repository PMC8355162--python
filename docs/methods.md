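# Methods

## Overview

`cardiomir` implements the dry-lab analysis chain for a mimic-transfection
study of the miR-106b~25 cluster (miR-106b, miR-93, miR-25) in neonatal rat
cardiomyocytes, together with a seeded synthetic-data generator that stands
in for the deposited raw data.  The chain is:

1. gene-level counts → RPKM → expressed filter → fold-change DE calls;
2. seed-family target predictions (mouse) → best score per gene → homology
   translation to rat → intersection with the 'down' calls = the targetome;
3. scored protein-interaction edge list → score ≥ 700 filter → per-miRNA
   induced subnetworks → merged multi-network with node roles and GO-style
   compartments;
4. hypergeometric over-representation with BH-FDR gates;
5. Pearson/UPGMA clustering of fold-change profiles;
6. closed-form cardiometrics (LV mass, EF, FS, volumes, nucleation,
   stereological cardiomyocyte counts, 2^-ddCt).

## Differential expression model

DE is a deterministic threshold, not a statistical test: a gene is
*expressed* when RPKM > 2.00 (strict) in both the treatment and the control
column, and *differentially expressed* when its fold change versus the
control exceeds 1.3 in either direction (the downregulated side is the
symmetric FC < 1/1.3 reading, i.e. |log2FC| > log2 1.3).  A pseudocount of
0.25 RPKM guards the ratio against zeros; it is irrelevant for any gene
that passes the expressed filter at realistic depths.  RPKM library sizes
default to column sums because the mapped-read total is not recoverable
from a count matrix; they are overridable per condition.  Both thresholds
are configuration (an RPKM cutoff of 1.0 is sometimes used with the same
fold-change rule); 2.00 is the default.

Because a threshold rule has no replicates to average over, its operating
point is governed directly by the count noise (see *Synthetic data* below).

## Targetome derivation

Prediction tables may carry several rows per (seed family, mouse gene) pair
— one per target site.  They are reduced to the strongest interaction,
read as the numerically lowest (most negative, context-score convention)
score.  The score is carried for reporting and never thresholded: the
targetome definition filters on observed downregulation, not on predicted
strength.  Homology translation is group-based — any rat gene sharing a
homology group with an input mouse gene is returned, many-to-one mappings
collapsing as sets — and mouse genes with no group are dropped and counted
in a translation report.  The final targetome is the intersection of the
translated predictions with the miRNA's 'down' set.  Both the
post-translation predicted sizes and the post-intersection targetome sizes
are exported, since published accountings exist for both.

## Multi-network construction

Edges with combined score ≥ 700 (of 1000) are kept; the cutoff is
inclusive and configurable.  Only one identifier namespace (rat proteins)
is admitted when an allowed-node set is supplied.  Each miRNA's subnetwork
is the induced subgraph on its DE genes (up or down) plus configured genes
of interest; nodes left isolated by induction are retained so their roles
stay reportable (export offers `--drop-isolated`), while genes absent from
the score-filtered network are ignored — they have no high-confidence
interactions to draw.  Subnetworks merge into one graph whose edges carry
the set of supporting miRNAs.  Node roles follow a fixed precedence:
`down_target` (down for ≥ 1 miRNA and in ≥ 1 predicted set), else
`down_any`, else `up_all` (up in *all* miRNAs), else `other`.  Compartment
labels (cell division GO:0051301/GO:0000086; actin cytoskeleton
GO:0015629/GO:0030036/GO:0031532/GO:0008154; oxidative stress GO:0006979;
canonical and non-canonical Hippo) are multi-membership annotations read
from a user-editable GMT; the two Hippo sets are literature-curated lists
without a fixed public membership, so the package ships no guessed gene
list for them — the synthetic generator fills them with placeholder sets.

## Enrichment statistics

The over-representation p-value is the upper tail P(X ≥ k) of the
hypergeometric distribution (background N, term K, query n, overlap k),
delegated to `scipy.stats.hypergeom.sf`, which is log-space stable.  The
plain upper tail is the default; the EASE variant (overlap deflated to
k−1) is available behind a switch for comparability with DAVID-style
reports.  BH adjustment is the standard step-up (via `statsmodels`),
validated against hand-computed vectors.  A term is significant when
p_raw < 0.01 **and** p_adjusted < 0.05.  The background defaults to the
expressed-gene universe; whether a published analysis used the expressed
set or the whole annotation universe is generally unknowable, so it is a
parameter.

## Clustering

Profiles are the per-gene log2 fold-change vectors, one per miRNA.
Pearson correlations drop missing genes pairwise and refuse constant
profiles.  The UPGMA (unweighted average linkage) tree is computed with an
explicit O(n³) recomputation of inter-cluster means — trivial at the
scale of a handful of treatments — because reproducibility requires a
deterministic tie-break: among minimal distances, the lexicographically
smallest pair of cluster signatures merges first, so input order can never
reshape the tree.  Distances are Euclidean on the fold-change vectors by
default; `--on-correlation` clusters the correlation-matrix rows instead
(both conventions appear in fold-change heatmap pipelines; neither is
asserted as canonical).  Trees export as ultrametric Newick (branch length
= half the merge-height difference) plus a flat merge-event table.

## Cardiometric formulas

* LV mass (mg) = 0.8 · 1.04 · ((LVIDd + LVPWd + IVSd)³ − LVIDd³) + 0.6.
  The widely printed form of this formula has unbalanced parentheses; the
  reading above is the standard ASE-cube convention.  The alternative
  (0.6 inside the ×0.8) differs by < 0.15 mg over the physiological range
  and sits behind `alt_parenthesis=True` for auditability.
* FS (%) = (LVIDd − LVIDs)/LVIDd · 100.
* EF via cube volumes Vd = πLVIDd³/6, Vs = πLVIDs³/6, SV = Vd − Vs,
  EF = SV/Vd · 100.  π is used at full precision (the "3,1416" often seen
  in methods text is the European decimal comma; the difference is
  invisible at printed precision).  Algebraically EF = (1 − (LVIDs/LVIDd)³)·100
  and EF ≥ FS whenever the ventricle contracts; both identities are tested.
* Average nuclei per cardiomyocyte = 2·f_bi + (1 − f_bi) with f_bi the
  binucleated fraction; inputs are accepted on the 0–1 or 0–100 scale with
  explicit tagging, bare values > 1 treated as percent.
* Total cardiomyocytes = nuclei density × LV volume / average nuclei per
  CM (the standard stereological accounting).
* qPCR fold change = 2^−ΔΔCt.

Group-level reporting is explicit about its mode: `per-animal`
(mean-of-formula) is what published tables normally contain;
`on-means` (formula-on-means) applies the formulas to group means and is
the desk-reproduction mode.  The two differ by ≈ 1 printed unit for EF/FS
in some cohorts because the formulas are nonlinear; LV-mass/BW ratios
differ enough between modes that ratios are reported but never treated as
reproducible from printed means.  The pressure-gradient inclusion rule
(> 50 mm Hg for banded animals) is a generic row filter in the CSV reader.

## Synthetic data

The generator emulates the four-condition transfection experiment
(cel-miR-67 control plus the three cluster members), one count column per
condition.  Per-gene molar abundances are lognormal (log10 sd 0.5); the
expected count splits the library proportionally to abundance × length, so
RPKM recovers the abundance scale.  Counts are negative-binomial with
variance μ + φμ² (φ = `nb_dispersion`), the standard RNA-seq
overdispersion model; φ = 0 degenerates to Poisson.  Defaults: 2000 genes,
two million reads per sample (the depth of the emulated experiment), 5%
planted targets per miRNA with two-fold repression applied as division of
the planted mean in that miRNA's column only, 50% target overlap between
miR-106b and miR-93 (the two cluster members whose targetomes overlap
substantially), and φ = 0.05, a typical bulk-RNA-seq magnitude.

Knowledge bases: each miRNA gets its own seed family by default — the
real miR-106b/miR-93 pair shares one family, but a shared family would
make their predicted sets identical and the planted-truth accounting
ambiguous, so overlap is modelled at the target level instead.  Each
predicted pair receives 1–3 site rows with scores from one distribution
for true targets and decoys alike, so best-score reduction is exercised
nontrivially and score cannot leak the truth.  Homology is 1:1 with a
configurable many-to-one paralog fraction and a dropout fraction applied
*only to non-planted genes*: this keeps the generator's contract that every
planted target is present in the prediction table (in mouse coordinates)
for any dropout value, while still exercising dropped-gene reporting.  The
interaction scaffold is a uniform random simple graph with integer scores
uniform on [150, 999]; compartment gene sets realize the configured sizes
(212/345/143/19/21 by default, scaled down for small universes), with the
cell-division compartment drawing half its members from the planted union
so that enrichment has a signal to find.

Echo cohorts are drawn per animal as normal noise around published group
means with sd = SEM·√n.  This reproduces the first two moments the tables
print and demonstrates the mean-of-formula vs formula-on-means gap; it
does not model echo physics (no within-animal correlation between
dimensions, truncation at a small positive floor only).

What passing tests on these simulations show — and what they do not: the
generator has, by construction, independent genes, no batch or library
composition effects, exact planted fold changes and clean identifier
namespaces.  Recovery results therefore characterize the pipeline's
arithmetic and the noise model, not performance on real transcriptomes.

### Recovery operating point

With a single column per condition, the observed log2 fold change of a
gene with mean count μ carries noise sd ≈ √(2(1/μ + φ))/ln 2.  At
φ = 0.1 this is ≈ 0.65 log2 units, so a true two-fold repression sits less
than one sd from the 1.3-fold cutoff: sensitivity plateaus near 0.8 and
roughly a quarter of null genes cross the cutoff in each direction.  This
is a property of threshold DE calling itself, not of the implementation.
At φ = 0.01 and the default two-million-read depth the planted signal sits
≈ 3 sd from the cutoff and recovery is clean (sensitivity ≈ 0.97,
false-positive rate ≈ 0.05); the regular suite tests the recovery property
there, and the acceptance suite additionally reports the φ = 0.1 operating
point.  Problem sizes used in tests and the acceptance script (2000 genes,
10 seeds, three miRNAs) keep full runs in seconds while the Monte-Carlo
SEMs of the reported rates stay below one percentage point.

## Numerical choices and degenerate inputs

* Hypergeometric tails: scipy survival function; exhaustive-enumeration
  agreement to < 1e−12 for all N ≤ 12 is part of the acceptance suite.
* BH: step-up with clipping at 1; p-values outside (0, 1] are rejected.
* UPGMA: exact rational-free arithmetic on floats; ties broken
  lexicographically; heights are non-decreasing for metric inputs.
* RPKM: zero lengths and zero library sizes are structural errors, not
  NaNs.  Fold changes of unexpressed genes are computed (with pseudocount)
  but always labelled `not_expressed`.
* Venn regions always partition the union; totals are emitted alongside.
* Non-contracting ventricles (LVIDs ≥ LVIDd) warn and yield EF, FS ≤ 0
  rather than failing, matching how such records appear in practice.

## Known limitations

* No statistical DE test (by design — the pipeline mirrors a threshold
  definition); conclusions at high dispersion inherit the threshold rule's
  error rates quantified above.
* No de-novo seed-site scanning; predictions are consumed as tables.
* No GO-graph propagation; compartments are flat gene sets.
* The Hippo compartment memberships are placeholders pending a curated
  list.
* Echo simulation reproduces moments, not physiology.
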