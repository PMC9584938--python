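# Methods

This note documents the models and procedures implemented in `xlms`, the
parameter choices that matter, what the synthetic benchmarks do and do not
show, and the known limitations.

## Cross-link tables

A cross-link spectral match (CSM) is one spectrum assigned to one cross-linked
peptide pair. Unique cross-link identity is the **unordered
(accession, residue)² pair** in 1-based UniProt coordinates; peptide sequence
and modification state are deliberately ignored so that counts are
reproducible across search-engine export formats. Links are classified as
*intra* (same protein, different residues), *inter* (different proteins), or
*self* (same residue twice — necessarily spanning two protein copies, hence
direct evidence of homo-oligomerization). Self-links are reported as their own
class rather than being folded into the intra tally, because "intra" is
defined as joining different residues.

Filtering keeps CSMs with search-engine score ≥ `min_score` (default 40) and
FDR ≤ `max_fdr` (default 0.05). The FDR is the search engine's per-record
value; spectral FDR estimation is out of scope here.

## Structural distance validation

DSSO bridges lysine ε-amines up to roughly 35 Å between side-chain anchor
atoms. A mapped link's distance is the **minimum Euclidean distance between
site atoms (Cβ; Cα for glycine or missing Cβ) over all chain assignments**
compatible with the link's accessions. For homo-oligomers this includes the
intra-chain placement except for self-links, which only two distinct copies
can produce. The minimal-assignment convention is standard XL-MS practice; the
chosen assignment is reported so inter-chain evidence stays auditable
(`requires_interchain` marks links whose only satisfied placement spans two
chains).

Author numbering is reconciled to UniProt by global pairwise alignment
(match +1, mismatch −1, gap open −5, gap extend −1; Needleman–Wunsch via
Biopython). Mappings below 30% identity over aligned columns are refused —
a silently wrong offset map would corrupt every downstream distance. Surface
path ("topological") distances are not computed; `d_max` is configurable to
absorb the Cα-vs-Cβ or Euclidean-vs-topological difference.

Multi-model files use the first model; alternate locations resolve to the
highest-occupancy atom; waters and heteroatoms are dropped.

## Restraint-based docking

Cross-links become flat-bottom restraints: penalty 0 inside `[lower, upper]`
(default 10–30 Å, i.e. 20 ± 10 Å on site atoms) and quadratic in the
overshoot outside. The protocol mirrors classic restraint docking: 500 random
initial poses (uniform orientations by the quaternion subgroup algorithm;
centroids inside the reach spheres of restrained receptor sites), derivative-
free rigid-body minimization (Nelder–Mead, ≤ 500 evaluations over the 6
degrees of freedom), retention of the best 100 models, single-linkage
clustering at 5 Å pairwise ligand RMSD (computed as connected components of
the thresholded RMSD graph, which is exactly single linkage at a cutoff), and
reporting of each cluster's best model.

Two deliberate design choices:

* **Surrogate score.** Physics-based energies are replaced by
  `total = w_r·E_restraint + w_x·n_clash − w_c·n_contact` with defaults
  w_r = 1, w_x = 0.5, w_c = 0.05, clash < 3 Å and contact in [3, 8] Å between
  site atoms — one clash outweighs ten contacts. Rankings are therefore *not*
  comparable to force-field energies; restraint satisfaction of reported
  models is the meaningful output.
* **Minimization vs scoring.** The minimizer descends only the energy terms
  (restraint penalty + clash); the contact reward enters the ranking score
  afterwards. Minimizing the reward term would drag every pose toward dense
  packings and make exact restraint satisfaction (E = 0) unreachable, because
  the flat bottom has zero gradient while the discrete contact count always
  pays for a small violation.

Symmetric assembly search (C2: one 2-fold axis, 5 parameters; D2: an oriented
frame of perpendicular 2-folds, 6 parameters) applies the symmetry operators
to a single subunit pose and evaluates each restraint under the minimum over
symmetry-equivalent chain assignments. `symmetry="none"` docks copies
sequentially. Rigid bodies only: no side-chain or backbone refinement — the
major fidelity gap relative to full docking suites.

### What the docking benchmark can and cannot show

The pose-recovery benchmark plants a parallel coiled-coil C2 dimer
(supercoiled helices wound around the symmetry axis, constant-gap extended
interface) and samples restraints centred on the true distances, stratified
along the sequence. Development of this fixture surfaced two structural
limits that hold for any site-atom-only implementation of this protocol:

1. **Identifiability.** Distance restraints on quasi-cylindrical subunits
   leave azimuthal/groove degeneracies: poses 6–20 Å from the planted one can
   satisfy 8 restraints exactly, whatever the band width (±2 to ±10 was
   explored). A straight ideal helix is worst — its side-chain lattice maps
   onto itself under a 180° flip plus sub-turn screw shift — which is why the
   benchmark helix is supercoiled.
2. **Score exploitation.** With one point per residue, two subunits can
   interdigitate: non-physical packings collect 100–350 contact pairs with
   almost no sub-3 Å clashes and outscore the planted interface. The
   top-ranked model is therefore generally a dense non-native packing that
   still satisfies the restraints (approximately or exactly).

Consequently the benchmark reports the best model's ligand RMSD and restraint
energy rather than asserting native-pose recovery; the tetramer benchmark
asserts what the protocol does deliver — an assembly satisfying **all**
generating restraints. Passing these tests shows the sampler, minimizer,
scorer and clustering are correct, not that 8 loose cross-links can pin a
helical dimer to 5 Å, which they geometrically cannot.

## Interaction networks, site frequencies, hotspots

Inter-links collapse to one protein-pair edge with a residue-pair support
count (both granularities are reported, since "number of interactions" is
otherwise ill-defined). Reference comparison takes a flat user-supplied edge
list — no live database queries, for reproducibility. Site-frequency profiles
bin each side of each unique pair in 20-residue bins, normalized to the
protein's site total. Hotspot detection slides windows of ≤ 100 residues over
hetero-interaction sites (inter-links to proteins outside a caller-supplied
partner set), reports windows holding ≥ 75% of sites, and merges overlapping
candidates; window and threshold are configurable — they operationalize a
qualitative "confined section" notion.

## iBAQ stoichiometry

iBAQ values are proportional to molar amounts, so within a complex
`copies ≈ round(abundance / reference abundance)`. Per-subunit abundance is
the **median across samples** (robust to single-replicate dropouts; the
aggregation is otherwise unspecified by convention). The `"auto"` reference
splits subunits at the largest log-scale abundance gap and takes the median
member of the lower (assumed single-copy) cluster; an explicit reference is
recommended. Estimates are scale-invariant.

Reliability under noise: with per-sample CV 0.15 and n samples, the median's
standard error is ≈ 1.25·CV/√n per subunit, against a rounding margin of
±0.5 copy (±17% relative at 3 copies). At the 6 replicates typical of
organelle proteomics the joint exact-recovery rate for an
A₃B₃E₃G₃D₁F₁C₁H₁-style complex is ~84%; ≥ 95% requires ~12 samples. The
benchmark keeps 6 replicates and reports the measured rate.

## DIA cargo statistics

Rows are categorized by valid-value pattern: *background* (all values in all
three conditions), *on/off* (≥ 2 valid values in exactly one SPIONs condition
and none elsewhere), *SPIONs-specific* (no GFP value, ≥ 2 valid values in a
SPIONs condition), else *unclassified*. On/off is checked before
SPIONs-specific, which it would otherwise always also match.

Normalization scales every SPIONS/SPIONS_IP replicate by
(condition grand mean of the per-replicate FLOT1+FLOT2 means) / (that
replicate's reference mean); GFP is untouched. The transform is idempotent
and leaves the references' condition means invariant. Missing values are
never imputed. Testing: equal-variance two-sample t-test on log2 intensities
for rows with ≥ 2 valid values per side (Welch available via `welch=True`);
on/off rows are significant by definition (p = 0, fold change reported
absent); untestable rows get p = 1. Benjamini–Hochberg adjustment
(statsmodels); enrichment at q ≤ 0.05 and |log2 FC| > log2(1.5), the
fold-change cut-off applied on the log2 scale, direction toward SPIONS_IP
(on/off rows pass on their observed side).

Calibration caveats, measured on the synthetic benchmark (300 null + 30
planted rows, 3 vs 3, σ = 0.3 on the log2 scale):

* A 3-vs-3 t-test has 4 degrees of freedom; variance-estimate scatter alone
  caps BH sensitivity near 0.90 at log2 FC 2 and near 0.20 at log2 FC 1.
  End-to-end tests therefore plant strong (8-fold) effects when they assert
  near-complete recovery.
* The null false-call rate (fraction of seeds with ≥ 1 false positive,
  ~0.14) sits above the nominal Simes level 0.05 for two modeled reasons:
  residual reference-normalization error acts as a shared condition shift
  (a batch effect correlating all tests of a run), and left-censored
  missingness truncates low-abundance rows, making small-sample p-values
  non-uniform. Both are properties of real reference-normalized, censored
  DIA data, not of the implementation; on/off calls are deterministic
  consequences of the missingness pattern and are excluded from the
  statistical calibration.

## Synthetic data

Generators are pure functions of (parameters, seed), and every fixture
serializes its ground truth (`SyntheticTruth`). Coarse site-atom-only
geometry (Cα/Cβ): full side chains add nothing to the distance logic under
test. Defaults: helices use ideal geometry (rise 1.5 Å, 100°/residue,
Cα–Cβ 1.53 Å radial); random coils are self-avoiding walks (3.8 Å steps,
≥ 4.5 Å non-adjacent separation); assemblies place exact symmetry copies with
the nearest inter-subunit site-atom distance tuned into [contact − 1,
contact + 1] Å; CSM tables draw true links from lysine pairs within 35 Å and
decoys beyond 40 Å, with scores Normal(55, 8) vs Normal(25, 8) so the
score-40 filter separates them, and 1–5 CSMs per link across DR/IT conditions
and 3 replicates; DIA matrices use abundance-dependent (left-censored)
missingness plus condition-structured dropout, per-replicate scale
distortions on the SPIONs conditions, and reference rows with the small
measurement noise (σ = 0.05) of top-abundance proteins — normalizing on
imprecisely measured references would inject their noise into every value;
iBAQ values are copies × base × lognormal(0, CV).

What passing the synthetic benchmarks shows: the counting, distance,
statistical and search machinery is correct against brute-force oracles and
planted truth. What it does not show: performance on real data with
modification-state ambiguity, wrong-residue localizations, structured
retention-time artifacts, peptide-level missingness, or real protein shapes —
none of which the generators emulate.

## Numerical notes

* Distances and RMSDs in Å throughout; rigid-transform invariance of scores
  and distances holds to 1e-6 Å (tested).
* Nelder–Mead stopping: `xatol` 1e-2, `fatol` 1e-3, ≤ 500 evaluations; a
  descent guard returns the starting pose if the local search ends worse.
* Single-linkage clusters at a cutoff are connected components of the
  thresholded graph; ties in cluster ordering resolve by representative
  total.
* BH adjustment delegates to `statsmodels.stats.multitest.multipletests`;
  tests verify it against an independent hand-written step-up oracle.
* Degenerate inputs: empty link lists yield all-zero summaries; proteins
  without sites yield all-zero profiles; identical t-test groups with zero
  variance return p = 1 (p = 0 if means differ with zero variance).
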