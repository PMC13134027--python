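# Methods

## Model

`osteomap` formalizes a radiological, not histological, description of
skull-involving meningiomas. The unit of analysis is the voxel on a common
reference grid (the intended use is MNI152 at 1-mm isotropic resolution; the
package treats the grid as given and never estimates a registration). Two
binary masks per case — tumor and skull — induce a partition of the head:

- **osseous** = the skull mask, verbatim;
- **intracranial cavity** = the bounded region enclosed by the skull;
- **juxta-osseous/dural band** = cavity voxels whose Euclidean
  voxel-center-to-voxel-center distance to the nearest skull voxel is at most
  the layer thickness (default 5 mm);
- **intradural** = the rest of the cavity;
- everything else is background/extracranial.

Overlaps that can arise after nearest-neighbor resampling are resolved by
fixed priority osseous → juxta-osseous → intradural, so the label map is a
partition by construction. The band is a proximity compartment: it makes no
claim about the anatomical dura, venous sinuses, or falx.

The subtype is a total, pure function of the tumor's compartment counts
(N_bone, N_dura, N_intra): POM when confined to bone; SOM-I when bone and
band are involved without intradural extension; SOM-IIA when all three are
involved and N_bone ≥ N_intra (ties deliberately go to IIA); SOM-IIB when
N_intra > N_bone. Two count patterns fall outside the rules and are flagged
instead of classified: N_bone = 0 (`not_osteomeningioma` — every rule
requires osseous involvement) and N_bone > 0, N_dura = 0, N_intra > 0
(`skipped_layer` — geometrically anomalous, since a connected lesion cannot
reach the intradural space without crossing the band). Tumor voxels outside
all three compartments (subcutaneous extension, for example) are tallied as
`n_other`, included in the percentage denominator, and excluded from the
classification comparison.

## Geometric construction

**Cavity extraction.** The skull is morphologically closed with a metric
ball (default radius 2 mm, spacing-aware) to seal foramina, the connected
components of the complement are labeled with 6-connectivity, components
touching the array border are discarded as extracranial, and the largest
enclosed component minus skull voxels is the cavity. Voxels swallowed by the
closing (inside sealed openings) belong to no compartment. One boundary
effect is inherent to closing-based sealing: the innermost voxel of a
drilled 1-voxel channel can never be restored, because the erosion ball
always protrudes past it into the cavity (distance √(r²+1) > r for every
radius r); the cavity of a perforated-and-sealed shell therefore may differ
from the intact shell's cavity by single voxels at the channel mouth. An
open shell with sealing disabled raises a "no cavity" error that suggests a
larger closing radius.

**Distance definition.** The band uses the exact Euclidean distance
transform with the grid spacing as sampling, so anisotropic voxels are
handled metrically rather than by iterated voxel dilation (on a 1-mm grid
the two differ for diagonal geometry; the metric reading of "5-mm inward
expansion" was chosen as the natural one). The boundary is inclusive
(distance ≤ t), with a 1e-7 mm tolerance so exactly attained distances such
as 5.0 survive floating-point square roots. Inclusivity plus the exact EDT
give the monotonicity properties the tests rely on: the band is nested in
thickness, N_bone is thickness-invariant, N_intra never decreases and
N_dura never increases as the layer thins, and consequently the subtype is
non-decreasing in the severity order POM < SOM-I < SOM-IIA < SOM-IIB as the
layer thins, with POM and SOM-IIB invariant.

**Resampling.** `resample_nearest` pulls values: the supplied 4×4 affine
maps source-world to target-world coordinates (the forward mapping a
registration produces) and is inverted internally; each target voxel takes
its nearest source voxel, and out-of-field voxels become 0 because masks are
absence-default. Grid compatibility is checked with 1e-4 relative tolerance
(header round-off); orientation mismatches are hard errors, never silent
reorientations.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `thickness_mm` | 5.0 | inward extent of the juxta-osseous band; sensitivity set {2, 3, 5} |
| `closing_radius_mm` | 2.0 | metric closing radius sealing skull openings before the cavity fill |
| `connectivity` | 6 | neighborhood for the fill and components; 6 avoids diagonal leaks |

## Statistics

Subtype–symptom associations collapse the four classes into target-vs-others
2×2 tables (SOM-IIB for edema, seizure, and raised intracranial pressure;
SOM-I for exophthalmos). Odds ratios use the Woolf (logit) interval,
exp(ln(ad/bc) ± z·√(1/a+1/b+1/c+1/d)) with z = 1.959964; this interval
method reproduces the published confidence limits for all four associations
exactly at printed precision, which is why it was adopted. Zero cells
trigger the Haldane–Anscombe +0.5 correction on all four cells, flagged in
the result (no published target has a zero cell, so the policy never touches
those numbers). Fisher's exact test and the Kruskal–Wallis test are
delegated to scipy and cross-checked in the test suite against an
independent hypergeometric enumeration and an independent rank-formula
implementation. Cases with missing flags are dropped complete-case with a
logged count; no multiplicity adjustment is applied and reports are
explicitly exploratory.

The logistic layer fits maximum-likelihood models via statsmodels with Wald
intervals (aOR = exp(β), endpoints exp(β ± 1.959964·SE)). Separation and
sparse data are flagged per term — |β| > 15, or an empty cell in a binary
covariate's margin against the outcome — rather than suppressed; on
separated data the reported aOR saturates to infinity instead of
overflowing. Total volume enters models as log(volume + 1), which tames the
right skew while keeping zero-volume components defined. Descriptives use
the n−1 sample SD and linear-interpolation percentiles; a single value
reports SD 0 with a degenerate flag. Rater agreement uses Dice and Jaccard
(two empty masks score 1.0 with a warning — agreement on absence, and a NaN
would silently poison batch reports) and Pearson correlation with the
Fisher-z interval.

## Phantoms: what they emulate and what they do not

The generator builds closed spherical shells (or half-space slabs) as
skulls, and lesions either as transmural spheres or voxel-by-voxel with an
exactly known compartment composition. By-counts lesions define their ground
truth on the generator's own compartment map; circularity is avoided
because that map is itself validated against brute-force all-pairs distance
and border-flood-fill oracles on small grids. Contiguous lesions grow by
breadth-first search, first carving a shortest path toward the next needed
compartment so the crossing stays reachable; a compartment that is
geometrically unreachable falls back to random placement inside that
compartment. Slab skulls enclose nothing, so their declared cavity is
constructed directly rather than extracted.

Synthetic clinical tables draw symptoms class-conditionally (one Bernoulli
probability per symptom per subtype), ages from a normal distribution
(mean 56.4, SD 12.5 years — the scale typical of meningioma cohorts, ~90%
female), and volumes log-normally. Phantoms emulate the *mask-level*
structure of the problem — a closed vault, lesions spanning one to three
compartments, class-conditional symptom frequencies — and deliberately not
MR intensities, segmentation error, skull-base anatomy with real foramina,
or spatially realistic lesion shapes. Passing tests therefore demonstrate
the correctness of the geometry, counting, classification, and inference
machinery, not the clinical validity of any particular cohort's numbers:
cohort-level figures such as the published subtype distribution or the
86.9% thickness-stability fraction depend on patient images the package
does not ship. The acceptance script's stability fraction is the computed
property of its own random transmural-sphere cohort, reported as such.

## Problem sizes and numerical choices

Tests and the acceptance script run on 32³ (oracle comparisons up to 32³)
1-mm grids with shells of outer/inner radius 13/10 mm — small enough for
exhaustive all-pairs distance oracles while preserving every geometric
regime (bone, band, intradural core). The phantom end-to-end check uses 100
seeded by-counts lesions; interval coverage uses 2000 Monte-Carlo
replicates at 100 exposed / 300 unexposed with a true odds ratio of 13.5
(event probabilities 0.72 vs 0.16, the regime of the strongest published
association). The classification rule table is verified exhaustively for
all count triples with entries ≤ 6. All randomness uses
`numpy.random.default_rng` with explicit integer seeds; identical seeds
yield bit-identical masks, tables, and output files.

## Known limitations

- The cavity definition is topological, not anatomical: orbit contents and
  sealed foramina are handled by the closing radius, not by anatomy.
- The band-thickness semantics are metric; an iterative-dilation variant
  would differ slightly on diagonal geometry and is not implemented.
- Multi-row (4×2) exact tests are out of scope; only 2×2 Fisher is exposed.
- Firth-penalized or exact logistic regression is not provided; separated
  fits are flagged, not repaired.
- The package consumes masks already in a common space; registration
  quality is entirely upstream.
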