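# Methods

This note records the models implemented in `olfscreen`, the parameter choices
that matter, and what the synthetic data used by the tests does and does not
emulate.

## Compounds and descriptors

Compounds wrap RDKit molecules with a stable identifier. Descriptors:

- **M** — average molecular mass (Da).
- **clogP** — Crippen atom-contribution logP. The screening literature rarely
  states the exact logP scheme; the Crippen model is the standard
  atom-contribution choice.
- **nRot** — RDKit rotatable-bond count (non-ring single bonds between
  non-terminal heavy atoms, amide C–N excluded).
- **PSA** — topological polar surface area (TPSA fragment sums), Å².
- **mol_volume** — grid integration of the union of van-der-Waals spheres of
  one seeded low-energy conformer, spacing 0.4 Å. The same vdW-sphere/grid
  construction underlies the pocket-volume and shape-counter engines so ligand
  and pocket volumes are directly comparable.
- **net_charge_pH7** — the charge of the dominant protonation state at pH 7,
  assigned group-by-group from a small pKa table: carboxylic acid 4.2, phenol
  10.0, aliphatic amine 10.5, aromatic amine 4.6, amidine/guanidine 12.5,
  imidazole 7.0 treated neutral-dominant. Groups not in the table count as
  neutral. This is a deliberately coarse rule engine — adequate for deciding
  "charged vs neutral at physiological pH" in a screening filter, not a pKa
  predictor.

The default property filter keeps the mass window 110–320 Da, the window used
to screen for OR-sized ligands. All filter intervals are closed. Conformers
come from ETKDG distance-geometry embedding with MMFF refinement; every
embedding is seeded (default seed 2019) so the whole pipeline is
deterministic.

## Pharmacophore perception and matching

Feature rules (heavy-atom centers):

- hydroxyl oxygen → *donor-or-acceptor* (an -OH can play either H-bond role);
- ether/carbonyl oxygen → *acceptor*; N–H → *donor*; other N → *acceptor*;
- aromatic ring → *aromatic* centroid;
- connected set of ≥3 apolar aliphatic carbons (no heteroatom neighbours) →
  *hydrophobic* centroid.

The six-site receptor model places a donor-or-acceptor sphere at the conserved
tyrosine hydroxyl (site I), an acceptor sphere beside it (site II) and four
hydrophobic spheres (III–VI). Site tolerance radius defaults to 1.0 Å
(configurable); all sites are required by default, partial matching
(`required_matches`) is available but off.

Matching searches rigid-body placements: kind-compatible injective
assignments of features to sites are enumerated with pairwise-distance
pruning (a rigid motion cannot change an inter-point distance by more than
twice the tolerance), each surviving assignment is superposed by Kabsch, and
it is accepted when every site's assigned feature lies inside its tolerance
sphere. Ties break by lower RMSD, then lexicographic assignment order. For
the model sizes used here (≤6 sites, ≤~15 features) the pruned enumeration is
exact — the test suite verifies equality with a brute-force oracle on random
instances.

The shape counter is the voxel union (0.5 Å spacing) of the van-der-Waals
spheres of known actives aligned into the model frame, with a 230 Å³ cap on
the candidate volume. A candidate passes when its conformer volume does not
exceed the cap and at most 10 % of its volume protrudes from the counter.
The ionization penalty is a hard filter on non-neutral species (a score-offset
mode exists in the funnel); the polarity counter is a TPSA ceiling, default
55 Å², the upper edge of the poor-potency PSA band in the potency map.

## Interaction fingerprints

Four contact types per pocket residue: hydrophobic, H-bond, ionic
("ion-lock"), aromatic. The source methodology names four types but spells
out only three; the fourth is implemented as aromatic ring stacking, which is
the natural reading for a binding pocket lined by phenylalanines and a
tyrosine. Geometric cutoffs follow common fingerprinting practice and are
configurable (`IFPParams`):

- H-bond: donor–acceptor heavy-atom distance ≤3.5 Å and D–H···A angle ≥120°
  when the donor hydrogen is explicit; for PDB side chains without hydrogens
  the angle test falls back to requiring the acceptor on the outward side of
  the donor (base–donor–acceptor angle ≥90°).
- Hydrophobic: any apolar-carbon pair ≤4.5 Å.
- Ionic: opposite formal charges ≤4.0 Å (ligand charges from the pKa rules).
- Aromatic: ring-centroid distance ≤5.0 Å.

A pose entirely outside the pocket bounding box yields an all-zero
fingerprint with a warning. Contact frequency is the percentage of
fingerprints with any bit set per residue.

## Pocket volume and volume change

Pocket volume is a flood fill (6-connectivity) from the pocket center over
voxels (0.5 Å default) whose centers lie at least `r_vdw + probe` from every
protein atom center; probe radius 1.4 Å (water). An atom-center mode (no
probe padding) is provided because published pocket volumes do not always
state which definition was used; probe-accessible is the default. Percent
volume change is `100·(V_holo − V_apo)/V_apo`, rounded half away from zero to
match printed integer percentages (230→280 Å³ prints as 22 %).

## Agonist clustering

Each compound's fingerprint concatenates (i) counts per feature kind and
(ii) soft-binned pairwise feature-distance descriptors: for every unordered
kind pair, triangular-membership bins centered at 3.0/6.5/10.0 Å (half-width
3.5 Å), capped at 1 per bin. Soft binning avoids the knife-edge bit flips of
hard bins under conformer noise; capping keeps one geometric outlier pair
from dominating. Distances are measured on the seeded (2019) low-energy
conformer.

Dissimilarity is the Soergel (generalized Jaccard) distance, max-normalized
to [0, 1] and squared (contrast exponent 2). Soergel was chosen over plain
Euclidean after it separated scaffold families substantially better; the
mild sharpening compresses within-scaffold conformer noise relative to
between-scaffold separation. Both the exponent and the bins are module
constants, not per-dataset knobs.

Agglomeration is average linkage ("average distance between all inter-cluster
pairs") with a deterministic tie-break: among equal-distance candidate
merges, the lexicographically smallest cluster-id pair merges first (ids in
input order, new clusters numbered consecutively). Merge heights are
cross-checked against SciPy's average linkage in the tests.

The number of classes is selected by the Kelley criterion: for each level,
the average spread is the mean over clusters with ≥2 members of their mean
pairwise dissimilarity; spreads are min–max normalized to [1, n−2] across all
levels *including the single-cluster level* (the full-merge spread anchors
the scale, as in the criterion's original formulation — without it the
criterion cannot return k = 2 on two pure tight families); the penalty is the
normalized spread plus the cluster count, minimized over 2 ≤ k ≤ n−1 with
ties to the smaller k.

On the packaged 42-agonist panel this pipeline selects 6 classes whose
memberships coincide with the panel labels; on synthetic scaffold-family
libraries it recovers the family count in ≥95 % of seeded runs for 2–6
families. Class *memberships* are sensitive to the fingerprint definition in
a way the class *count* is not; only the count is treated as a stable result.

## Molecular-field QSAR

Lattice: 2.0 Å spacing, 4 Å margin beyond the union bounding box of the
aligned training ligands. Probe: sp3 carbon (Rmin/2 1.7 Å, ε 0.1 kcal/mol),
charge +1. Steric field: Lennard-Jones 6-12 with Lorentz–Berthelot
combination, capped at +30 kcal/mol; electrostatic: Coulomb with
distance-dependent dielectric ε = r (i.e. 332.0636·q/r² kcal/mol), capped at
±30 kcal/mol; partial charges are Gasteiger. Capping guarantees finite
fields at atom–probe overlap. Columns with standard deviation <0.05 kcal/mol
are dropped before regression (standard field-analysis practice). PLS
components (≤5) are chosen by leave-one-out q² unless fixed explicitly;
candidate ranking is by predicted pEC50, descending, ties by compound id.
The original campaign's training R² is *not* a reproduction target — it
depends on a commercial field implementation, its charge scheme and the
original alignment; the package asserts property-based sanity instead
(exact fit of exactly-linear activities, non-positive median q² under
activity permutation).

## Dose–response analysis

The Hill model `f(x) = f_max/(1 + (EC50/x)^n)` is fitted by unweighted
nonlinear least squares (no weighting is standard for reporter-assay
readouts), with a geometric multi-start grid of 12 EC50 starts spanning the
observed concentration range; the lowest-residual solution wins, making the
fit deterministic for fixed data. Replicate curves are stacked and fitted
jointly. Data must contain ≥4 points spanning ≥1 decade. If no start
converges the best-effort parameters are returned with `converged=False`.

The potency map partitions (volume, PSA): favorable a1 (120–140 Å³,
20–35 Å²), a2 (140–160, 35–40), a3 (>160, 10–20), a4 (120–130, 42–45);
medium b1 (120–150, 10–20), b2 (150–160, 20–30), b3 (130–150, 35–40); poor
c1 (<130, 45–55), c2 (>145, >50). Printed bounds are closed; ">x" bounds are
open below. Overlaps (e.g. PSA 45 on the a4/c1 edge) resolve by the fixed
precedence a1..a4, b1..b3, c1, c2 — favorable regions are the map's headline,
so they claim contested points. Volumes above 300 Å³ lie beyond any studied
agonist and return "unclassified".

## The screening funnel

Stage order is fixed: property filter → PH4 match → shape volume →
ionization → polarity → QSAR ranking; stages can be disabled but not
reordered. One master seed yields per-stage seeds by fixed offsets, all
recorded in the report, and reruns are bit-identical. The report carries the
original campaign's survivor counts (1.58 M → 312,800 → 266,000 → 493 → 371 →
204 → 100 → 64) as explicitly non-reproducible reference metadata: they
derive from an external 1.58 M-compound library and commercial PH4/QSAR
engines. The original rank-then-dock-then-inspect tail is represented by the
QSAR top-k cut alone; docking is out of scope and the report says so.

`build_reference_model` derives the funnel's pharmacophore model from a
reference agonist (hydroxyl → site I, methoxy → site II, aromatic centroid
and aliphatic hydrophobic centroid → hydrophobic sites) and builds the shape
counter from all references aligned by their own matches.

## Synthetic data: what it emulates, and what it does not

**Agonist panel.** The packaged 42-record panel is a synthetic
reconstruction of the published Olfr73 agonist collection: 17 A-compounds and
25 B-compounds in six structural classes, with B3 = isoeugenol and
A1 = 4-isobutylphenol, reported-compound masses inside 134–218 Da, and
per-class EC50 values spanning the published ranges (class 1: 13–64 µM,
class 2: 7–240, class 3: 26–270, class 4: ten in 4–100 and six in 200–660,
class 5: 36–63, class 6: 630). Where the published class descriptions pin a
structure down (isoeugenol, eugenol, vanillin, …) the literature odorant is
used; remaining members are plausible class-consistent odorants, and
positional-isomer choices that the descriptions leave open are flagged
`ambiguous-isomer` in the metadata. EC50 values are representative fixture
data, not measurements; nothing downstream treats them as experimental.

**Library generator.** Planted hits are guaiacol-family agonist analogs that
pass every funnel stage by construction; decoys are built to violate a named
stage (mass outside 110–320 Da; carboxylic acids/amines charged at pH 7;
neutral polyols with TPSA > 55 Å²; scaffolds with too few pharmacophore
features to cover the model sites). This localizes funnel regressions but
means the decoys are *easy*: a real screening deck contains near-miss
compounds the generator does not attempt to produce, so exact planted-hit
recovery demonstrates pipeline correctness, not enrichment performance.

**Toy pockets.** Cavity shells (cube/sphere) place atom centers offset
outward by `r_vdw + probe` so the probe-accessible boundary coincides with
the nominal cavity surface, giving analytically known volumes; shells carry
the Olfr73 contact-residue labels (F102^3.30 … T280^7.42) and a hydroxyl
"tyrosine" oxygen can be added for H-bond pose construction. These are
geometry fixtures, not receptor models — no side-chain packing, no
electrostatics, no flexibility.

**Problem sizes.** The test suite runs the funnel end-to-end on 500-compound
libraries with 10 planted hits, scaffold-family recovery over 100 seeded
runs (2–6 families × 5 members), Hill recovery over 100 seeded triplicates,
and 100-instance oracle comparisons for matching and Kelley selection —
sizes chosen so the whole suite exercises every code path in a couple of
minutes on a laptop core.

## Known limitations

- Homology modelling, MD simulation and docking are out of scope; poses are
  inputs. The published MD-derived pocket volumes and contact-frequency
  percentages are reference metadata, not reproduction targets.
- The pKa rule table covers common drug-like groups only; zwitterions and
  tautomer-dependent cases are beyond it.
- Pharmacophore matching treats conformers as rigid; flexibility enters only
  through the seeded conformer ensemble (default 10 per compound).
- The PDB reader takes the first model, altloc A, and classifies side chains
  by a fixed template table; nonstandard residues fall back to generic
  carbon/apolar handling.
- Clustering results at the membership level depend on the fingerprint
  definition; the class count is the robust quantity.
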