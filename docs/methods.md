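# Methods

## Pipeline overview

`condock` couples two components: a per-residue-pair contact classifier
trained on structure- and alignment-derived features, and a rigid-body
docking search whose translational stage is pruned by contact-derived
distance constraints. The classifier does not need to be right about any
particular pair; it needs to place at least one true contact among its top
~100 predictions, because the docking stage screens every predicted contact
independently and retains a fixed quota of models from each.

## Geometry and candidate definition

Structures are heavy-atom only (hydrogens and deuterium removed at parse
time); alternate locations resolve to the highest-occupancy conformer,
ties to the first in file order. Residues missing from the coordinates are
simply absent from the model and can never enter a candidate pair.

Contacts use the minimum heavy-atom center distance with a 5 Å criterion,
inclusive (d ≤ 5 Å), for both inter-partner true contacts and the
intra-partner contacts that define surface neighborhoods.

Solvent-accessible areas come from Shrake–Rupley rolling-probe sampling
(probe 1.4 Å, 960 Fibonacci points per atom, via `biotite.structure.sasa`)
with vdW radii C 1.70, N 1.55, O 1.52, S/P 1.80, Se 1.90 Å and a 1.70 Å
fallback that logs a warning. Side-chain area sums over atoms outside the
N/CA/C/O(/OXT) backbone, so glycine's side-chain area is 0. Because probe
radius, point density and radii are free choices, absolute areas — and
therefore the effect of any fixed cutoff — can differ between SASA
implementations; the default 38 Å² candidate cutoff should be re-derived
with `select_area_cutoff` when absolute areas matter. The surface test is
strict (area > cutoff).

`select_area_cutoff` scores each cutoff on training complexes as
(mean candidate pairs ÷ min surviving true contacts) × (fraction of true
contacts lost in the complex retaining the fewest), guards the division by
scoring any cutoff that extinguishes a complex's true contacts as +∞, and
breaks ties toward the smaller cutoff (keeping more true contacts). The
default grid is integer Å² over [0, 60].

## Alignments and descriptors

Rows of the two partners' alignments are matched by organism tag
(UniProt-style `OS=` field, bracketed suffix, or a user regex). When an
organism has several rows, the row with the highest ungapped identity to
its own query wins, ties to the first occurrence. The query pair is always
matched. Descriptors are computed over matched rows only, which makes them
invariant to row order and to unmatched rows.

The 17 base descriptors are listed in `condock.descriptors`. Conventions
chosen where the definitions were genuinely open:

* "relative to the protein average" is a difference (score minus the mean
  per-residue substitution score over all mapped residues), not a ratio;
* the per-residue substitution score averages Gonnet(query aa, row aa) over
  matched rows, skipping gaps; the query row participates;
* the co-occurrence score is the mean over matched rows of
  log f(a,b) − log f(a) − log f(b), with +1 pseudocounts on joint (over 400
  cells) and marginal (over 20 cells) counts — an average log-odds of the
  observed pair against independence, using the amino-acid pair only;
* rows with a gap in a needed column are skipped in means; a descriptor
  with no usable rows is NaN, later imputed with the training column mean
  and flagged (`impute_missing`);
* the four inter-residue pair-score tables shipped in `condock/data/` are
  **synthetic stand-ins** (filenames say so) built from the Kyte–Doolittle
  hydropathy scale and Zamyatnin residue volumes: two hydropathy-product
  propensities (all-atom and Cα variants) and two volume-normalized
  versions. Literature tables can be substituted via
  `condock.descriptors.load_pair_table` and a custom `ScoreTables`.

Neighborhood aggregation uses closed neighborhoods (the residue plus all
candidate residues in intra-partner contact with it). "All-to-one" averages
the descriptor over {(a′,b): a′∈N(a)} ∪ {(a,b′): b′∈N(b)} — the symmetrized
union, with the pair itself counted once; one-directional variants are
available (`a2o_mode`). "All-to-all" averages over N(a) × N(b). With 17
base descriptors this yields 51 features, min–max scaled to [−1, 1] on the
training set; test values are deliberately not clipped, and constant
features map to 0.

## Classifier

Equal-width discretization is per class: each class's bin count follows the
Rice rule (round-half-away-from-zero of 2·n^⅓, minimum 1) on that class's
training count, and its bin edges span that class's observed range, so the
sparse contact class gets coarser bins. Degenerate ranges expand by a small
epsilon. Test values outside a class's range clamp into the boundary bin.
Probabilities take Laplace +1 smoothing, (count+1)/(N_k+n_k), so no log is
ever −∞; priors are pooled class frequencies; everything is stored as
natural logs (the base cannot affect the ranking).

A consequence of per-class bin counts worth knowing: for a feature
distributed identically in both classes, the score is constant in x but
offset from the log prior ratio by log(n_bins₀/n_bins₁) — the bin-width
correction. The unit tests assert this closed form.

The modified R-precision follows the two-branch definition: precision in
the top R when the best true contact ranks ≤ R, else 1 − highestTrue/R
(negative). Its null distribution is **not** centered at the prevalence:
when R ≪ n the no-true-in-top-R branch dominates and the null mean is
markedly negative (≈ −4 at the synthetic study sizes below). The test
suite therefore checks the null against a direct simulation of the metric
under random rankings rather than against the prevalence.

Cross-validation partitions complexes, never pairs, into 5 folds by a
seeded shuffle (default seed 75); each complex is scored by a model trained
on the other folds and contributes its R-precision to a macro average.
Complexes without true contacts are skipped (the metric is undefined).
Score ties in rankings break by the residue-pair identifier, making every
ranking deterministic.

## Feature selection

Forward sequential search with a beam: all single features are evaluated,
the best N kept, every retained subset is extended by every unused feature,
deduplicated as sorted index tuples, re-scored by cross-validated mean
R-precision, and the top N survive. Score ties break lexicographically.
The original beam width is unknown; the default is N = 10. With N = 1 the
procedure is classic greedy forward selection, and with N ≥ C(pool, s) it
is exhaustive — both verified against independent implementations. The
search stops at 45 features by default (scores degrade well before that).

## Docking

Digitization uses a cubic lattice (default 1 Å) with cell-center tests:
core cells lie within an atom's vdW radius, surface cells within radius +
margin (default 1.5 Å) and not in the core. The translational scan scores
every lattice offset by the number of surface–surface cell overlaps and
discards offsets whose core–core overlap exceeds a tolerance (0 by
default; a soft-core budget is the knob for unbound-style docking). The
scan is computed exactly as integer cross-correlations of the occupancy
grids via `scipy.signal.correlate` (values rounded to integers), which is
identical to explicit enumeration — verified against a per-offset brute
force. Rotations come from a deterministic ZYZ Euler grid (default step
24°) or seeded random sampling; the default for already-oriented inputs is
the identity rotation.

A constraint (residue pair, max distance; default 8 Å = 5 Å contact
criterion + 3 Å slack for discretization) prunes translations to the ball
|δ − (c_A − R·c_B)| ≤ d_max + ρ_A + ρ_B (+ optional slack), where c and ρ
are the constrained residues' atom centroids and radii. This bound is
sound: any placement with a heavy-atom pair within d_max lies inside it,
so pruning can only discard infeasible translations. Candidate placements
are then ordered by surface score (ties by rotation index, then z, y, x)
and verified by the exact minimum atom distance before the per-constraint
quota is filled. Cross-constraint sampling retains total/constraints models
per constraint (largest-remainder rounding, ties toward earlier
constraints) and deduplicates identical placements keeping the
higher-score provenance.

BiGGER-style soft side chains and electrostatic/scoring terms are out of
scope; the surface-overlap count is the only score.

## Evaluation

Ligand RMSD superposes the model on the reference over the receptor (the
larger partner: more residues, ties by heavy atoms) and measures the RMSD
of the ligand without refitting; interface RMSD is the best-fit RMSD over
the reference-defined interface (residues within 5 Å of the other
partner). Both default to Cα atoms (`atom_mode='heavy'` switches to all
heavy atoms); which atom set the original benchmark used is unknowable
from the outside, a documented divergence risk. Superposition is
least-squares with a proper rotation (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`); the RMSD is recomputed
from the aligned coordinates because the solver's residual carries
cancellation noise near zero. Acceptability is the strict conjunction
ligand RMSD < 10 Å and interface RMSD < 4 Å.

The gain statistic divides total acceptable constrained models by total
unconstrained. The packaged table
(`condock/data/benchmark_acceptable_models.csv`) carries published
acceptable-model counts for 28 benchmark complexes (bound and unbound, at
500–5000 retained models); recomputing the column gains yields
2.48/2.24/2.26/1.86 (unbound) and 2.08/2.16/2.43/2.38 (bound), mean 2.2,
sd 0.2. Two bound columns differ from the published row by 0.01 at the
second decimal — the published row is internally inconsistent with its own
totals there, so the tests allow that last-digit discrepancy.

## Synthetic data

The generators define the study conditions for every test:

* **Toy complexes** place single-radius (1.7 Å) pseudo-residue blobs (3–4
  atoms within ~1 Å of the center, Cα at the center) on jittered cubic
  lattices (4.5 Å spacing) facing across an interface plane. Facing residue
  pairs share a smooth random corrugation field (two sinusoids, ~1.2 Å
  amplitude, wavelength two lattice spacings) applied identically to both
  sides — bumps on one partner match dents on the other, emulating the
  shape complementarity that pins a bound pose laterally. Designated
  contact pairs are pulled to 4.2 Å center separation; remaining facing
  pairs sit at 5.2 Å. The generator verifies ≥ the designated number of
  ≤5 Å contacts and no inter-partner atom pair under 2 Å, and returns the
  ground truth recomputed by the contact scan. Output is bit-reproducible
  per seed. These toys capture solidity, surface complementarity and
  contact geometry; they do not capture fold topology, side-chain
  flexibility or chemistry, so docking results on them demonstrate the
  constraint/scan machinery, not real-complex accuracy.
* **Alignments** mutate both partners' sequences jointly per organism:
  contact column pairs co-substitute with probability = coevolution
  strength through a fixed amino-acid bijection (creating mutual
  information), other columns mutate independently at the substitution
  rate (default 0.3), and gaps appear at 2% per cell outside the query
  rows. Defaults are 50 organisms — the benchmark's minimum homolog count
  per chain. No phylogenetic correlation between organisms is modeled.
* **Feature tables** draw negatives from a standard normal and shift
  positives by a chosen amount on informative features. The recovery
  conditions used in tests and the acceptance script — 10⁴ pairs, 20
  features, 5 informative at 1.0 σ, 1% prevalence — mirror the scale and
  class imbalance of real candidate-pair sets. Planted-feature-selection
  runs use 10 features with 2 informative at 1.0 σ, 5% prevalence, 4
  complexes of 500 pairs, beam width 3 — small enough to be exhaustive
  where needed.

## Problem sizes and numerical choices

Test and acceptance-script problem sizes (toy complexes of 6–30 residues
per partner, grids ≤ ~50³ cells, 20-seed recovery panels, 100-toy
soundness panels) were chosen so the whole suite completes in well under a
minute while every check retains statistical teeth; all sizes are stated
at the call sites. Numerical guards: epsilon expansion of degenerate
histogram ranges, clamping of out-of-range values to boundary bins,
integer rounding of correlation scores, a 1e-9 slack in exact constraint
verification, and rank checks before superposition (≥3 non-collinear
points required).

## Known limitations

* Absolute SASA values, and hence the literal 38 Å² cutoff, are
  implementation-relative.
* The shipped pair-score tables are synthetic stand-ins; feature values
  will differ from any implementation using the literature tables.
* The docking score is surface-overlap only; absolute model counts are not
  comparable with full docking programs, only the constrained-vs-
  unconstrained contrast is meaningful.
* The modified R-precision's negative branch makes null means strongly
  size-dependent; compare values only at matched problem sizes.
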