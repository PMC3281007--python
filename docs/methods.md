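# Methods

This note documents the models and procedures implemented in `cpsite`, the
parameters that matter, the synthetic data the tests run on, and the
numerical and design choices made where the design was genuinely open.

## Problem setting

A circular permutation (CP) at position *s* of a chain of length *n*
creates new termini by breaking the peptide bond between residues *s−1*
and *s* (the *cleavage point*) and joining the native termini. A CP site
is *viable* if the permutant folds into a stable, purifiable protein.
`cpsite` treats viability prediction as per-residue binary scoring: every
position 2..n of a chain receives a probability-like score in [0, 1], with
≥ 0.5 calling the site viable. Position 1 is the identity permutation and
is never scored as a site.

The unit of analysis is a single chain (first model of a PDB entry;
multi-chain files require an explicit chain selection). Residues are
renumbered contiguously from 1; author numbering is carried alongside.
Hydrogens are ignored everywhere; measures that would classically be
computed after hydrogen restoration use heavy-atom geometric criteria
instead.

## Per-residue descriptors

All distances in Å; a residue's location is its Cα unless stated.

| descriptor | definition | key parameter (default) |
|---|---|---|
| RSA | 100 · residue SASA / MaxASA(aa) | probe 1.4 Å, 960 sphere points |
| depth | distance from Cα to nearest solvent-accessible heavy atom (0 if that atom is the residue's own) | — |
| CM | ‖Cα_i − centroid‖, centroid = unweighted Cα mean | — |
| H-bonds | N/O–N/O pairs of different residues at ≤ 3.5 Å, excluding backbone pairs of sequence neighbors | d_max 3.5 Å |
| closeness | harmonic centrality / (n−1) on the Cα contact graph | edge cutoff 8.0 Å |
| CN | heavy atoms of other residues within radius of Cα | radius 6.4 Å |
| WCN | Σ_{j≠i} d_ij⁻², no cutoff | exponent 2 |
| B-factor | Cα B-factor passthrough | — |
| GNM-F | diag of Kirchhoff pseudo-inverse (zero mode dropped) | cutoff 10.0 Å |
| DIS_G | mean Cα distance to core set G | — |
| F_G (farness) | [Σ_{j∈G,j≠i} W(j)·d_ij⁻¹]⁻¹, W(j)=d_ij⁻^q | q = 2 |

SASA uses a vectorized Shrake–Rupley sphere-point count on a golden-spiral
lattice with van der Waals radii C 1.70 / N 1.55 / O 1.52 / S 1.80 and the
fixed theoretical Gly-X-Gly MaxASA reference scale, shipped as in-code data
so RSA is bit-reproducible. Tests compare it against an independently
constructed equal-area ring-grid quadrature at 10,000 points (2%
per-residue agreement); a *random*-direction oracle is unsuitable at that
resolution because its own Monte-Carlo noise exceeds 2%.

Core sets: B = {RSA < 10%} (buried), H = hydrophobic amino acids
{A C F I L M V W}, plus B∪H and B∩H. An empty core set is an error, not a
silent NaN. The farness weight exponent follows the inverse-square design
of WCN and the q = 0 case reduces to the unnormalized harmonic mean of the
distances; the outer inversion is fixed so that larger F means farther
from the core. DIS for a residue that is the sole core member is an NaN
sentinel, excluded from standardization (and mapped to the protein mean,
z = 0, if it ever reaches the predictor).

Closeness uses the *harmonic* form (1/(n−1) · Σ 1/sp(i,j), unreachable
nodes contributing 0) so disconnected contact graphs are well defined; the
classical closed-form closeness is ill-defined there.

Eight-state secondary structure is ingested verbatim from DSSP output text
when supplied. Without DSSP a coarse dihedral-window fallback assigns only
{H, E, −}: φ∈(−100°,−30°) ∧ ψ∈(−80°,−5°) → H; φ∈(−180°,−60°) ∧
ψ∈(60°,180°) → E. This is an approximation intended for synthetic chains
and smoke use, and is overridden by real DSSP output.

## Propensity statistics

A CP site is represented by the 2k-residue window around its cleavage
point, positions s−k .. s+k−1, truncated (not discarded) at chain ends;
k = 3 by default (a 6-residue segment; k = 10 reproduces the wider
20-residue representative window). Pattern catalogs: the 20 amino acids; a
3-class physiochemical map (hydrophobic A C F I L M V W / hydrophilic
R N D Q E K / neutral G H P S T Y); a 5-class side-chain map (nonpolar
aliphatic G A P V L I M / aromatic F Y W / polar uncharged S T C N Q /
positive K R H / negative D E); the 8 DSSP states; di-residue pairs; and
gapped pairs (s_i, s_{i+g}), g = 1..3.

Per-polypeptide frequency: count/length for single symbols,
count/(length−g) for pairs. Bootstrap aggregating draws m = 5,000
resamples of n polypeptides with replacement (n′ = n) and reports the mean
and SD of the group-mean frequency per pattern.

The permutation test uses the difference of group means θ̂ as the
statistic, two-sided (|θ*| ≥ |θ̂|), with group sizes preserved under
relabeling. With T Monte-Carlo relabelings the p-value is (t+1)/(T+1);
when C(N, n_e) ≤ 10,000 a full enumeration replaces sampling and p = t/total
is exact. T defaults to 99,999. Monte-Carlo sampling exploits the fact
that the statistic depends only on the subset *sum*: when the pooled
values take ≤ 1024 distinct levels (always true for short-window
frequencies), the level composition of a random subset is multivariate
hypergeometric and is sampled in O(levels) per draw; otherwise random
index subsets are drawn directly. The two paths are distributionally
identical and the sampler is tested against exact enumeration.

The propensity score is S_p = W · log₂((f_e+ε)/(f_c+ε)) with W = 1 − p.
ε is half the sum of each group's smallest *nonzero* per-polypeptide
frequency of the pattern (a group in which the pattern never occurs
contributes 1/Σlengths instead). This pseudo-frequency exists solely to
prevent division by zero; the published description leaves "minimum
frequency" ambiguous when zeros occur, and the nonzero-minimum reading is
the recorded choice here. S_p is zero at equal frequencies or p = 1,
positive for enrichment, and antisymmetric under swapping the groups.

Per-residue propensity features (R_aa, R_aat3, R_aat5, R_sse) are the mean
S_p of the window's symbols under the corresponding catalog; symbols
missing from a score table contribute 0 with a warning.

## Prediction

**Orientation.** Any feature whose viable-class mean is below its
inviable-class mean is multiplied by −1, so viable sites score higher on
every feature. Sign flip is used uniformly — the reciprocal alternative
1/M is undefined for zero-crossing features.

**Standardization.** z = (x − μ)/σ per *protein* and per feature (no
pooling across proteins); constant columns become zeros with a warning.

**Hierarchical integration.** Features are grouped into a rooted tree
(default: sequence propensities / SSE propensity / exposure / packing /
flexibility / core distance, joined at the root; user-editable). Bottom-up,
each node's integrated feature is IF = Σ_f w_f·z_f with Σw_f = 1.00 on a
two-decimal grid (step 0.05 by default, 0.01 at higher cost), searched
exhaustively and selected by 10-fold mean MCC (threshold per fold at the
training ROC point nearest (0,1)), ties broken by mean AUC, then by the
two-sample Mann–Whitney p-value of IF between classes. The fold split is
fixed once per fit, so singleton weightings of every leaf are inside every
ancestor's search space: the root's selected CV MCC can never be below any
leaf's (a property the tests assert). The weights-sum-to-1 normalization
is a design choice keeping IF scale-stable across nodes. Grids beyond
2·10⁶ combinations (e.g. 7+ branches at step 0.01) are rejected with
advice to coarsen the step. The HI probability score of a residue counts
training positives with IF ≥ IF_i (N_p) and negatives with IF ≤ IF_i
(N_n): score = N_n/(N_p+N_n), 0.5 when both counts are empty; it is
monotone non-decreasing in IF.

**ANN.** Three sigmoid layers, N_h = Round(√(N_i·N_o)) hidden units (a
standard heuristic of the era; the source formula is not printable),
weights initialized uniformly in ±2, learning rate 0.5, momentum 0.1,
5,000 iterations of single-case backpropagation with the training case
drawn uniformly *with replacement* each iteration (the alternative without
replacement is unstated in the source; with-replacement is the recorded
choice). Non-finite weights trigger re-initialization with the next seed.
The sigmoid output is the probability score.

**RF.** 1,000 unpruned CART trees (Gini splits), each grown on a bootstrap
sample of all n_t cases (expected ≈ 63% unique) over a per-tree random
subset of max(1, ⌊0.5·n_f⌋) features; each tree is scored by MCC on its
out-of-bag cases (empty OOB → MCC −1) and the 500 best trees are retained.
The forest score is the fraction of retained trees voting viable, hence on
the grid {0, 1/500, …, 1}. Trees are hand-grown CART so the whole model
serializes as versioned JSON text.

**SVM.** RBF-kernel soft-margin classification (scikit-learn SVC) with
(C, γ) grid-searched by stratified cross-validated accuracy; decision
values are calibrated to probabilities by a Platt sigmoid fitted by Newton
iteration on *out-of-fold* decision values. Prediction recomputes the
kernel decision function from the stored support vectors, so the model
file is self-contained text.

**Combination and smoothing.** The four scores (each in [0,1]) are
averaged unweighted, then smoothed along the chain with a 3-residue window
(0.25, 0.50, 0.25), renormalized over the neighbors that exist at the
termini. The smoothing weights stand behind a placeholder in the source
and are a recorded choice (configurable). A residue is predicted viable
iff its smoothed score ≥ 0.5.

## Evaluation

ROC by threshold sweep over unique scores with ties grouped; trapezoidal
AUC; decision thresholds are *inclusive* (score ≥ t → viable), consistent
with the ≥ 0.5 viability rule. The operating threshold is the ROC point
nearest (0,1) (ties → higher threshold). MCC is 0 whenever a confusion
marginal is empty. PPF = fraction of residues called viable; fixing
PPF = 0.5 gives a fair basis for comparing features on datasets without
negative labels, where a random predictor theoretically attains
sensitivity 0.5 (verified by simulation). `threshold_at_ppf` returns the
largest threshold reaching the target and reports the achieved fraction,
which can overshoot under ties. Retrieval tables report PPF, recall and
precision at fixed cutoffs; zero-retrieval rows print precision 1.0 with
an explicit flag rather than NaN. Cross-validation folds are seeded,
class-stratified, and partition the data exactly.

## Synthetic data

The generator emulates the statistical structure the analyses assume, not
protein physics:

* **Structures** — backbones (N, CA, C, O) built by sequential
  internal-coordinate placement with ideal bond geometry; helix
  (φ,ψ) = (−57°,−47°), strand (−120°,120°), loop dihedrals uniform over a
  generous coil region, with clash-triggered resampling and optional
  Gaussian coordinate noise (default 0.15 Å in the simulated studies).
  B-factors are synthesized as a noisy increasing function of distance
  from the centroid, mimicking surface mobility.
* **Labels** — P(viable at i) = logistic(β₀ + Σ β_f x_f(i)) with the
  default model β₀ = 0, β_WCN = −2.0 on the per-protein z-score of WCN and
  β_loop = +1.0 on a coil indicator: exposed/unpacked loop residues viable,
  the association direction the real analyses report.
* **Sequences** — site windows drawn from a fixed average amino-acid
  composition reweighted by per-residue multipliers (e.g. proline ×1.32)
  and renormalized; the background group is drawn at whole-chain length
  (default 300) versus 6-residue site windows, mirroring the real contrast
  of full protein sequences against cleavage-point segments. Equal lengths
  are available for exchangeable-null calibration studies, where they are
  used by the uniformity tests.

Because the chains are backbone-only, RSA (normalized by full-residue
reference areas) never falls below ~14%, so the buried set B at the
real-protein 10% threshold would be empty; simulated studies therefore use
a backbone-mode burial threshold of 35% RSA, which marks the relatively
buried ~40% of residues. Residue depth is likewise nearly constant
(almost every backbone atom is accessible) and contributes no signal in
synthetic mode. Consequently, passing tests demonstrate that the pipeline
recovers planted associations under idealized geometry — they do not
certify predictive accuracy on real proteins, which have side chains, real
packing, and experimental noise.

## Problem sizes in tests and acceptance runs

The simulated recovery study uses 16 proteins × 50 residues (784 labeled
cases), the desk-scale ensemble configuration (RF 200 trees / keep 100,
HI weight step 0.1 with 5 inner folds, ANN 5,000 iterations), and 10-fold
outer cross-validation; planted-enrichment recovery uses 40 repeats of
1,000 sequences per group at T = 99,999 permutations; null-calibration
uses 200 repetitions at T = 999. These sizes are the package's chosen
desk-scale defaults; the full-scale settings (RF 1000/500, HI step 0.01)
remain available through `EnsembleConfig`.

## Known limitations

* The dihedral-window secondary-structure fallback assigns only {H, E, −}
  and is deliberately crude; supply DSSP output for real analyses.
* Backbone-only synthetic mode exercises atom-level descriptors (SASA, CN,
  H-bonds) on four atoms per residue; absolute values are not comparable
  to real proteins.
* The SVM grid is small (3 costs × 3 gamma multiples) by default;
  widen it for real datasets.
* Ramachandran-code and kappa-alpha conformational-alphabet propensities
  are not implemented (their alphabet maps are not reproducible from the
  available description), and no structure-alignment-based CP-site
  refinement is attempted.
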