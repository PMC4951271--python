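# Methods

This note documents the models, conventions and numerical choices behind
`hotspotter`, in the spirit of a package methods appendix: what is computed,
under which assumptions, with which defaults, and what the synthetic tests
do and do not demonstrate.

## Structure model

PDB files are read through Biopython and normalised into a lightweight
coordinate model. Conventions where common practice varies:

- **First MODEL only.** NMR ensembles and multi-model files contribute their
  first model.
- **Altloc:** the highest-occupancy copy is kept; occupancy ties break by
  altloc letter order. Deterministic and conventional.
- **Hydrogens are ignored everywhere** (heavy atoms only); the structures
  this method targets are predominantly X-ray without hydrogens.
- **Non-standard residues** (MSE, SEC, SEP, TPO, PTR, HYP, …) map to their
  parent types via a fixed table; unmapped residues are dropped with a
  logged warning. Waters and ligand HETATM groups are dropped.
- **Residue identity** is (chain, author residue number, insertion code);
  author numbering is preserved because mutation annotations use it.
- A residue is kept when backbone N, CA, C are present; side-chain features
  are computed over whatever atoms exist.
- B-factors are clamped at 0 on ingestion.

Unbound states are **rigid chain-group extractions** from the complex — no
relaxation, no separately deposited monomers. This is the standard
approximation behind "change upon binding" descriptors.

## Surface geometry

- **ASA** — Shrake–Rupley point sampling with a *deterministic
  Fibonacci-spiral lattice*, default 960 points per atom, probe 1.4 Å.
  Van der Waals radii: C 1.87, N 1.65, O 1.40, S 1.85 (P 1.80, Se 1.90) Å.
  With 960 points a lone sphere reproduces 4π(r+probe)² to well under 2 %.
  Determinism (identical output for identical input) was preferred over the
  marginally better variance of random lattices.
- **Relative ASA** divides residue aggregates by bundled reference maxima:
  totals are the theoretical maxima of Tien et al. (2013); the
  backbone reference is a shared 46 Å² extended-tripeptide convention, the
  side-chain reference is total − backbone, and polar/non-polar references
  split the total by each residue's polar-atom fraction (polar = N, O;
  sulfur counts apolar). Glycine's side-chain RASA is 0 by convention.
  RASA may exceed 1 for unusually extended conformations; values are not
  clipped at this stage (min–max scaling handles ranges downstream).
- **Protrusion index** (CX construction): for each heavy atom, count atom
  centres within a 10.0 Å sphere, V_int = count × 20.1 Å³,
  V_ext = sphere volume − V_int (floored at 0), PI = V_ext/V_int. An
  isolated atom scores ≈ 207.4 with these defaults.
- **Depth index**: distance to the nearest atom whose ASA exceeds 1.0 Å²;
  exposed atoms have DI 0. A structure with no exposed atom is degenerate
  and raises an error (inside profile computation the column becomes NaN and
  is imputed downstream).
- **Interface**: a residue is interface iff its total ASA drops by more than
  1e−6 Å² between unbound and bound states. ΔASA is never negative beyond
  sampling tolerance (occlusion monotonicity).
- **Position classes** use a RASA threshold of 0.25 on the *total* RASA:
  support (unbound < 0.25), core (unbound ≥ 0.25, bound < 0.25), rim
  (otherwise); encoded 0/1/2.
- **Relative changes** are (unbound − bound)/unbound, so burial upon binding
  is positive; a zero unbound value yields 0 with a row flag. The
  protrusion column `pi_total_mean_relchange` is RctmPI.

The 55-column structural group is the cross product
{ASA, RASA} × {total, backbone, side-chain, polar, non-polar} ×
{unbound, bound, relative change} (30) plus {DI, PI} × {total mean,
side-chain mean, max, min} × the same three states (24) plus the position
class. This enumeration reproduces the documented group size; the precise
historical composition of the original 55 was never published, so this
layout is this package's declared reconstruction.

## Physicochemical features

16 base properties per residue type ship in `data/aa_properties.tsv`
(overridable): Fauchère–Pliska hydrophobicity, Hopp–Woods hydrophilicity,
isoelectric point, residue mass, a 14 Å contact-number scale, Veljković
EIIP (4 decimals), formal charge (Asp/Glu −1, Lys/Arg +1, His 0), Zamyatnin
volume, Grantham polarity, Bhaskaran–Ponnuswamy flexibility, Chou–Fasman
helix/sheet/turn propensities, Charton polarizability and steric parameter,
and Janin buriedness. The historical feature set named only six of its
sixteen properties; the remaining ten here are this package's documented
choice of published indices. Any result that depends on the hydrophobicity
scale should be reported with the scale name (Fauchère–Pliska by default).

Derived encodings: **PSHP** = hydrophobicity × charge for the negatively
charged residues (Asp, Glu), hydrophobicity otherwise — charged interface
residues can be hot spots through salt bridges, and the sign flip aligns
them with the classically hot hydrophobic aromatics. **CHP** extends the
flip to Lys and Arg. Histidine is treated as non-negative (no flip).

## Neighbourhood features

Neighbours of a target residue are atoms of *any other residue* (either
binding partner) within 4.0 or 5.0 Å of the target's side-chain atoms (CA
stands in for glycine). The 33-column group holds 15 per-cutoff aggregates
(atom/residue counts, polar/apolar and backbone/side-chain splits,
partner-side counts, neighbour B-factor mean/max, charged/hydrophobic/polar
residue counts, hydrophobicity sum and mean) plus rotatable-bond counts.
Rotatable side-chain bonds are single, acyclic, non-terminal heavy-atom
bonds including CA–CB (so Ala: 0, Lys: 4, Arg: 5, Pro: 0 — the ring
closes through the backbone nitrogen); the weighted count divides by the
side chain's heavy-atom count. As with the structural group, the exact
historical 33-column roster was unpublished; the per-cutoff aggregates
beyond the documented ones are this package's choice.

## Other features

- **Normalized B-factor**: z-score (population SD) of the residue's mean
  side-chain B over all residues of the structure; all-equal B gives 0s
  with a warning.
- **Pair preference**: sum over partner-side residues within 5.0 Å
  (heavy-atom contact) of a symmetric 20×20 residue-pair score matrix. The
  bundled `pair_preference_synthetic.tsv` is a *synthetic stand-in*
  (hydrophobicity products plus charge complementarity, deterministic);
  supply an empirically derived matrix for production use.
- **Conservation** is ingested from a (chain, resnum, score) file, never
  computed (it would require homolog search and alignment); missing values
  are median-imputed. **Secondary structure** is ingested from DSSP output
  files (8→3 state collapse: H/G/I helix, E/B strand, else coil) and carried
  as metadata — it is not one of the 108 columns, resolving the group-4
  composition in favour of the three-feature roster (pair preference,
  conservation, B-factor).

## Labels and dataset assembly

ΔΔG ≥ 2.0 kcal/mol → hot; < 0.4 → non-hot; [0.4, 2.0) → excluded.
Categorical annotations map strong → hot, everything else → non-hot.
Records that do not resolve to a residue are skipped and reported; records
resolving to non-interface residues are kept with a warning (curated sets
guarantee interface residues; synthetic tests should not silently drop).
Remaining missing values are median-imputed. Model-fitting paths re-fit
median imputation and per-column min–max scaling to [0, 1] **inside each
training split only**, frozen into the model bundle.

## Feature selection

- **Discretisation** for mutual information: 3 states at z = ±1; constant
  columns become all-mid with a warning.
- **MI** is the plug-in estimate in bits.
- **mRMR** uses the MID (difference) criterion — relevance minus mean
  redundancy — the headline variant of the original mRMR publication; ties
  break by column order. Top-third retention is round-half-up(size/3) with
  a minimum of 1, which reproduces 17→6, 55→18, 33→11, 3→1.
- **Wrapper**: all C(36,2) = 630 candidate pairs are scored by pooled
  stratified k-fold CV F1 (MCC breaks ties, then candidate order); the best
  pair seeds a greedy forward search that accepts an addition only when CV
  F1 strictly improves. "Strict F1, MCC as tie-break among candidate
  additions" is the declared reading of the looser historical description
  ("add until F1 and MCC improve").

## Classifier

RBF-kernel SVM (scikit-learn SVC), defaults C = 80.0, G (gamma) = 0.002 —
the published optimum for the three-feature model. Grid search covers
C ∈ {0.5, 1, 2, 5, 10, 20, 40, 80} and G ∈ {0.0005 … 2.0} (zero excluded
as invalid), winner by pooled CV F1 with MCC/smaller-C/smaller-G
tie-breaks. Cross-validation uses stratified folds with a fixed seed and
**pools** out-of-fold predictions into one confusion matrix, matching
integer benchmark counts that sum to the dataset size. No class weighting
(62/92 imbalance is mild). Metrics guard zero denominators by returning 0;
report tables round half-up to 2 decimals. Class-separation reports use the
two-sided Mann–Whitney U test (exact for small tie-free samples, otherwise
tie-corrected normal approximation; an all-constant column returns p = 1).

## Synthetic data: what it shows and what it does not

`generate_feature_table` emulates the curated training set: 62 hot / 92
non-hot rows, 108 columns, three planted informative features among 105
independent standard-normal noise columns. Planted class-conditional
Gaussians: RctmPI-like (means 0.92 vs 0.64, SD 0.27), PSHP-like (0.77 vs
−0.04, SD 0.80), EIIP-like (0.065 vs 0.144, SD 0.13, and within the hot
class correlated at 0.85 with the protrusion latent, making it informative
jointly as well as marginally). The spreads were fixed once so that the
default conditions land in the intended operating regime: the
three-feature model's pooled 10-fold CV F1 averages ≈ 0.71 (range
0.34–0.82 over ten seeds), and the two-step selection recovers all three
planted features in 9/10 seeds. A purely jointly-informative EIIP (zero
marginal shift) was considered and rejected: a marginal-relevance mRMR
filter cannot retain such a feature, so the emulation gives it a modest
marginal shift as a design choice.

What passing tests show: the selection and classification machinery
recovers known signal at realistic sample size and imbalance, is
deterministic under fixed seeds, and is correctly calibrated under the
null (label-shuffled MCC stays within ±0.2 of 0). What they do not show:
anything about real interfaces — the noise columns are independent,
whereas real descriptors are heavily correlated; effect sizes are
Gaussian idealisations; and the toy complexes have single-pseudo-atom side
chains and planar geometry. Real-data performance claims require real
curated structures and ΔΔG lists, which are out of scope here.

`generate_fixture_complex` builds two roughly planar chains whose first
⌈n/2⌉ residue pairs face each other with CB tips exactly the requested gap
apart, and whose remaining pairs are displaced ±30 Å so they cannot occlude
each other. Interface truth is geometric: a residue is interface iff some
cross-chain atom pair lies more than 0.5 Å inside the solvent-probe
occlusion reach (r_i + r_j + 2·probe), which guarantees detectability at
the default lattice resolution; ASA-based detection reproduces this truth
exactly.

## Problem sizes and determinism

Default test and acceptance runs use the 154-row synthetic table, toy
complexes of 5–6 residues per chain, 960-point lattices, and 10-fold CV;
the wrapper's pair stage is the dominant cost (630 pairs × 10 folds).
These sizes were chosen as the smallest that exercise every code path at
the study's sample-size regime. All randomness flows from explicit seeds;
identical inputs and seeds produce byte-identical tables, traces and
predictions.

## Known limitations

- One published metric cell (an independent-test comparator row's F1)
  disagrees with its own counts by 0.01; the formulas here are taken as
  authoritative and the recomputed value is asserted in tests.
- ASA is sampled, not analytic; per-atom values carry ~1 % lattice noise
  (deterministic, so reproducible bit-for-bit).
- The bundled pair-preference matrix is synthetic (see above).
- mmCIF input, structure repair, hydrogen placement, and
  biological-assembly expansion are unsupported.
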