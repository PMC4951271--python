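# hotspotter

Prediction of **hot-spot residues** in protein–protein interfaces.

A small fraction of interface residues contributes most of the binding free
energy of a protein–protein interaction. Experimentally these *hot spots* are
found by alanine-scanning mutagenesis: a residue is a hot spot when mutating
it to alanine raises the binding free energy by ΔΔG ≥ 2.0 kcal/mol, a
non-hot spot when ΔΔG < 0.4 kcal/mol (the 0.4–2.0 band is excluded from
training to sharpen the contrast). Because alanine scanning is slow and
expensive, `hotspotter` predicts hot spots directly from the structure of a
complex.

## Method

For every interface residue the package computes **108 named descriptors**
in four groups:

| Group | n | Content |
|---|---|---|
| physicochemical | 17 | 16 tabulated amino-acid properties (hydrophobicity, hydrophilicity, pI, mass, 14 Å contact number, EIIP, charge, …) plus **PSHP** — pseudo hydrophobicity, the hydrophobicity sign-flipped for Asp/Glu |
| structural | 55 | ASA, relative ASA, depth index (DI) and protrusion index (PI) per residue, each in the unbound state, the bound state, and as relative change (unbound − bound)/unbound, plus the support/core/rim interface position class |
| neighbourhood | 33 | packing around the side chain at 4.0 and 5.0 Å heavy-atom cutoffs (residue/atom counts, environmental hydrophobicity, B-factor and polarity summaries) and rotatable side-chain bond counts |
| other | 3 | interface residue-pair preference score, conservation (ingested, never computed), normalized B-factor |

ASA is computed by Shrake–Rupley sampling on a deterministic Fibonacci
lattice (960 points, probe 1.4 Å); PI follows the CX construction
(PI = V_ext/V_int in a 10 Å sphere, 20.1 Å³ mean atom volume); DI is the
distance to the nearest solvent-exposed atom. A residue is *interface* when
it loses ASA upon binding (rigid chain extraction defines the unbound
state). The key shape feature is **RctmPI**, the relative change in a
residue's total mean PI upon binding — hot spots protrude before binding
and bury that protrusion in the complex.

Features are reduced in two steps: per-group **mRMR** ranking (mutual
information on 3-state discretised columns, MID criterion) keeping the top
third of each group (17→6, 55→18, 33→11, 3→1 = 36), then an **SVM wrapper**
that scores every candidate pair by pooled 10-fold cross-validated F1,
seeds the best pair, and greedily adds features while F1 strictly improves.
The classifier is an RBF-kernel SVM (defaults C = 80.0, G = 0.002) over
min–max scaled features; the reference model uses three features: EIIP,
PSHP and RctmPI. Performance is reported as ACC, SPE, PRE, REC, F1 and MCC
from the pooled confusion matrix.

## Worked example

The pipeline runs end-to-end on synthetic data — no downloads needed:

```sh
hotspotter simulate --seed 5 --out table.tsv
hotspotter train --table table.tsv \
    --features eiip,pshp,pi_total_mean_relchange --out model.joblib
hotspotter evaluate --table table.tsv --model model.joblib --name demo
```

which prints (tab-separated):

```
model   TP  TN  FP  FN  ACC   SPE   PRE   REC   F1    MCC
demo    49  85  7   13  0.87  0.92  0.88  0.79  0.83  0.73
```

Here the synthetic table emulates a curated training set of 62 hot spots
and 92 non-hot spots; TP/FN count hot spots correctly/incorrectly
classified, TN/FP the non-hot spots, and the six metrics derive from those
counts (training-set evaluation, hence the optimistic values; use
cross-validation via the selection trace for honest estimates). Scoring a
published confusion matrix directly also works:

```sh
hotspotter evaluate --counts 32 68 21 6
```

A structure-based run takes a PDB file of a complex, the partner chain
split, and a ΔΔG (or strong/intermediate/weak/insignificant) table:

```sh
hotspotter featurize complex.pdb --split A:B \
    --mutations ddg.tsv --out features.tsv
hotspotter select --table features.tsv --folds 2 --out trace.tsv
```

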