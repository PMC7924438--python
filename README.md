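# clusmote

Hybrid resampling for severely imbalanced classification problems in
structural bioinformatics, built around **CluSMOTE**: density-cluster-based
undersampling of the majority class combined with SMOTE oversampling of the
minority class. The package also ships the imbalance-aware evaluation
protocol the method is judged by (grouped leave-one-out cross-validation
with TPR, TNR, precision, FPR, AUC, Gmean, adjusted Gmean and F-measure),
per-residue structural feature extraction for conformational B-cell epitope
prediction, and synthetic-data generators so everything is testable without
any external download.

## Who this is for

Conformational epitopes — the antibody-binding patches on an antigen
surface — are rare: on surface residues the non-epitope class outnumbers
the epitope class roughly 10:1. Classifiers trained on such data ignore
the minority class; random undersampling balances the classes but throws
away majority-class structure. `clusmote` is for anyone training
residue-level (or any tabular) classifiers under this kind of imbalance who
wants a resampler that preserves the majority class's density structure.

## The method

Given minority count `MI` and majority count `MA`:

1. Separate the classes.
2. Cluster the majority class with HDBSCAN (stability-based flat clusters;
   noise points allowed).
3. Give each cluster `Ci` (size `M_ci`) the sampling quota

   `Size_Ci = r · MI · M_ci / MA`

   where `r` is the desired majority-to-minority ratio after
   undersampling. Quotas are integerized by largest-remainder rounding so
   they sum exactly to `min(round(r · MI), MA)`.
4. Draw each quota uniformly without replacement and recombine with the
   minority class.
5. Oversample the minority with SMOTE — synthetic points
   `s = x + u (x_nn − x)`, `u ~ U(0,1)`, `x_nn` one of the `k` nearest
   minority neighbors — until the classes balance exactly.

`r = 1` is pure cluster-based undersampling (no synthetic points);
larger `r` keeps more of the majority class and synthesizes more minority
points. The trade-off is systematic: sensitivity (TPR) falls and
specificity (TNR) rises as `r` grows.

## Worked example

```python
from clusmote import SyntheticSpec, make_imbalanced, clusmote, ResamplerConfig

ds = make_imbalanced(SyntheticSpec(n_minority=50, imbalance_ratio=10, seed=1))
print(len(ds), ds.n_positive, ds.n_negative)
out = clusmote(ds, ResamplerConfig(r=2.0, seed=0))
print(out.n_positive, out.n_negative, (out.provenance == "synthetic").sum())
```

prints

```
550 50 500
100 100 50
```

— the generator made 50 epitope-like positives and 500 negatives; with
`r = 2` the resampler kept `2 × 50 = 100` negatives (drawn
proportionally from the majority clusters), retained all 50 original
positives and synthesized 50 more, so the output is exactly balanced at
100/100 with 50 rows tagged `synthetic`.

The same pipeline from the shell:

```bash
clusmote simulate --seed 1 --out data.csv
clusmote resample --in data.csv --strategy clusmote --r 2 --seed 0 --out balanced.csv
clusmote simulate --seed 2 --groups 8 --out grouped.csv
clusmote evaluate --in grouped.csv --seed 0 --out results.csv
```

`evaluate` runs the full strategy × r sweep (no resampling, SMOTE only,
cluster-based undersampling only, CluSMOTE with r = 1…5) under grouped
leave-one-out cross-validation, resampling the training folds only, and
writes one row of the eight metrics per grid cell.

Structural features for an antigen chain (contact number, half-sphere and
quadrant-sphere exposure, B factors, AAindex physicochemical values,
sequence log-odds, 4 Å antibody-contact epitope labels, RSA > 0.01 surface
filtering):

```bash
clusmote features --pdb antigen.pdb --antibody ab.pdb \
    --aaindex aaindex1.txt --rsa-threshold 0.01 --radius 13 --out features.csv
```

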