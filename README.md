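# topoland

Structural feature landscape of cytoplasmic versus exported bacterial
proteomes.

More than a third of a bacterial proteome leaves the cytoplasm.  Proteins
of the **secretome** (periplasmic enzymes, lipoproteins, outer-membrane
β-barrels, surface/extracellular proteins) must stay unfolded and soluble
while they transit the cytoplasm, cross the inner membrane through a
narrow translocase channel, and only then fold — the opposite demand to
that on their cytoplasmic siblings.  `topoland` is a library (plus thin
CLI) for quantifying the intrinsic features that tell these two protein
classes apart, aimed at structural bioinformaticians studying protein
export, disorder and folding:

* **Sequence features** of mature domains (signal peptide removed):
  residue-set composition fractions, GRAVY (mean Kyte–Doolittle
  hydropathy), isoelectric point (Henderson–Hasselbalch net charge, EMBOSS
  pKa set, solved by bisection), mean biosynthetic cost (ATP equivalents),
  continuous hydrophobic patches and their flanking quintapeptides.
* **Track segmentation** of per-residue predictor outputs into
  intrinsically disordered regions (IDRs, ≥ 5 residues; short 5–19, long
  ≥ 20; a protein with ≥ 30% merged IDR coverage is an IDP), early foldons
  and aggregation-prone regions (APRs) with their gatekeeper flanks.
* **Structure features**: contact maps and relative contact order
  rCO = (1/N) Σ<sub>contacts</sub> |i − j| / L — the length-normalised
  mean sequence separation of residue pairs in spatial contact, a
  folding-speed correlate — plus N–C termini distance and secondary-
  structure content.
* **Fold-repertoire census** across topology groups: unique vs shared
  folds, rare (1–3 proteome occurrences) vs frequent (≥ 4), SCOP-class
  composition, popular folds (≥ 3% of a group's instances), folds per
  protein.
* **Abundance variability**: per-protein VS = SD of log2 abundance across
  growth conditions, binned into very-low/low/moderate/high classes.
* **Group statistics and classification**: Kruskal–Wallis / Fisher exact
  comparisons with the conventional star scheme, positional N-terminal
  profiles, and a seeded cross-validated cytoplasmome-vs-secretome
  classifier with a disorder-feature ablation suite.
* A **synthetic proteome generator** with known ground truth (planted
  composition shifts, segments, fold pools, variability classes), so every
  stage has a recovery test without downloading any external dataset.

## Worked example

Run the default synthetic study — 400 proteins per group — end to end:

```python
from topoland.pipeline import run_synthetic_study

result = run_synthetic_study(seed=1)
print(result.comparisons.loc[["polar", "gravy", "idrs_per_100", "rco"],
                             ["p_value", "stars", "direction"]])
print({r.label: round(r.auc, 3) for r in result.reports})
```

prints

```
                   p_value stars     direction
feature
polar         3.776658e-84   ***     secretome
gravy         7.126798e-81   ***  cytoplasmome
idrs_per_100  3.776507e-13   ***     secretome
rco           3.408651e-45   ***     secretome
{'all_features': 1.0, 'non_disorder': 1.0, 'disorder_only': 1.0}
```

Reading this: on the synthetic proteome the secretome is significantly more
polar, less hydrophobic (lower GRAVY), carries more IDRs per 100 residues
and has higher relative contact order — each direction matching the
programmed ground truth (`result.ledger_check` tabulates all 19 programmed
contrasts; all recover with p < 0.01) — and the planted group contrast is
strong enough that the cross-validated classifier separates the groups
perfectly in every ablation, while permuted labels score at chance
(`result.permuted_report.auc ≈ 0.484`).

The same study is available from the shell:

```bash
topoland simulate --seed 1 --n-per-group 100 --out-dir synth/   # write inputs
topoland features --seed 1 --n-per-group 100 --out features.tsv
topoland compare  --features features.tsv --out comparisons.tsv
topoland classify --features features.tsv --seed 1 --out report.json
```

Real datasets enter through the same readers the simulator writes for:
FASTA sequences, a topology TSV (class letter, signal-peptide length,
essentiality), per-residue score-track TSVs, PDB ATOM records, a fold
table and an abundance matrix.

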