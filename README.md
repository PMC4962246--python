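# erscreen

A two-tier in silico screen for estrogenic activity, built for chemists
evaluating candidate bisphenol-A (BPA) replacement monomers before any
wet-lab assay.

**Tier 1 (qualitative).** Two Decision Forest (DF) classifiers — each
trained on a different curated set of compounds with measured rat
estrogen-receptor (ER) binding data, described by numeric molecular
descriptors — each emit a probability *p* that a compound binds ER. The
consensus probability is their mean; the compound is called a **binder**
when *p* > 0.5 (exactly 0.5 is a non-binder), with prediction confidence

    confidence = |p − 0.5| / 0.5  ∈ [0, 1].

A Decision Forest differs from a random forest: there is no bagging and no
random feature sampling. Each successive CART tree is grown on the full
training set but may only split on descriptors **unused by every earlier
tree**, and the ensemble stops growing when an additional tree no longer
improves the training fit. A compound's probability is the unweighted mean
of the binder fractions in the terminal nodes it reaches.

**Tier 2 (quantitative).** For predicted binders, a docking/MM-GBSA
binding free energy ΔG (kcal/mol, supplied externally) is converted to a
log10 relative binding affinity on the scale where 17β-estradiol has
logRBA = 2:

    logRBA = −7.719 − 0.086 · ΔG

Supporting machinery: descriptor-table I/O with degenerate-column removal
(constant and exact-duplicate descriptors), the five confusion-table
statistics (accuracy, sensitivity, specificity, MCC, balanced accuracy),
repeated five-fold cross-validation, external validation, a synthetic
labeled-descriptor generator for offline testing, and a CLI.

## Worked example

The package ships the 29 published consensus probability pairs for the
candidate BPA replacement compounds. Feeding them through the consensus
tier:

```python
from erscreen import screen, table1_fixture

fx = table1_fixture()
report = screen(probabilities=fx.probability_frame())
print(report.n_binders, report.n_nonbinders)
for r in report.records[:3]:
    print(r.compound_id, r.p_model1, r.p_model2, r.call, f"{r.confidence:.3f}")
```

prints

```
14 15
6 0.984 1.0 binder 0.984
7 0.984 0.8 binder 0.784
8 0.788 0.6 binder 0.388
```

Fourteen of the 29 candidates are called ER binders and fifteen
non-binders. Compound 6's two model probabilities (0.984, 1.000) average
to 0.992, far from the 0.5 boundary, hence confidence 0.984; compound 8
(0.788, 0.600) averages to 0.694, a binder call but at low confidence
0.388.

Training a model of your own from a labeled descriptor table:

```sh
erscreen synth --n-compounds 232 --n-binders 131 --effect-size 2.0 \
         --seed 1 --out train.csv
erscreen fit train.csv --label-column label --out model1.json
erscreen cv train.csv --label-column label --k 5 --repeats 20 --seed 1
erscreen screen model1.json model2.json candidates.csv \
         --energies energies.csv --out report.csv
```

`screen` writes a per-compound CSV (probabilities and confidence to three
decimals, calls as `+`/`-`, logRBA for binders with an energy entry) plus
a full-precision JSON sidecar.

## Layout

- `src/erscreen/dataset_io.py` — descriptor/label/energy table I/O, preprocessing
- `src/erscreen/decision_forest.py` — CART trees, DF fitting, prediction, persistence
- `src/erscreen/validation.py` — metrics, repeated k-fold CV, external validation
- `src/erscreen/consensus.py` — consensus probability, confidence, screen report
- `src/erscreen/affinity.py` — ΔG → logRBA conversion
- `src/erscreen/synthetic.py` — synthetic dataset generator, packaged fixture
- `src/erscreen/cli.py` — `erscreen` command-line interface
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
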