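# borysite

Site-level regioselectivity and yield prediction for undirected,
iridium-catalyzed aromatic C–H borylation.

## The problem

C–H borylation installs a pinacol boronate (Bpin) group at an aromatic
C–H position, giving a versatile handle for cross-coupling in
medicinal-chemistry synthesis. The synthetic question is *which* of a
substrate's chemically similar C–H positions reacts. Qualitatively, the
reaction avoids positions flanked by ortho substituents or basic
(pyridine-type) nitrogen atoms and prefers five-membered heteroarenes
over six-membered ones — but for multi-ring, multi-substituent drug-like
molecules the competing factors quickly outgrow hand rules.

`borysite` treats the problem as per-site binary classification and
per-site yield regression. For a substrate with *k* symmetry-distinct
C–H positions it enumerates the *k* hypothetical monoborylation
reactions `substrate>>site_product`, featurizes each with a 256-bit
**differential reaction fingerprint** (DRFP: the symmetric set
difference of the circular-substructure SMILES shingles of reactant and
product, hashed onto a fixed-length bit vector), and scores each with a
random forest. The fingerprint of a site reaction encodes exactly the
chemical environment the substitution changes, which is what controls
selectivity at the rate-determining C–H oxidative addition.

The package covers the full workflow:

* **curation** — a filtering funnel from raw reaction SMILES to clean
  aromatic C–H borylations: naive C–H/C–B screening, fragmentation of
  products along C–B bonds with reactant matching (which rejects
  Miyaura-type aryl-halide borylations), validity, optional yield
  presence, and the iridium + aromatic-site requirement;
* **site enumeration** — symmetry-class deduplicated candidate sites,
  labeled 0/1 against experimental products (mixtures label several
  sites);
* **models** — scikit-learn-style `SiteReactivityClassifier` and
  `SiteYieldRegressor` estimators over a `DrfpFeaturizer` transformer,
  with molecule-level aggregation (`predict_molecule`) and the
  substrate-substructure post-filter for candidate products;
* **metrics & splits** — MCC/PPV/F1 at the site level, strict all-sites
  molecule-level accuracy, major-product accuracy, yield-regression
  metrics with the 5 % reaction-success threshold, and substrate-level
  random / heterocycle-vs-carbocycle / one-vs-many-ring splits;
* **synthetic data** — a seeded generator of borylation reaction sets
  whose selectivity follows the qualitative guidelines above, used as
  the test bed since curated literature reaction data is
  license-restricted.

## Worked example

```python
from borysite import (CurationConfig, build_site_dataset, curate,
                      predict_molecule, synthesize_dataset, train)

records = synthesize_dataset(200, seed=5, noise=0.0)
retained, funnel = curate(records, CurationConfig(require_yield=True))
dataset, _ = build_site_dataset(retained)
clf = train(dataset, "classifier", seed=7)

pred = predict_molecule(clf, "c1ccncc1")   # pyridine
print(sorted(pred.scores.items()))
print(sorted(pred.reactive_set), pred.major_site, pred.no_reaction_flag)
```

prints

```
[(0, 0.97), (1, 0.85), (2, 0.0)]
[0, 1] 0 False
```

Pyridine's three symmetry-distinct C–H classes get per-site reactive
probabilities: the two classes away from the ring nitrogen (canonical
atoms 0 and 1, the 4- and 3-positions) are called reactive, while the
class adjacent to the basic nitrogen (atom 2) is correctly suppressed.
A substrate with no aromatic C–H at all (e.g. hexafluorobenzene) comes
back with `no_reaction_flag=True`.

The same pipeline is scriptable from the shell:

```
borysite synth --n 200 --seed 5 --out rxns.csv
borysite curate --in rxns.csv --out curated.csv --report funnel.json --require-yield
borysite build-sites --in curated.csv --out sites.csv
borysite train --sites sites.csv --task classify --model clf.joblib --seed 7
borysite predict --model clf.joblib --substrate "c1ccncc1" --json
```

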