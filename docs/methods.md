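# Methods

## Problem framing

Undirected iridium-catalyzed C–H borylation replaces one aromatic C–H
hydrogen by a pinacol boronate group. Selectivity is decided at the
irreversible C–H oxidative addition, so it is a local property of each
candidate position: sterics (ortho substitution), the basicity of
adjacent ring nitrogens, and the ring system the position sits on.
`borysite` casts regioselectivity as supervised learning over *site
reactions*: for each substrate every symmetry-distinct eligible carbon
is turned into the hypothetical reaction `substrate>>site_product`, and
a model classifies the site as reactive or not (and regresses its
yield). Site predictions aggregate to a molecule-level call: the set of
reactive sites, the major site, or "no reaction" when every site is
negative.

## Canonicalization and site identity

All structures run through RDKit with its default aromaticity
perception; the model name is recorded in `RunConfig.aromaticity` so
results are reproducible across toolkit versions. Atom identifiers are
indices into the canonical atom ordering (every `Molecule` re-parses
its own canonical SMILES), so a site id is stable across input
serializations. Two positions are the *same site* iff they are
equivalent under the molecular graph's automorphisms (RDKit canonical
ranking without tie-breaking): substitution at either gives the same
product molecule, so enumeration yields one instance per symmetry
class and site-count metrics weight each unique product once. A
consequence worth noting: reversing a product back to its substrate can
only identify the site up to its automorphism orbit, so the curation
round-trip invariant is checked as symmetry-class equality.

## Curation funnel

Raw records pass, in order: (1) a naive screen — the substrate has a
C–H bond and some product a C–B bond; (2) fragment matching — each
product C–B bond is cleaved, the boron-containing fragment discarded
whole (the boron group's identity is deliberately unrestricted), the
carbon capped with exactly one hydrogen, and the capped fragment
compared with the substrate's canonical SMILES. This is the step with
chemical teeth: a genuine C–H borylation reverses cleanly, while a
Miyaura-type aryl-halide borylation leaves a fragment missing its
halogen and is rejected. (3) validity — unparseable inputs are counted
here and logged by source id, replacing any external
structure-resolution service; (4) optional yield presence; (5) the
iridium + aromatic-site requirement. Retained records are deduplicated
by canonical (substrate, product) pair with agents ignored, because
reaction databases multiply report the same transformation under
different conditions. With several reactant-field molecules the
substrate is the largest boron-free one.

## Differential reaction fingerprints

A molecule's shingles are the canonical SMILES of every atom-centred
circular environment of radius 0..r plus every smallest ring; a
reaction's feature set is the symmetric difference of its reactant-side
and product-side shingle unions, so everything unchanged by the
reaction cancels. Each surviving shingle sets bit `crc32(shingle) mod
n_bits`. Defaults: `n_bits=256`, `radius=3`, ring shingles included.
The 256-bit length is the deliberately compact setting used for the
borylation benchmark; the radius and the inclusion of ring shingles
follow the original differential-fingerprint construction and are
config keys, since the borylation study did not pin them. CRC-32 was
chosen as the shingle hash because it is a named, platform-independent
32-bit function — fingerprints are bit-identical across processes and
machines, which the test suite verifies with subprocesses. Hydrogens
are left implicit in shingle SMILES. Agents never enter the
fingerprint; site reactions are written with the bare substrate on the
left, so boron co-reagents cannot leak into features.

## Models

Both estimators are scikit-learn compatible. The classifier is a
100-tree random forest (Gini, `sqrt` feature sampling) on the 256-bit
DRFPs with the conventional 0.5 majority-vote threshold; the regressor
is a 100-tree forest (squared error, all features). These are the
classical "default hyperparameters", written out numerically in
`FOREST_DEFAULTS` so they cannot drift with library versions. The
regressor trains unreactive sites at 0 % yield; reactive sites lacking
a reported yield are *excluded* rather than imputed, because missing
yields in literature data reflect reporting bias, not failed reactions.
At prediction time a site is called successful when its predicted yield
reaches the 5 % threshold, the conventional cut between a detectable
reaction and none. Major-site ties break to the lowest canonical atom
id, a deterministic and serialization-stable rule. The
substrate-substructure post-filter drops any candidate product that
does not embed the substrate's full molecular graph
(aromaticity-aware), since C–H functionalization leaves the starting
material intact inside the product.

## Synthetic data generator

Curated borylation reaction sets derive from licensed databases, so the
package ships a seeded generator instead of data. Substrates are
assembled from the ring systems that dominate real borylation
substrates (benzene, thiophene, pyridine, furan, pyrazole, pyrimidine,
indole, quinoline, benzothiophene, benzofuran), decorated with 0–3
common substituents (Me, OMe, F, Cl, CF3, CN, CO2Me) and an optional
biaryl linkage (probability 0.25). Selectivity follows an additive rule
score per site: base 2.0 for five-membered heteroaromatic positions,
1.5 for six-membered N-heteroaromatic, 1.0 for carbocyclic; −1.5 per
substituted (or ring-fusion) ortho ring neighbour; −2.0 per adjacent
pyridine-type nitrogen. The constants are generator design choices —
the underlying guidelines are ordinal — set so each rule is decisive in
isolation, and the test suite checks exactly that. Rule-maximal sites
react (ties produce mixtures, emitted as one record per product); major
yields are drawn from N(70, 15) clipped to [5, 99], minor mixture
yields from N(30, 10) clipped to [5, 60], both rounded; an optional
noise rate reassigns a substrate's reactive site uniformly at random.
Yields are only ever reported at ≥5 %, emulating the reporting bias of
literature data. Agents carry an iridium species and B2pin2 so every
synthetic record survives the curation funnel — a generator/curation
round-trip the tests enforce at 100 %.

What the generator does *not* emulate: directing/chelation effects,
electronic activation beyond ring-type ordering, solvent and
stoichiometry effects, the empirical frequency distribution of ring
systems, and real experimental noise structure. Passing the recovery
benchmark therefore shows the featurization + forest pipeline can learn
a local, graph-determined selectivity rule from reaction outcomes; it
does not certify accuracy on real laboratory data.

## Evaluation protocol

Site metrics are computed from the confusion counts with the
degenerate-denominator → 0 convention (MCC, PPV, recall, F1); MCC is
the headline because unreactive sites heavily outnumber reactive ones.
Molecule-level accuracy is strict: all of a substrate's sites must be
correct. Major-product accuracy compares the argmax predicted yield
with the highest experimentally yielding site (experimental ties count
either way; substrates with no labeled site are excluded and counted).
Splits operate on unique substrates, never on reaction records, to
prevent train/test leakage: a seeded random split (default 10 % held
out, matching the ~1 in 10 validation proportion typical for this data
scale), the heterocycle/carbocycle partition by ring kind at the
experimental site (substrates reacting at both kinds go to the
heterocyclic side, logged), and the one-ring/multi-ring partition by
aromatic SSSR count.

## Benchmark problem sizes

The standing recovery benchmark trains on 800 synthetic substrates and
evaluates on 200 held out (seed 7, noise 0, via the package's random
split), about 4200 candidate sites in total with a median of 4
candidate site classes per substrate — the same median the curated
literature set exhibits. Unit and property tests use 20–200 substrate
corpora. On this benchmark the classifier reaches site MCC ≈ 0.64 with
strict molecule-level accuracy 0.50, and the yield regressor's
thresholded outcome-MCC ≈ 0.46 with major-product accuracy ≈ 0.80
(numbers recomputed by `scripts/acceptance.py`, not stored). The gap
between the classifier's MCC and the regressor's outcome-MCC is a known
property of this baseline: thresholding a conservative regression
estimate at 5 % calls borderline sites failed, so the regression route
under-calls reactivity relative to the direct classifier — consistent
with published observations that fingerprint-based yield regression
trails fingerprint-based site classification by a wide margin while
shared-representation transformer heads keep the two consistent.

## Known limitations

* Selectivity factors that are not functions of the local molecular
  graph (chelation, directed borylation, solvent effects) are invisible
  to both the generator and the DRFP features.
* 256-bit fingerprints collide; raising `n_bits` reduces collisions at
  the cost of sparser training signal per bit.
* Stereochemistry is ignored throughout; site identity is 2D.
* The curation funnel's absolute counts on licensed raw data are not
  reproducible here; only the funnel's structure and invariants are.
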