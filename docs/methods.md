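# Methods

## 1. The bioactivity similarity index

Two compounds are encoded as the element-wise **sum of their 256-bit
radius-2 Morgan fingerprints**; each entry is 0, 1 or 2 (2 = substructure
environment present in both). A feedforward network with sigmoid output maps
this 256-vector to the probability that the pair is an **S pair** — both
members active (pChEMBL > 6.5) on the same protein target — as opposed to an
**N pair** (one active, one inactive/decoy). Training pairs are restricted
to **Tanimoto < 0.4** (computed on 2048-bit fingerprints), so the model
learns only in the regime where the Tanimoto coefficient itself is
uninformative.

Reference configurations:

| name | hidden layers | dropout | epochs | learning rate |
|---|---|---|---|---|
| `MPG_CONFIG` (per-group) | [256] | 0.5 | 10 | 1e-3 |
| `LARGE_CONFIG` (cross-family) | [512, 256, 128, 64] | 0.3 | 10 | 1e-4 |

Fine-tuning: 5 epochs at learning rate 1e-4, no layer freezing. The standard
hyperparameter grid crosses 3 architectures × 3 dropouts × 3 epoch settings
= 27 configurations.

The network is a seeded NumPy implementation (Adam with bias correction,
binary cross-entropy, inverted dropout, fan-in uniform initialisation);
training is exactly reproducible from `(config, data, seed)`.

## 2. Dataset protocol

1. **Labeling** — per (compound, target): median pChEMBL > 6.5 → active,
   < 4.5 → inactive, otherwise ambiguous (discarded); an explicit
   "inactive"/"not active" assay comment forces inactive unless the median
   crosses the active threshold.
2. **Diversity cascade** on each target's actives: Bemis–Murcko scaffold
   deduplication (min-id representative; acyclic molecules are their own
   scaffold) → Butina leader clustering at TC ≥ 0.4 (leaders in descending
   neighbour count, id tiebreak) → K-means capping at 100 actives (nearest
   real member to each centroid).
3. **Decoys** — for each active, candidates must fall inside six DUD-E-style
   windows (±25 Da MW, ±1 logP, ±2 rotatable bonds, ±1 HBA, ±1 HBD,
   identical net charge) *and* have TC < 0.3 to that active; 10 are drawn
   uniformly without replacement (seeded), with a logged warning on
   shortfall.
4. **Pairs** — S: all active–active pairs within a target; N: all
   active×(inactive ∪ decoy) pairs. Pairs with TC ≥ 0.4 are dropped, exact
   duplicates deduplicated, and pairs labeled both S and N across targets
   are removed entirely.
5. **Class ratio** — `slight` regime 25:75 S:N, `heavy` 4:96; the excess
   class is subsampled with a seeded generator (e.g. 100 S + 1,000 N →
   100 S : 300 N in the slight regime).

## 3. Evaluation

- **LOPO**: one split per protein target; the held-out target's pairs form
  the test set, and any training pair touching a held-out compound is purged
  (leakage guard, on by default).
- Metrics: ROC-AUC (midrank ties), PR-AUC (average precision), enrichment
  factor at the top 2% (`ceil` slice, stable sort), all cross-checked in the
  tests against brute-force re-implementations.
- **Screening**: 10 unseen actives + 1,500 decoys (TC < 0.3 to every
  library active). Each active queries the remaining 1,509 compounds; the
  recorded statistic is the rank of the best-scoring *other* active (midrank
  for ties, rounded half-up). A random scorer's expected mean rank is
  (L+1)/(n_act+1) = (1509+1)/(9+1) = **151**.
- Paired two-sided t-tests compare per-protein metrics between scorers;
  zero-variance differences are flagged degenerate instead of producing
  NaNs.

## 4. Synthetic universe (generative model)

Real bioactivity data cannot ship with the package, so experiments run on a
synthetic, ChEMBL-like universe with planted ground truth. Per compound,
fingerprint bits are independent Bernoulli draws whose rates depend on role:

- a universe-level **chemotype pool** (128 of 256 bits) and **signature
  pool** (64 bits) fix which positions can ever carry signal; every group
  draws its 96 chemotype bits from the chemotype pool and every target its
  24 signature bits from the signature pool (50% shared within a group via a
  group sub-pool). Bit positions therefore keep one meaning across groups —
  the property that makes transfer learning possible, just as Morgan bits
  mean the same substructure in every protein family.
- **actives** of a target: chemotype bits at rate 0.28, signature bits at
  the signal rate 0.70, everything else at background 0.08.
- **decoys/inactives**: signature bits at q = β + 0.6·(s − β), and a
  chemotype rate c_d solved in closed form so that
  **E[TC(active, decoy)] = E[TC(active, active′)]** — the synthetic analogue
  of DUD-E property matching. With expected intersection/union written in
  the per-bit rates, E[TC] ≈ τ/(1+τ) with τ = Σᵢ pᵢqᵢ / Σᵢ (pᵢ+qᵢ−pᵢqᵢ),
  linear in c_d, giving a one-line solution (clipped to [β, 1]).

Consequences, all verified empirically in the tests:

- active–active TC ≈ 0.23 with ≥ 95% (in practice 100%) of pairs below 0.4;
- active–decoy TC distribution matches active–active (TC-baseline LOPO
  ROC-AUC ≈ 0.5);
- the planted signature is learnable: BSI LOPO ROC-AUC ≥ 0.9;
- at `signal = background` the model collapses to decoys ≡ actives
  statistically and any LOPO AUC outside [0.45, 0.55] indicates leakage;
- a per-bit Bernoulli log-likelihood-ratio **Bayes oracle**
  (`bayes_oracle_score`) upper-bounds achievable discrimination, with the N
  hypothesis a ½-mixture over which pair member is the active.

Activity values: actives pChEMBL ~ U(6.6, 9.5); experimental inactives
alternate pChEMBL ~ U(3.0, 4.4) and an "inactive" comment. Decoy candidates
are property-sampled inside all six matching windows of a paired active.

A second mode (`mode="smiles"`) emits real, RDKit-valid molecules from a
fragment grammar (56 scaffolds × 30 substituents, all 1,680 combinations
valid) for end-to-end tests of the chemistry path (canonicalization,
scaffolds, physchem properties); signal planting is only supported in
fingerprint mode.

### Default problem sizes (package choices)

| quantity | default | note |
|---|---|---|
| targets per group | 8 | LOPO needs ≥ 2 |
| actives per target | 60 | under the 100 cap |
| experimental inactives per target | 10 | half commented, half pChEMBL |
| decoy-candidate pool per active | 20 | ~13 eligible on average |
| decoys selected per active | 10 | |
| transfer experiment | 4 groups × 4 targets × 40 actives | pretrain on 3, adapt to the 4th with 20 actives |
| screening library | 10 actives + 1,500 decoys | |

## 5. Limitations

- The synthetic generator is a deliberately simple independence model: no
  bit correlations within a compound, no activity cliffs, no assay noise
  beyond the sampling itself. It validates the *protocol*, not real-world
  performance.
- SMILES-mode universes exercise the chemistry path but carry no planted
  bioactivity signal, so model-performance experiments use fingerprint mode.
- The NumPy network is exact but not fast; it is sized for the problem
  scales above (minutes, one CPU), not for millions of pairs.
- Spot-checks against named public database entries are not included: the
  package is built and graded fully offline.
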