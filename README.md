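# polyclust

Two-factor clustering of multi-crystal diffraction data for polymorph
detection.

## The problem

Modern synchrotron beamlines collect partial data sets from dozens to
hundreds of small, nominally isomorphous crystals. Molecules in those
crystals are not necessarily in a single conformational state: merging all
data indiscriminately averages distinct polymorphs into one blurred
structure. The remedy is to cluster the per-crystal data sets first and
merge only within clusters, so each cluster can be refined into its own
structural state.

`polyclust` implements a two-factor clustering scheme for this problem:

1. **Coarse stage — unit cells.** Crystals are grouped by unit-cell
   similarity, measured as the Euclidean norm of
   (Δa, Δb, Δc, w·Δα, w·Δβ, w·Δγ) with a configurable angle weight w
   (default 0.25 Å/degree). Cell parameters are available from indexing
   alone, so this works even for thin data wedges.
2. **Fine stage — structure-factor amplitudes.** Within each coarse
   cluster, the similarity of two crystals i, j is the Pearson correlation
   coefficient CC(i, j) of their amplitudes over the Miller indices both
   observed (after mapping to the asymmetric unit of the Laue group and
   merging symmetry equivalents). The distance

       d(i, j) = [1 − CC(i, j)]^(1/2)

   feeds Ward minimum-variance hierarchical clustering; cutting the
   dendrogram at a height k yields the fine clusters. Crystals below a
   completeness threshold (default 70%) are excluded from the CC stage, or
   admitted at much lower completeness with a penalty for unmatched
   structure factors, d = [1 − CC·w]^(1/2) with w = 2·n_common/(n_i+n_j).

The package also provides: structure-factor averaging per cluster with
merging statistics (R_merge, completeness, multiplicity), a seeded
synthetic-data generator with planted cell polymorphs and amplitude
subgroups, and the diagnostics used to decide which clusters are physically
meaningful — per-residue maximum Cα displacement profiles, minimum-volume
enclosing ellipsoids of per-cluster Cα positions, cell-parameter scatter
and colored dendrograms.

## Worked example

Simulate 40 crystals drawn from two tetragonal cell polymorphs
(a ≈ 111.4 Å and a ≈ 114.5 Å, c ≈ 52 Å) containing 3 + 2 amplitude
subgroups, then run the two-factor workflow:

```python
from collections import Counter
from sklearn.metrics import adjusted_rand_score
from polyclust import (SimulationConfig, ClusterConfig,
                       generate_reflection_sets, two_factor_cluster,
                       merge_cluster)

cfg = SimulationConfig(n_sets=40, seed=1)
sets, truth = generate_reflection_sets(cfg)
assignment, trees = two_factor_cluster(sets, ClusterConfig(),
                                       cell_cut=2.0, amp_cut=1.0)
ids = [s.id for s in sets]
print("coarse clusters:", Counter(assignment.coarse_of[i] for i in ids))
print("fine clusters:  ", Counter(assignment.labels[i] for i in ids))
print("fine ARI:", adjusted_rand_score(truth.fine_labels(ids),
                                       [assignment.labels[i] for i in ids]))

members = [s for s in sets if assignment.labels[s.id] == 0]
merged, report = merge_cluster(members, cluster_id="cluster0",
                               apply_scaling=True)
print(report.table())
```

Output:

```
coarse clusters: Counter({0: 32, 1: 8})
fine clusters:   Counter({0: 11, 1: 11, 2: 10, 3: 4, 4: 4})
fine ARI: 1.0
cluster             cluster0
data sets           11
unique reflections  6979
observations        73069
completeness        1.000
R_merge             0.0806
multiplicity        10.47
<F/sigF>            26.37
```

The coarse stage splits the crystals 32/8 by cell polymorph; the fine stage
recovers all five planted amplitude subgroups exactly (adjusted Rand index
1.0 against the generator's ground truth). Merging one 11-crystal cluster
gives a complete data set with R_merge ≈ 8% — consistent with the ~10%
multiplicative amplitude noise the generator plants.

The same workflow is available from the shell:

```sh
polyclust simulate --seed 1 --n-sets 40 --out sim/
polyclust cluster sim/ --cell-cut 2.0 --amp-cut 1.0 --out clust/
polyclust merge sim/ --assignment clust/assignment.tsv --out merged/
polyclust viz --assignment clust/assignment.tsv --linkage clust/linkage.json \
              --hkl-dir sim/ --out figs/
```

## Layout

- `polyclust.reflection_model` — unit cells, Laue groups (−1, 2/m, mmm,
  4/mmm), ASU mapping, merging of equivalents, d-spacings, completeness,
  HKL text I/O
- `polyclust.cell_cluster` — cell distance and the coarse partition
- `polyclust.amplitude_cluster` — CC matrices, distance transforms, Ward
  linkage, dendrogram cuts, the combined two-factor workflow
- `polyclust.cluster_merge` — per-set scaling, structure-factor averaging,
  R_merge and merge reports
- `polyclust.ensemble_analysis` — PDB Cα extraction, rigid superposition,
  displacement profiles, minimum-volume ellipsoids, plot-ready exports
- `polyclust.synthetic_data` — seeded generators of reflection data and
  coordinate ensembles with planted ground truth
- `polyclust.cli` — the `polyclust` command

See `docs/methods.md` for the model assumptions, parameter choices and
limitations.
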