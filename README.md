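# h4screen

Sequential ligand-based and structure-based virtual screening for human
histamine H4 receptor (hH4R) antagonists.

The hH4R is a class-A GPCR with two negatively charged orthosteric
residues (Asp at Ballesteros–Weinstein position 3.32, Glu at 5.46); its
known antagonists are small, positively charged, nitrogen-rich
molecules. `h4screen` implements the screening workflow that exploits
this: a ligand-based stage learns axis-aligned descriptor-range filters
separating antagonists from decoys and combines them into a single
ranking score, and a structure-based stage triages docking poses of the
top-ranked compounds by their electrostatic energies and their contacts
with the two anchor carboxylates. It is aimed at computational chemists
who want a transparent, fully reproducible rank-and-filter pipeline
rather than a black-box scoring function.

## Method

**Range filters and ISE.** A *filter* is a conjunction of closed
intervals over a panel of eleven 2D descriptors (molecular weight,
formal charge, N/O counts, aromatic atoms, H-bond donors/acceptors,
logP, rings, rotatable bonds, fractional negative VdW surface area). A
molecule passes iff every constrained descriptor lies in its interval.
Filter quality is the Matthews correlation coefficient on
class-normalised counts: with PA the percentage of actives and PNA the
percentage of non-actives passing,

    MCC = (PA·NNA − PNA·NA) / √((PA+PNA)(PA+NA)(NNA+PNA)(NNA+NA)),

where NA = 100 − PA, NNA = 100 − PNA. Interval bounds live on a
quantile discretisation of the training data; Iterative Stochastic
Elimination (ISE) samples random filters, ranks them by MCC, eliminates
cut-point values over-represented among the worst samples, and finishes
with exhaustive enumeration once the surviving space is small. The
canonical example of such a filter is the published three-rule
antagonist model — formal charge +1, 3 ≤ N atoms ≤ 7, fractional
negative VdW surface area ≤ 0.42 — whose printed per-class rates (87%
of actives, 5% of decoys passing) give MCC 0.82.

**MBI ranking.** The n retained "efficient filters" are combined into
the Molecular Bioactivity Index: a molecule earns +PA_i/PNA_i for every
filter i it passes and −NNA_i/NA_i for every filter it fails, averaged
over filters. Libraries are ranked by descending MBI and the top
fraction becomes the focused set.

**Pose triage.** Docking poses (best pose per compound, by total docked
energy) are filtered conjunctively by (1) membership of the lowest one
or two electrostatic-energy clusters found by exact 1-D k-means, and
(2) a distance score counting the anchor residues (of the two) whose
carboxylate oxygens lie strictly within 4 Å of a polar heavy ligand
atom. Enrichment factors — active pass % over reference pass % — are
estimated with sub-sampling of the reference set, and the consensus
library is the pose-filter passers in MBI rank order.

Since the original screening libraries and docking runs are not
redistributable, the `synthsets` module generates statistically
faithful stand-ins with planted ground truth (rule-satisfying actives,
binder poses in contact with both carboxylates), so every stage is
testable end to end.

## Worked example

```python
from h4screen import default_config, run_pipeline

manifest = run_pipeline(default_config(workdir="run1", seed=7))
for stage in manifest["stages"]:
    print(stage["name"], {k: v for k, v in stage.items()
                          if k in ("n_filters", "best_mcc", "n_focused_active",
                                   "boundaries", "enrichment_factor", "n_selected")})
```

prints (numbers from this exact seed):

```
training_set {}
learn {'n_filters': 251, 'best_mcc': 0.8708904174815991}
score {'n_focused_active': 388}
triage {'boundaries': [-2.7847357077175294, -0.4835733974479957]}
enrich {'enrichment_factor': 14.480771458357466}
consensus {'n_selected': 11}
```

Reading: ISE learned 251 efficient filters (best MCC 0.87) on a
synthetic training set; MBI ranking placed 388 of the 500 planted
actives in the focused top 10% of a 5500-compound library; k-means on
the pose electrostatic energies put the cluster boundaries at −2.78 and
−0.48 kcal/mol; the combined EE + distance filters enriched actives
14.5-fold over the random reference set (the generator's analytic
expectation is 20, within sampling error at these population sizes);
and 11 consensus candidates passed both stages. Rerunning with the same
seed reproduces every output checksum.

The same workflow is available from the shell:

```bash
h4screen simulate descriptors --seed 3 --out set.csv
h4screen learn --train set.csv --bins 8 --seed 5 --out ensemble.json
h4screen score --library set.csv --ensemble ensemble.json --out ranked.csv
h4screen run --workdir run1 --seed 7
```

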