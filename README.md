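# gamerge

Genetic-algorithm grouping of partial multi-crystal diffraction data sets
for anomalous-signal recovery.

Mesh and serial crystallography experiments collect hundreds of partial
*sub-data sets* — small wedges from individual micro-crystal positions —
that must be merged into one data set. When phasing relies on a weak
anomalous signal (Bijvoet ratios of 1–2%), merging everything is often the
wrong move: non-isomorphism between crystals inflates merging residuals and
washes out the Friedel-pair differences that carry the signal. Picking the
best subset to merge is combinatorial (2ⁿ − 1 subsets for n wedges), so
`gamerge` searches the space with a genetic algorithm:

* a **chromosome** is an integer array of length n assigning each sub-data
  set to a merging group (default three groups: two candidate isomorphous
  groups plus a low-quality sink);
* **fitness** of a chromosome is the score of its best group,
  `−w_R·R_meas(inner) + w_I·⟨I/σ⟩ + w_anom·CC_anom + w_half·CC1/2 +
  w_comp·completeness + w_mult·multiplicity` (overall-shell values except
  R_meas), with default weights 1.0, 2.0, 0.0, 1.0, 0.2, 0.0 and an
  optional one-cycle automatic balancing that rescales each term to a
  common magnitude `r_user`;
* mutation (p = 0.6), single/double crossover (p = 0.3), tournament
  selection and elitism evolve the population; **every evaluation is kept
  in an archive**, so one run yields thousands of scored groupings for
  statistic-versus-signal analysis.

The package also contains the complete merging-statistics engine (R_merge,
R_meas, ⟨I/σ⟩, CC1/2, CC_anom, SigAno, completeness, multiplicity; inner /
outer / overall shells), a synthetic multi-crystal generator with planted
anomalous signal and non-isomorphous classes, an exhaustive oracle for
small pools, a matched-budget random control, and archive analysis tools.
See `docs/methods.md` for the model and all conventions.

## Worked example

```python
import gamerge as gm
from gamerge import GeneticGrouping, GAConfig, SyntheticConfig, ClassSpec

# a small synthetic pool: two non-isomorphous classes of 10 wedges + 4 junk,
# 1.5% Bijvoet ratio, known ground truth
cfg = SyntheticConfig(
    n_unique=300, seed=7,
    classes=[ClassSpec("A", 10, 1.0, 0.0, 0.15), ClassSpec("B", 10, 0.9, 4.0, 0.15)],
    junk_count=4,
)
pool, truth = gm.make_pool(cfg)

model = GeneticGrouping(pool, config=GAConfig(population_size=30, generations=40, seed=7))
res = model.fit(auto_balance=True, r_user=0.1,
                user_multipliers={"r_meas": 1.0, "i_over_sigma": 2.0, "cc_anom": 0.0,
                                  "cc_half": 1.0, "completeness": 0.2, "multiplicity": 0.0})
print(res.summary())
print(res.compare_with_all(truth).to_text())
```

This prints (abridged):

```
Genetic-algorithm merging-group selection
=========================================================
pool: 24 sub-data sets, 8296 observations, 300 unique reflections
config: population 30, generations 40, groups 3, p_mut 0.6, p_cx 0.3, seed 7
evaluations archived: 1200
best fitness: 0.271953 (group 0, 10 sub-data sets)

all-merged vs GA-selected group  (inner / outer / overall)
  sub-data sets: 24 vs 10
  r_meas         all: 0.1734 / 0.3227 / 0.2213       GA: 0.03027 / 0.1179 / 0.05791  [improved]
  cc_half        all: 0.9974 / 0.9742 / 0.9966       GA: 0.9998 / 0.9954 / 0.9995  [improved]
  cc_anom        all: 0.2745 / 0.3306 / 0.1719       GA: 0.462 / 0.2662 / 0.261  [improved]
  multiplicity   all: 26.3 / 28.07 / 27.65           GA: 10.9 / 10.97 / 11.49
  anomalous recovery: all 0.130 vs GA 0.507
```

The selected ten wedges are exactly planted class B: against the all-merged
set, R_meas drops from 22% to 6%, the anomalous half-set correlation rises
from 17% to 26% overall, and the correlation of merged Bijvoet differences
with the planted ground truth ("anomalous recovery") rises from 0.13 to
0.51 — at less than half the multiplicity. That is the method's central
trade: discard data to gain signal.

## Command line

Each step is also a subcommand of the `gamerge` CLI, with explicit seeds
and parameter logs:

```sh
gamerge simulate --seed 1 --out-prefix scratch/demo
gamerge stats   --pool scratch/demo.pool.tsv --subset all
gamerge ga-run  --pool scratch/demo.pool.tsv --balance --r-user 0.1 \
                --seed 1 --out-prefix scratch/run
gamerge control --pool scratch/demo.pool.tsv --seed 1 --out-prefix scratch/ctrl
gamerge analyze --archive scratch/run.archive.csv --pool scratch/demo.pool.tsv \
                --truth-prefix scratch/demo
gamerge compare --pool scratch/demo.pool.tsv --grouping scratch/run.grouping.json \
                --truth-prefix scratch/demo
```

Input is either the internal table format (`subdataset h k l I sigI`) or
unmerged XDS_ASCII HKL files (one per sub-data set, parsed with gemmi).

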