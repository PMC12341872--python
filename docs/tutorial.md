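# Tutorial: the five-step validation pipeline

The canonical workflow, start to finish, on a synthetic population.  Each
step is one CLI call; the same operations are available as library
functions (shown at the end).

## 0. Make a dataset (stands in for your renumbered data)

```sh
lrvalidate simulate --outdir . --seed 42
```

writes `pedigree.txt` (animal, sire, dam), `data_whole.txt` and
`data_partial.txt` (the latter with the last generation's records flagged
missing), `focal_ids.txt` (the last cohort) and
`true_breeding_values.txt` (simulation ground truth, not used by the
validator).

With real data you bring your own renumbered pedigree/data files and a
focal ID list; the partial dataset is the whole dataset with the focal
records flagged missing (`truncate_to_partial` does this in the library).

## 1. Parameter file

```text
DATAFILE data_whole.txt
DATAFILE_PARTIAL data_partial.txt
PEDFILE pedigree.txt
COLUMNS id gen sex t1 m1
ID id
FIXED mean gen sex
TRAITS t1
MISSING_FLAGS m1
N_TRAITS 1
GENETIC_COVARIANCE
 0.3
RESIDUAL_COVARIANCE
 0.7
OPTION validation 4 focal_ids.txt
OPTION store_pev_pec 4 full
OPTION se exact
OPTION predictive_ability
OPTION include_effects 4
```

Effects are numbered in model order (mean = 1, gen = 2, sex = 3,
animal = 4), so `OPTION validation 4` validates the additive genetic
effect.  `OPTION store_pev_pec` makes the blup runs write the PEV store
that exact-mode intervals need.  Unknown options are fatal, never ignored.

## 2.–5. Solve, predict, solve, validate

```sh
lrvalidate blup     --config par.txt --dataset whole    # solutions_whole + pev_1_Cw22 + pev_1_G22 + acc_1_whole
lrvalidate predict  --config par.txt                    # yhat_residual (adjusted phenotypes y*)
lrvalidate blup     --config par.txt --dataset partial  # solutions_partial + pev_1_Cp22 + acc_1_partial
lrvalidate validate --config par.txt --out report.json
```

Variants:

* point estimates only — drop `OPTION se ...` (and `store_pev_pec`);
* bootstrap intervals — `OPTION se boot` (+ `OPTION nrepboot 10000` to
  change the default 10,000), no PEV store needed;
* approximated intervals — `OPTION se approx`, which reads the
  reliability files `acc_1_whole` / `acc_1_partial` instead of the store.

## Library equivalent

```python
import numpy as np, lrvalidate as lv

cfg   = lv.SimConfig(seed=42)
pop   = lv.simulate(cfg)
ped, model, vc = pop.pedigree, pop.model_spec(), cfg.variance_components()
pheno = pop.phenotype_table()
focal = lv.focal_last_generation(pop)
part  = lv.truncate_to_partial(pheno, focal=focal)

sw = lv.solve_mme(pheno, ped, vc, model)
sp = lv.solve_mme(part,  ped, vc, model)
block = lv.extract_focal(lv.solutions_table(sw), lv.solutions_table(sp),
                         model.genetic_effect_number, focal)
block.ystar = lv.adjusted_phenotypes(sw, pheno,
                                     model.genetic_effect_number).for_focal(focal)

h  = float(np.sqrt(lv.heritability(vc, 1)))
st = lv.compute_statistics(block, vc.sigma_g2(1), h=h, want_predictivity=True)

blocks, rel_w, rel_p = lv.covblocks_from_runs(sw, sp, ped, focal)
spec = lv.CiSpec(alpha=0.05)
print(lv.ci_bias_exact(st.bias, blocks, spec))
print(lv.ci_dispersion_exact(st.dispersion, blocks, spec))
```
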