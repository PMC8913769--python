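# imperham

Implicitly perturbed Hamiltonian (ImPerHam) molecular representations, with
the screening and learning protocols built on top of them: mRMR feature
selection, capacity-controlled single-hidden-layer neural networks with a
replica t-test acceptance protocol, and linear-SVM classification.

## The idea

A continuum solvation model perturbs a solute's Hamiltonian through the
dielectric response of an implicit solvent.  Instead of using that
perturbation only to estimate a solvation free energy, one can treat the
*energy attributes of the perturbed Hamiltonian itself* — evaluated in a
whole panel of media — as a molecular representation.  For each molecule and
each medium in a panel (vacuum plus nine solvents spanning dielectric
constants from ~1.9 to ~80: hexane, benzene, ether, ethyl acetate, phenol,
1-octanol, acetone, acetonitrile, water), eighteen scalar attributes are
collected: total and SCC energies, frontier-orbital eigenvalues and the
HOMO–LUMO gap, the solvation free-energy decomposition
(G_total, G_elec, G_cav, G_hb, infinite-dilution shift), the gradient norm,
electrostatic/exchange-correlation partial energies, dispersion, repulsion,
and atomization energy — a 10 × 18 = 180-dimensional descriptor per
structure.  Because these are energies and free energies, they relate
directly to most thermodynamic observables while remaining invariant to
translation, rotation and atom permutation.

Three task modes are supported:

* **conformers** — delta-learning of conformer relative energies: within
  each conformer group the lowest-energy member becomes the reference, and
  features and target are re-expressed as deviations from it;
* **solvation** — solvation free-energy regression: no delta treatment, but
  the solvent's dielectric constant joins the feature vector;
* **classification** — binary activity (inhibitor / non-inhibitor)
  prediction with a soft-margin linear SVM.

The regression protocol is deliberately conservative.  Candidate networks
have one tanh hidden layer whose width is capped so the training partition
provides roughly ten samples per adjustable constant, P = (d+1)h + (h+1).
A grid over mRMR input-set sizes, hidden widths, data divisions (60/15/25
train/validation/test, group-aware so conformers of one system never
straddle partitions) and weight initializations is searched; any candidate
beating the incumbent validation MUE must then survive *replica validation*:
retrained from its optimized weights under many fresh random divisions, it
is accepted only if a Welch t-test finds no significant difference
(p ≥ 0.05) between training and validation unsigned errors in at least 80%
of replicas.  Accuracy is reported as

    MUE  = (1/N) Σ |y_exp − y_pred|        RMSE = sqrt((1/N) Σ (y_exp − y_pred)²)

in kcal/mol.

An adapter for an external GFN2-xTB/ALPB engine is included (pattern-based
stdout parsing, Hartree → kcal/mol conversion); all tests and examples run
on a built-in deterministic mock engine with documented closed forms, so the
entire pipeline works offline.

## Worked example

Generate a synthetic conformer dataset with a known planted linear truth
(100 dimer-like groups × 5 conformers, Gaussian noise σ = 0.5 kcal/mol),
delta-correct it, screen the 180-column pool, and run the protocol:

```python
import imperham as ip

spec = ip.SyntheticSpec(preset="conformers", n_groups=100, noise_sigma=0.5, seed=11)
ds = ip.gen_conformer_dataset(spec)
fm, refs, y = ip.delta_correct(ds.features, ds.groups, "vacuum|1", target=ds.target)
groups = dict(zip(fm.sample_ids, fm.group_ids))

sel = ip.mrmr_select(fm, y, sizes=[4, 8])
print("top-4 mRMR columns:", sel.per_size_sets[4])

run = ip.protocol_search(fm, y, sel.per_size_sets, groups=groups,
                         n_divisions=2, n_inits=2, replica_budget=20, seed=3)
best = run.best_result
print(f"accepted model: {len(run.best_model.input_columns)} inputs, "
      f"{run.best_model.hidden_units} hidden units "
      f"({run.best_model.n_parameters} parameters)")
print(f"test MUE  = {best.test_mue:.3f} kcal/mol "
      f"(Bayes MUE for sigma=0.5: {ip.bayes_mue(0.5):.3f})")
```

prints

```
top-4 mRMR columns: ['water|7', 'acetone|9', 'vacuum|3', 'acetonitrile|7']
accepted model: 4 inputs, 3 hidden units (19 parameters)
test MUE  = 0.549 kcal/mol (Bayes MUE for sigma=0.5: 0.399)
```

The selector lands on the water total solvation free energy (`water|7`) and
the acetone cavitation term (`acetone|9`) — linear combinations of the
planted truth columns, which the delta correction preserves exactly — and
the accepted 19-parameter network sits close to the best error any model
could reach given the injected noise (the delta correction also folds each
group's reference-row noise into its members, which is why the achievable
MUE lies somewhat above σ·√(2/π)).

The same stages are available as a shell tool:

```bash
imperham synth --preset conformers --seed 7 --out run/synth
imperham featurize --structures run/synth/structures.xyz \
    --groups run/synth/groups.csv --target run/synth/target.csv \
    --delta --out run/feat
imperham select --features run/feat/features.csv \
    --target run/feat/target_delta.csv --sizes 4:16 --out run/sel
imperham train-ann --features run/feat/features.csv \
    --target run/feat/target_delta.csv --selection run/sel/selection.json \
    --divisions 4 --inits 4 --replicas 20 --seed 3 --out run/ann
imperham analyze --trial-log run/ann/trial_log.json --out run/analysis
```

Every stage writes a manifest (config hash, seeds, timings); a seeded
mock-path run is byte-for-byte reproducible from its manifest.

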