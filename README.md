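# flychrome

Why are biting flies attracted to blue? `flychrome` models the visual
front end of a generic higher fly — five photoreceptor classes (R1-6, R7p,
R7y, R8p, R8y) viewing natural scenes under open/cloudy daylight and under
woodland shade — and trains small neural-network ensembles to make the two
discriminations a host-seeking fly needs: *animal vs. leaf* and *shaded
vs. unshaded*. Trained networks are then challenged with the reflectance
spectra of blue, black and violet fabrics used in tsetse and stable-fly
control devices, to measure how often such fabrics are mistaken for animal
hosts or for shade.

The package is aimed at visual ecologists and vector-control researchers
who want a reproducible, fully synthetic test bed for photoreceptor-based
classification analyses: every stage — spectra, illuminants,
sensitivities, excitations, classifiers, interpretability — is generated,
computed and evaluated in code, with real measured spectra substitutable
through plain CSV loaders.

## The model

The quantum catch of receptor *i* for a stimulus with reflectance R_s
under irradiance I_s, against an adapting background (mean leaf, open
illumination) R_b, I_b, is the von Kries ratio

    Q_i = ∫₃₀₀⁷⁰⁰ I_s(λ) R_s(λ) S_i(λ) dλ / ∫₃₀₀⁷⁰⁰ I_b(λ) R_b(λ) S_i(λ) dλ

and the receptor signal is the excitation E_i = ln Q_i. A stimulus set of
72 leaf-green and 72 grey–brown (melanin) reflectances × 2 illumination
conditions yields a 288-record excitation database. Classifiers are
fully connected k→3→1 logistic networks trained by maximum conditional
likelihood; per task, 100 networks are trained on a random 60% of stimuli
and the best-fitting one is kept, over 20 repeated splits — an ensemble of
20 networks whose held-out accuracy, input-clamping behaviour and fabric
votes are the analysis outputs. See `docs/methods.md` for the full
account.

## Worked example

```python
from flychrome import (SpectrumTable, TaskSpec, TrainConfig,
                       build_excitation_dataset, evaluate_fabrics, run_ensemble)
from flychrome.cli_reports import RunConfig, build_study_inputs

leaves, animals, fabrics, illuminants, receptors = build_study_inputs(
    RunConfig(master_seed=1))
dataset = build_excitation_dataset(
    SpectrumTable.concat([leaves, animals]), illuminants, receptors)
print(len(dataset))                      # 288

shaded = run_ensemble(dataset, TaskSpec("shaded"), TrainConfig(master_seed=42))
animal = run_ensemble(dataset, TaskSpec("animal"), TrainConfig(master_seed=43))
print(f"shaded {shaded.mean_accuracy:.3f}  animal {animal.mean_accuracy:.3f}")
# shaded 1.000  animal 0.930

fabric_ds = build_excitation_dataset(fabrics, illuminants, receptors,
                                     background=dataset.background_reflectance)
report = evaluate_fabrics(animal, shaded, fabric_ds)
print(report[["fabric_id", "p_animal_open", "p_shaded_open",
              "p_shaded_shade"]].head(1).to_string(index=False))
#       fabric_id  p_animal_open  p_shaded_open  p_shaded_shade
# phthalogen_blue            0.9            0.0             1.0
```

Reading: the shaded task is solved almost perfectly from achromatic
intensity; the animal task is harder (ln-transformed, illumination-
invariant chromatic cues only). The phthalogen-blue fabric is voted
'animal' by 18 of the 20 animal-networks under open light, is never called
'shaded' in the open, and is always called 'shaded' under woodland shade —
blue objects resemble hosts, not shadows, to the model fly.

The same pipeline runs end to end from the shell:

```bash
flychrome run-all --seed 1 --out results/run1        # full report bundle
flychrome subsets --task animal --seed 1 --out results/run1
flychrome check --seed 1                             # quick invariants
```

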