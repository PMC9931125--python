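# moanet

Ensemble network models of drug mechanism of action.

`moanet` is for systems-biology researchers who want to ask, *given a
drug's protein targets and a molecular characterization of a disease,
by which network paths and how strongly does the drug revert the
disease state — alone and in combination with another drug?*  It
implements the full loop: constraint-trained ensembles of weighted
signal-propagation models over a directed protein–protein interaction
network, motive-level intensity scoring, combination synergy, MoA path
extraction, and hypergeometric enrichment of the modulated proteins —
plus a seeded synthetic-data generator with planted mechanisms so the
whole pipeline is testable without any proprietary interactome or
training database.

## The model in brief

A disease is characterized by *motives* — pathophysiological processes,
each a set of protein effectors with disease signs ±1.  Drug targets
are clamped at ±1 and the signal propagates synchronously over the
weighted network,

x_v(t+1) = clip( Σ_{u→v} w_{uv} x_u(t), −1, 1 ),

for a fixed number of steps (default 3), with the basal motive's
effectors as the initial patient state.  Link weights are trained
against a *truth table* of stimulus→response rules by simulated
annealing; every solution with accuracy strictly above 90% is retained
until an ensemble of 250 solutions — the model — is assembled.  On the
ensemble-mean activity profile each motive is scored by

- **#Eff** — effectors *reversed*: activity opposite to the disease
  sign with |activity| ≥ 0.1 (and **#-Eff**, pushed the disease way),
- **T-Signal** = mean(−disease_sign × activity) over the motive,
- **W-Signal** = ((1+#Eff)/(1+#-Eff)) · (#Eff/BED_p) + T-Signal,

where BED_p is the motive's effector count.  A two-drug combination is
*synergistic* on a motive when its W-Signal strictly exceeds both
single-drug values.  High-support target→effector paths across the
ensemble form the mechanism-of-action subgraph, and up/down-regulated
protein sets (|activity| ≥ 0.1) are tested for enrichment against
annotation collections (terms of ≥ 500 proteins excluded,
Benjamini–Hochberg q < 0.05 per direction and collection).

See `docs/methods.md` for assumptions, parameter defaults, and the
design choices made where the underlying method is under-specified.

## Worked example

Generate a small planted fixture, train an ensemble, and score both
drugs and their combination:

```python
from moanet import (FixtureSpec, TrainingConfig, generate_fixture,
                    build_ensemble, ensemble_profile)
from moanet.metrics import (drug_stimulus, combination_stimulus,
                            impact_table, assess_synergy)

spec = FixtureSpec(
    n_nodes=60, m=4, effectors_per_motive=(5, 5, 6), n_shared_effectors=1,
    motive_names=("Cytokine storm", "Tissue damage", "Baseline state"),
    targets_per_drug=(1, 1), n_bioflags_per_drug=1, n_rules=10,
    n_terms=8, term_size_range=(4, 12), seed=3)
fix = generate_fixture(spec)

cfg = TrainingConfig(target_size=25, max_attempts=100, n_iterations=1500, seed=3)
ens = build_ensemble(fix.network, list(fix.rules), cfg, fix.drugs)

basal = fix.characterization.basal_state()
profiles = {d.name: ensemble_profile(fix.network, ens.solutions,
                                     drug_stimulus(d).with_basal(basal))
            for d in fix.drugs}
profiles["DrugA+DrugB"] = ensemble_profile(
    fix.network, ens.solutions,
    combination_stimulus(*fix.drugs).with_basal(basal))
print(impact_table(profiles, fix.characterization).round(3).to_string(index=False))
```

which prints (25 solutions retained, mean accuracy 1.000):

```
  treatment         motive  n_eff  n_anti  bed_p  pct_reversed  t_signal  w_signal
      DrugA Cytokine storm      4       0      5        80.000     0.187     4.187
      DrugA  Tissue damage      3       0      5        60.000     0.093     2.493
      DrugA Baseline state      4       2      6        66.667     0.260     1.371
      DrugB Cytokine storm      2       0      5        40.000     0.210     1.410
      DrugB  Tissue damage      1       0      5        20.000     0.090     0.490
      DrugB Baseline state      5       0      6        83.333     0.282     5.282
DrugA+DrugB Cytokine storm      5       0      5       100.000     0.343     6.343
DrugA+DrugB  Tissue damage      4       0      5        80.000     0.206     4.206
DrugA+DrugB Baseline state      5       0      6        83.333     0.467     5.467
```

Each row reads: of the motive's `bed_p` effectors, the treatment
reverses `n_eff` (`pct_reversed` %) and worsens `n_anti`; `t_signal` is
the mean reversion strength and `w_signal` the composite intensity.
Here the combination reverses all five cytokine-storm effectors, and

```python
assess_synergy(4.187, 1.410, 6.343).label   # -> 'synergistic'
```

classifies it as synergistic there, since 6.343 exceeds both
single-drug W-Signals.

The same pipeline is available from the shell:

```sh
moanet run-all --seed 1 --outdir out/       # simulate -> train -> analyze -> enrich
```

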