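# mlal — active learning for reactive machine-learning potentials in solution

Modelling a chemical reaction in explicit solvent with a machine-learning
potential (MLP) stands or falls with the training set: it must cover the
reactant, transition-state and product regions *and* the solute–solvent and
solvent–solvent interactions around them, while every label costs an
expensive reference (electronic-structure) calculation. `mlal` implements
an active-learning (AL) workflow that builds such training sets
automatically, plus the analysis stack used to study the resulting reaction
dynamics. It is aimed at method developers who want a complete, inspectable,
desk-scale implementation of the workflow: every component — descriptors,
selectors, MLP, MD, free-energy machinery — is pure scientific Python, and
built-in analytic potentials stand in for the reference method so the whole
pipeline runs on one workstation.

## The workflow

Starting from a small labeled set, the loop repeats:

1. train the MLP on the current set;
2. run a short MLP-MD episode of **(n³ + 2) fs** (n = MD-run index, reset
   to 0 after every accepted structure; 0.5 fs timestep);
3. hand the episode's last frame to a **selector**:
   * *energy* — add if E_T < |E_ref − E_MLP| ≤ 10·E_T, discard above
     10·E_T (needs a reference call per frame);
   * *similarity* — add if max(**K**) < k_T, where
     K_i = |**p**₀·**p**ᵢ|^ζ over unit-normalized global SOAP descriptors;
   * *distance* — add if the frame's local outlier factor in descriptor
     space exceeds the 80th percentile of the training set's own LOF values;
4. label accepted frames with the reference, append, retrain, reset n.

The run converges when no structure is selected within the maximum
simulation time (default 5 ps). Descriptor-based selectors need reference
calls only for *accepted* frames — the core efficiency argument for them.

The internal MLP is ridge regression on SOAP power spectra (linear,
extensive features; optionally several descriptor channels at different
length scales) trained on energies and forces; forces come from analytic
descriptor gradients. Umbrella sampling with WHAM reconstruction,
downhill/uphill trajectory ensembles with bond-formation time gaps, radial
distribution functions and hydrogen-bond statistics complete the toolkit.

## A worked example

Train an MLP for a small water cluster with the similarity selector and
check its accuracy against the reference potential:

```python
from mlal import ALConfig, al_train, mad_metrics
from mlal.descriptors import SoapParams
from mlal.potentials import ToyWaterPotential
from mlal.selectors import SimilaritySelectorConfig
from mlal.studies import calibrated_similarity_kt, reference_snapshots
from mlal.systems import equilibrated_water_cluster

reference = ToyWaterPotential()                       # stands in for the QM backend
cluster = equilibrated_water_cluster(8, reference, rng_seed=0)
initial = reference_snapshots(reference, cluster, 10, rng_seed=1, labeled=False)

soap = SoapParams(r_cut=6.0, sigma_atom=0.25, n_max=9,
                  radial_power=1.3, radial_width_factor=0.8)
# operating point of the similarity selector, calibrated from the spread of
# the initial data itself
k_T = calibrated_similarity_kt(initial, soap)

cfg = ALConfig(
    selector="similarity",
    selector_config=SimilaritySelectorConfig(k_T=k_T, zeta=4),
    soap=soap, max_time=200.0, rng_seed=7,
)
result = al_train(initial, reference, cfg, start_config=cluster)

held_out = reference_snapshots(reference, cluster, 40, rng_seed=99,
                               interval_fs=10.0, labeled=False)
mad_e, mad_f = mad_metrics(result.model, reference, held_out)
print(f"converged={result.converged} training_set={len(result.training_set)} "
      f"reference_calls={result.reference_calls}")
print(f"MAD energy {mad_e:.2f} kcal/mol, MAD forces {mad_f:.2f} kcal/mol/Å")
```

Output:

```
converged=True training_set=10 reference_calls=10
MAD energy 0.55 kcal/mol, MAD forces 1.89 kcal/mol/Å
```

Ten labeled structures suffice here: the loop runs its full episode
schedule, every candidate frame scores above the calibrated similarity
threshold — the selector certifies that the initial snapshots already
cover the thermally accessible region — and the converged model tracks the
reference to a fraction of a kcal/mol on unseen thermal frames. On a
poorly covered system the same loop would instead keep selecting and
labeling frames; `reference_calls` counts the labeling budget a real
electronic-structure backend would have paid.

For reaction dynamics, `TwoBondReactivePotential` provides a model
cycloaddition (two forming bonds on coupled double wells); see
`mlal.reaction` for relaxed 2D scans, umbrella sampling along
ξ = (r₁+r₂)/2, and downhill/uphill ensembles classified by the 1.6 Å / 3.0 Å
product/reactant distances and the 60 fs concertedness time gap.

A `mlal` command-line tool wraps the main operations (`mlal al-train`,
`mlal md`, `mlal umbrella`, `mlal fes`, `mlal downhill`, `mlal uphill`,
`mlal rdf`, `mlal hbonds`, `mlal scan2d`); run configurations are YAML and
structures travel as extended XYZ.

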