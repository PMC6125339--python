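# b2bsample

Direct-sampling **bound-to-bound data collaboration** (B2BDC) for parametric
molecular-property models: given experimental observations with uncertainty
bounds and a model with adjustable parameters, find the parameter vectors
consistent with *all* the data at once, diagnose when no such vector exists,
and propagate what remains of the parameter freedom into prediction
intervals for unobserved quantities.

The package is aimed at method developers and UQ practitioners who want a
deterministic, auditable consistency diagnostic for semi-empirical-style
models — here a 27-parameter heat-of-formation model over the homologous
series of linear alkanes — rather than a Bayesian posterior.

## The method

Each quantity of interest (QOI) is a scalar model output `M_e(x)` (the heat
of formation Δ_f H°₂₉₈ of the alkane with `e` carbons, kcal/mol) compared
against experimental bounds `[L_e, U_e] = value_e ± uncertainty_e`.  Within
a prior region `H` the feasible set of one QOI is

    F_e = { x ∈ H : L_e ≤ M_e(x) ≤ U_e },

and a collection of observations indexed by `I` constrains the parameters
to the intersection `F_I = ∩_{e∈I} F_e`.  The model and data are
*consistent* when `F_{1:N}` is nonempty.  Predictions for a molecule `p`
are reported as the inner approximation

    [ min_{x∈F_I} M_p(x) ,  max_{x∈F_I} M_p(x) ]

evaluated over the sampled members of `F_I` — the true range can only be
wider.  Because accurate surrogates for this model class exist only on
domains that are a ~10¹⁰-fold shrink of the prior box (the package's
surrogate-fidelity sweep quantifies this), feasible sets are found by
*direct sampling*: a calibrated prior box, an optimization-seeded local
search, PCA rotation and extension of the found feasible cloud, and
large Latin-Hypercube batches evaluated through the model.

The shipped study system is a synthetic stand-in whose 27 named parameters
map through three *effective coefficients* (α, β, γ) to size-extensive
QOIs, `M_n = α + β(n−1) + γ(1/n − 1)`.  Everything downstream treats it as
a black box, but its linearity in (α, β, γ) makes ground truth decidable
by linear programming — so every sampled verdict can be audited against an
exact oracle — while nonlinear coefficient maps (including a sinusoid)
keep the feasible sets non-convex in parameter space, as in the real
application.

## Worked example

```python
from b2bsample import (SyntheticAlkaneModel, load_qoi_table,
                       coefficient_box, lp_feasibility_oracle)

table = load_qoi_table("default")     # methane..octane, value ± 95%-CI
model = SyntheticAlkaneModel()        # shipped synthetic study system
box = coefficient_box(model.cfg)      # achievable (alpha, beta, gamma)
for I in [range(1, 9), range(2, 9), range(3, 9)]:
    v = lp_feasibility_oracle(table, I, box)
    print(f"QOIs {min(I)}..{max(I)}: {'feasible' if v.feasible else 'infeasible'}")
```

prints

```
QOIs 1..8: infeasible
QOIs 2..8: infeasible
QOIs 3..8: feasible
```

i.e. no parameter vector can reconcile methane and ethane with the larger
alkanes at the reported uncertainties (the two shortest members are
energetically unlike the rest of the series), while propane through octane
admit a common feasible set.

The full pipeline runs from a YAML config (`seed` and `outdir` required;
every stage size has desk-scale defaults) or directly:

```python
from b2bsample import RunConfig, run_pipeline
from b2bsample.pipeline import summarize_run

run_pipeline(RunConfig(seed=1, outdir="runs/demo", local_n=4000,
                       rotated_n=20000, fidelity_n=1500, fidelity_folds=3,
                       classify_per_class=1500, classify_trees=100,
                       ga_budget=3000))
print(summarize_run("runs/demo"))
```

```
pipeline run in runs/demo (package version 0.1.0)
           calibrate: max_target_dev=0.0009215924014362997, n_parameters=27
            classify: mean_auc=0.6990011111111112, per_class=1500
         feasibility: full_verdict=no_evidence, longest=[3, 4, 5, 6, 7, 8], n_feasible_any=11000
            fidelity: k_star=0.01
      local_sampling: n_members=3997, n_samples=4000
          pca_region: extension=10.0, n_input_samples=3997
          prediction: n_members=820, r_squared=0.9999999998729654, slope=0.06758457391645932
           prior_box: k_report=0.4, volume_ratio=55511151231.25783
               probe: n_crossings=2, qoi=6, verdict=non_convex
    rotated_sampling: n_failed=0, n_samples=20000
         seed_search: feasible=True, objective=5.2645572832123246e-23
```

Reading the run: all 27 prior half-widths were calibrated to a 10 kcal/mol
single-parameter effect (worst deviation 9e-4); the pentane/hexane seed
optimization found a feasible point (objective ~0); of 20,000 rotated-LHS
samples 11,000 satisfied at least one bound, the longest consecutive
feasible run was propane..octane (820 joint members) and no sample
satisfied the whole series (`no_evidence` — sample-limited, but here the
LP oracle confirms true infeasibility); prediction-interval length grows
linearly in molecule size (slope 0.068 kcal/mol per carbon, R² ≈ 1); the
hexane feasible set is provably non-convex along a probed segment; and a
random-forest feasible/infeasible classifier reaches AUC ≈ 0.70, i.e. the
sampled feasible set has learnable structure.

The same stages are available as CLI subcommands
(`b2bsample run|calibrate|sample|feasibility|predict|fidelity|probe|classify|report -c config.yaml`).

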