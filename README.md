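# psmcure

Partitioned-survival cost-effectiveness modelling with mixture cure
extrapolation, built around the economic evaluation of first-line
atezolizumab + chemotherapy versus chemotherapy for extensive-stage
small-cell lung cancer (ES-SCLC) from a US payer perspective.

The package is aimed at health-economics and biostatistics practitioners
who need the full chain of that analysis as tested, reusable code:

1. **Pseudo-IPD reconstruction** — invert digitized Kaplan–Meier
   coordinates plus numbers-at-risk tables back into patient-level
   event/censoring times (the Guyot-style interval algorithm).
2. **Survival extrapolation** — right-censored maximum likelihood for the
   exponential, Weibull, Gompertz, log-logistic and log-normal families,
   AIC selection, additive general-population background mortality, a
   Schoenfeld proportional-hazards diagnostic, and the **mixture cure
   model**

   S<sub>pop</sub>(t) = S<sub>gen</sub>(t) · (p<sub>cured</sub> + (1 −
   p<sub>cured</sub>) · S<sub>uncured</sub>(t)),

   in which a cured fraction p<sub>cured</sub> is subject only to
   general-population mortality — the natural description of the late
   survival plateau seen under PD-L1 blockade.  The non-mixture
   (proportional-hazards) cure form S<sub>gen</sub>·exp(ln p<sub>cured</sub>·(1−S))
   is provided for evaluation.
3. **Three-state partitioned survival model** — per 21-day cycle,
   PF = min(S<sub>PFS</sub>, S<sub>OS</sub>), PP = S<sub>OS</sub> − PF,
   dead = 1 − S<sub>OS</sub> over a 2.5-year horizon; discounted costs
   (drugs by trial dosing incl. Calvert-formula carboplatin,
   administration, supportive care, second-line, adverse events, death)
   and QALYs/life-years, yielding ICUR = ΔC/ΔQALY and ICER = ΔC/ΔLYG.
4. **Sensitivity analysis** — one-way tornado tables, 1,000-draw
   probabilistic sensitivity analysis over the published input
   distributions (beta/gamma/normal by moment matching), net monetary
   benefit NMB(λ) = λ·ΔQALY − ΔC and cost-effectiveness acceptability
   curves.

Because no patient-level trial data are public, the package ships a
**calibrated synthetic trial generator**: a two-arm cohort (~403 patients)
whose Kaplan–Meier summaries reproduce the published trial statistics —
median OS 12.3 vs 10.3 months, 1-year OS 51.7% vs 38.2%, median PFS 5.2
vs 4.3 months, OS HR ≈ 0.70, PFS HR ≈ 0.77 — including a cured-fraction
plateau in the intervention arm.  Everything downstream is exercised
end-to-end on that generator.

## Worked example

`examples/` contains one narrative script per capability.  The headline
pipeline run (`python examples/04_cost_effectiveness.py`) simulates the
calibrated trial, reconstructs pseudo-IPD from digitized curves, fits the
survival models, and evaluates both extrapolation variants ("model 1" =
mixture cure for the intervention arm, "model 2" = standard Gompertz;
the control arm always uses the standard parametric fit):

```
base-case results (discounted, per patient):
                     model  delta_cost  delta_qaly  delta_lyg       icur       icer
       model1_mixture_cure   90858.401       0.117      0.184 776275.102 493286.229
model2_standard_parametric   90789.447       0.113      0.176 802046.988 515616.269

model1_mixture_cure:
  top tornado drivers: ['utilities.pp', 'utilities.pf']
  P(not cost-effective at $100k/QALY): 100.0%

scenario analysis (PF utility 0.840 -> 0.673):
                     model  icur_base  icur_scenario
       model1_mixture_cure   776275.0       879284.0
model2_standard_parametric   802047.0       912547.0
```

Read: adding the immunotherapy buys ≈0.12 QALYs for ≈$91,000, an ICUR of
roughly $780,000–800,000 per QALY — far beyond a US$100,000/QALY
willingness-to-pay, with a 100% probability of not being cost-effective
in the probabilistic analysis.  The cure-model variant credits the
intervention with slightly more tail survival, so its ICUR is the lower
of the two.  The PF/PP health-state utilities dominate the tornado, and
the lower-utility scenario pushes the ICUR higher still — the
qualitative conclusions are insensitive to every input varied.

A thin CLI wraps the same library:

```bash
psmcure simulate --seed 1 --out out/
psmcure fit --ipd out/ipd.csv --arm C --cure
psmcure report --seed 1 --draws 1000 --out report/
```

## Layout

- `src/psmcure/synthetic_trial.py` — calibrated generator, life table, ArmSpec
- `src/psmcure/km_reconstruction.py` — KM estimation, pseudo-IPD reconstruction
- `src/psmcure/survival_fitting.py` — parametric + cure MLE, AIC, PH diagnostic
- `src/psmcure/ps_model.py` — cycle grid, state occupancy, costs, QALYs
- `src/psmcure/economics.py` — ICUR/ICER, DSA, PSA, CEAC, scenarios
- `src/psmcure/pipeline.py`, `cli.py` — orchestration and command line
- `src/psmcure/data/econ_inputs.yaml` — the cost/utility/AE input ledger
- `docs/methods.md` — modelling assumptions and design choices
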