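# brixflow

Voxel-wise pharmacokinetic analysis of dynamic contrast-enhanced MRI
(DCE-MRI) for preclinical tumor treatment-response studies, together with
the caliper-based tumor-growth-delay endpoint and the group statistics that
tie imaging, growth and hypoxia readouts together. A seeded synthetic
xenograft-cohort generator makes the entire chain runnable and testable
without any imaging data.

The intended user is a preclinical imaging scientist monitoring
radiotherapy/chemotherapy response in subcutaneous xenografts: tumors are
imaged dynamically before and after treatment, fitted voxel-by-voxel with a
two-compartment model, and the fitted-parameter changes are compared across
treatment arms and correlated with hypoxic fractions and growth endpoints.

## The model

Signal is first normalized per voxel to relative signal intensity against
the pre-contrast baseline,

```
RSI(t) = (SI(t) - SI(0)) / SI(0),
```

with `SI(0)` the mean over the pre-contrast frames. Each voxel's
enhancement curve is then fitted with the Brix two-compartment model, in
which contrast agent exchanges between blood plasma and the extracellular
extravascular space (EES) at rate `k_ep` (min⁻¹) and is eliminated from
plasma at rate `k_el` (min⁻¹):

```
RSI(t) = A · k_ep / (k_el − k_ep) · (exp(−k_ep·t) − exp(−k_el·t)),
```

where the dimensionless amplitude `A` is related to the size of the EES.
Fitting is bounded nonlinear least squares (Trust Region Reflective with
analytic Jacobian, multi-start). Voxels are excluded for failed fits, low
r², or bound saturation, and a reliability check flags `k_ep` whenever the
enhancement upslope is too fast for the frame rate to sample — in that
regime ROI summaries report `A` and `k_el` only.

Growth response uses caliper volumes `V = (π/6)·length²·width`; the tumor
growth delay `TGD_V3` is the extra time, relative to controls, for tumors
to reach 3× their day-0 volume (reported as a lower bound when tumors never
get there), and growth curves are additionally compared through per-animal
orthogonal-polynomial trend scores. Group inference uses two-sided
Student's t-tests and Pearson correlations across arm means.

## Worked example

The numbered scripts under `analysis/` run a complete study on a simulated
five-arm cohort (untreated control, liposomal doxorubicin `PL-DXR`,
radiotherapy `RT`, RT under induced hypoxia, and the combination), 4 tumors
per arm, ~80-voxel ROIs, 5 % signal noise:

```
python analysis/01_simulate_cohort.py
python analysis/02_fit_kinetics.py
python analysis/03_growth_endpoints.py
python analysis/04_group_statistics.py
```

The final stage prints (abridged):

```
group means:
              group  delta_A_pct  delta_kel_pct  hypoxic_fraction_pct
            Control        -17.9           46.8                  21.8
             PL-DXR        -25.0           92.5                  23.0
PL-DXR + hypoxic RT          4.0           46.0                  16.2
         Hypoxic RT         20.2          -27.0                  13.0
                 RT         29.0          -27.0                  10.6

correlations across arm means:
                   x                y      r     p  n
hypoxic_fraction_pct      delta_A_pct -0.999 0.000  5
hypoxic_fraction_pct    delta_kel_pct  0.919 0.027  5
```

Reading this: the amplitude parameter `A` falls in the unirradiated arms
and rises in every irradiated arm (the fitted group means recover the
generator's configured effect multipliers), `k_el` falls only in the two
RT-only arms, and arms with larger `A` increases have smaller hypoxic
fractions — the negative coupling the cohort generator builds in.
`03_growth_endpoints.py` prints the growth delays, e.g. `RT: more than
17.3 d`, a lower bound because every RT tumor stays below 3× volume within
the observation window.

The same pipeline is available as a CLI (`brixflow simulate|fit|growth|
stats|report|run`) operating on NIfTI series, JSON timing sidecars and CSV
tables, and as a single call `brixflow.run_pipeline(config)`.

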