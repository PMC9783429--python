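# sacontrast

Statistical tests for **local adaptation** and **adaptive phenotypic
plasticity** from reciprocal common-environment experiments, built around
the sympatric–allopatric (SA) contrast.

## The problem

Populations sampled from different environments (for example, insect
populations collected from different host fruits) often perform best in
the environment they came from. Two very different mechanisms can produce
that pattern: genetic local adaptation, and environmentally induced
(plastic) phenotype shifts. The two can be separated by assaying each
population in every environment **twice** — once on field-derived
individuals (phase G0/G1) and again after two generations of common
laboratory rearing (phase G2/G3): a sympatric advantage that persists into
the common-environment phase is genetic; an advantage confined to the
field phase is plastic.

The statistical difficulty is that the sympatric signal is small and sits
on top of large nuisance variation: intrinsic quality differences among
populations, quality differences among test environments, and unit
(arena/vial) effects. `sacontrast` implements an ANOVA framework that
removes these nuisances and tests the sympatric contrast against the
remaining genotype × environment interaction.

## The model

For a transformed trait $y$ observed on population $i$ (of origin
environment $k$) in test environment $j$, phase $l$, unit $m$:

$$
y = \mathrm{pop}_i + \mathrm{env}_j + (\mathrm{env}\times\mathrm{orig})_{jk}
  + I_l\,[\Delta\mathrm{pop}_i + \Delta\mathrm{env}_j + \Delta(\mathrm{env}\times\mathrm{orig})_{jk}]
  + SA_\text{genetic}\,S_{jk} + I_l\,SA_\text{plastic}\,S_{jk}
  + \mathrm{unit}_m + \varepsilon
$$

where $S_{jk}=1$ iff test and origin environment match and $I_l=1$ in the
field phase. All factors use sum-to-zero contrasts; each SA term is a
single contrast carved out of the interaction space, entered (Type I)
before the interaction remainder. The tests are

$$
F_\text{genetic} = \frac{MS(SA_\text{genetic})}{MS(\text{interaction remainder})},\qquad
F_\text{plastic} = \frac{MS(SA_\text{plastic})}{MS(\Delta\text{interaction remainder})},
$$

each with $(1,\,(J-1)(K-1)-1)$ degrees of freedom — $(1, 3)$ for three
environments. The share of interaction variance captured by an SA term is

$$
\varphi = \frac{MS_{SA=0} - MS_{SA\neq 0}}{MS_{SA=0}},
$$

with $MS_{SA=0}$ the interaction mean square when the SA column is
omitted. A significant **positive** genetic term supports local
adaptation; a significant positive plastic term supports adaptive
plasticity; $\varphi$ may be negative because the two mean squares divide
by different degrees of freedom.

Three traits are supported with the field's conventional transforms:
oviposition preference and fecundity as log egg counts (preference with a
fixed arena block), and offspring performance as arcsine-square-root
egg-to-adult survival with a log egg-density covariate (survival capped at
one for miscounted vials).

## Worked example

Generate a synthetic experiment in the study layout (3 fruits, 9/3/13
populations per origin, 8 arenas per population and phase) with a genuine
genetic sympatric bonus of 0.4 on the log scale and no plasticity, and fit
the dual-generation model:

```python
from sacontrast import (SimulationConfig, generate_dataset, analysis_model,
                        transform_response, sa_test_dual)

cfg = SimulationConfig(family="poisson", sa_genetic_true=0.4, seed=12)
spec = analysis_model(cfg)
table = transform_response(generate_dataset(cfg), spec.trait_spec)
res = sa_test_dual(table, spec)
g, p = res.genetic, res.plastic
print(f"genetic: estimate={g.sa.estimate:+.3f} (SE {g.sa.se:.3f}), "
      f"F(1,{g.df_den})={g.F:.2f}, p={g.p:.4f}, phi={g.phi:.3f}")
print(f"plastic: estimate={p.sa.estimate:+.3f} (SE {p.sa.se:.3f}), "
      f"F(1,{p.df_den})={p.F:.2f}, p={p.p:.4f}, phi={p.phi:.3f}")
```

prints

```
genetic: estimate=+0.386 (SE 0.099), F(1,3)=29.90, p=0.0120, phi=0.878
plastic: estimate=-0.003 (SE 0.059), F(1,3)=0.00, p=0.9677, phi=-0.332
```

The genetic SA estimate recovers the injected 0.4 (populations lay ~47%
more eggs on their own fruit), the F test flags it as significant, and
φ ≈ 0.88 says the sympatric contrast explains most of the
test × origin interaction; the plastic term is correctly null.
`res.anova.to_frame()` gives the full sequential ANOVA table.

The same analyses are available from the shell:

```sh
sacontrast generate --seed 12 --family poisson --sa-genetic 0.4 --out data.csv
sacontrast fit-dual --input data.csv --trait preference --out-dir results/
sacontrast fpr --reps 1000 --seed 1 --family normal --out-dir results/
sacontrast power --reps 500 --seed 1 --out-dir results/
```

## Layout

- `src/sacontrast/datamodel.py` — long-format observation tables, validation, transforms
- `src/sacontrast/design.py` — sum-to-zero design matrices with centered SA contrasts
- `src/sacontrast/inference.py` — sequential ANOVA, F tests, φ, estimates and SEs
- `src/sacontrast/descriptives.py` — effect means, original-vs-alternative plots data, weighted correlations
- `src/sacontrast/simulate.py` — synthetic experiments, false-positive-rate and power studies
- `src/sacontrast/cli.py` — command-line interface
- `docs/methods.md` — modeling and simulation details
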