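# cocultrsm

Response-surface methodology (RSM) toolkit for optimizing microbial
coculture bioprocesses, built around the workflow used to tune a two-strain
*E. coli* system producing multi-methyl-branched esters (MBE): one strain
supplies branched-chain alcohols, the other esterifies them, and the
productivity of the pair depends jointly on the inoculation ratio, the
induction time and the inducer (IPTG) concentration.

The package covers the full statistical workflow:

- **Central composite designs** (`doe`): replicated, blocked, 5-level CCDs
  in coded units, with linear natural-unit coding and lossless CSV
  serialization. The reference layout — 3 factors, duplicated factorial and
  star points, six center replicates, two day-blocks — needs 34 runs where a
  5-level full factorial would need 5³ = 125.
- **Hierarchical polynomial models** (`models`): least-squares fits of
  monomial bases up to cubic, forward-selection and backward-elimination
  stepwise regression with divisor-closure hierarchy correction, ANOVA with
  pure-error/lack-of-fit decomposition, and PRESS-based predicted R².
- **Optimization** (`optimize`): seeded multistart maximization over the
  coded design region (cube or sphere), and Derringer–Suich desirability
  for multiresponse optimization:

  d_i = 0 for Ŷ_i ≤ Y_i^min, ((Ŷ_i − Y_i^min)/(Y_i^max − Y_i^min))^r in
  between, 1 for Ŷ_i ≥ Y_i^max, combined as
  D = [∏ d_i^{w_i}]^{1/Σw_i} (so D = √(d₁·d₂) for two equally weighted
  responses).

- **Assay conversions** (`quantify`): TLC densitometry → mg/L through a
  cetyl-palmitate calibration line, GC internal-standard alcohol
  quantification, and fluorescent-colony strain-ratio percentages.
- **Synthetic data** (`synthetic`): the reduced cubic ester-production
  surface

  Y₁ = 23.91 − 2.5A − 1.32B + 1.19C − 2.33AB − 0.078AC + 0.68BC − 5.62A²
  − 4.42B² − 5.48C² − 3.3ABC − 1.6A²B + 1.45C³

  as ground truth (A.U., coded factors), a documented concave OD₆₀₀
  surrogate, Gaussian replicate noise and block offsets, plus a minimal
  two-strain lag/exponential growth simulator reproducing the fast-strain
  takeover seen in fed-batch cocultures.
- **Pipeline** (`pipeline`, `cocultrsm` CLI): design → simulate/ingest →
  fit → validate → optimize → report, driven by a validated JSON config,
  writing only plain-text artifacts.

## Worked example

```python
import cocultrsm as crs

model = crs.maximize_response(crs.mbe_truth_model(), n_restarts=50, seed=1,
                              factors=crs.default_factors())
```

Running `python examples/03_single_response_optimum.py` prints:

```
predicted maximum: 24.3 A.U.
coded optimum:     [-0.208 -0.086  0.104]
natural units:     A = 46.9 %RQ5.1, B = 2.41 h, C = 0.24 mM IPTG
center prediction: 23.91 A.U.
```

The predicted ester-production maximum (24.3 arbitrary densitometric
units) sits at an interior point close to the coded origin, i.e. the
design's center conditions are already near-optimal; the center prediction
is the model intercept. The other scripts in `examples/` walk through
design generation and simulation, model fitting and ANOVA validation
(lack-of-fit p-values against pure error), desirability-based joint
optimization of production and cell density, and the coculture takeover
dynamics with the assay conversions.

The same workflow is available from the shell:

```bash
cocultrsm --seed 5 --outdir demo demo     # fixture bundle + full pipeline
cocultrsm design -o design.csv            # individual stages: design,
cocultrsm simulate design.csv -o r.csv    # simulate, fit, anova, optimize,
cocultrsm fit design.csv r.csv -o m.json  # desirability, report
```

## Layout

- `src/cocultrsm/` — library modules (`doe`, `models`, `optimize`,
  `quantify`, `synthetic`, `pipeline`, `cli`)
- `examples/` — narrative scripts, one per capability
- `tests/` — pytest suite (unit, property-based, end-to-end)
- `docs/methods.md` — modelling and design notes
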