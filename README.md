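# mcmgene

Stochastic simulation of a gene regulated by competing transcription
factors, using discrete-time Markov-chain promoter models.

## The problem

A doxycycline (dox)-inducible reporter can be driven by an activator
alone, silenced by a repressor alone, or controlled by both factors
competing for the same operator.  Flow-cytometry dose–response curves of
the single-factor systems have Hill coefficients of about 1.6
(activator) and 1.8 (repressor), while the combined system is observed
at about 3.2 — steeper than either, and not obviously the customary sum
(3.4) or product (2.88).  The combined system also switches from a
graded to an all-or-none (bimodal) single-cell response at intermediate
dox.

`mcmgene` is for modellers who want to reproduce this behaviour without
detailed molecular kinetics.  The promoter is a Markov chain over up to
three states — repressor-bound, unbound, activator-bound — whose
per-cycle switching probabilities are Hill functions of [dox],

    p(dox) = dox^H / (K^H + dox^H),

estimated from the single-factor dose–response curves only.  The two
factors cannot be bound at once ("binding contingency",
P_A1 + P_R1 < 1).  Expression follows a noisy birth–death update

    X' = max(0, X + (α·f + γ·10^z − γ·δ·X)·Δt),

with promoter activity f ∈ {0, 1, 10} by state, δ ~ N(1, 0.5²),
z ~ N(0, 0.5²), α = 2.0, γ = 0.2, Δt = 1.  Populations of 10,000 cells
run for 200 cycles give steady-state expression distributions; their
normalized means over a 34-dose grid are refitted with a Hill function
to predict the combined system's cooperativity.  See `docs/methods.md`
for the model, the estimation strategy, and what the data do and do not
determine.

## Worked example

```python
import mcmgene as m

report, artifacts = m.run_prediction(seed=1)
for name, fit in [("activator-only", report.fit_act),
                  ("repressor-only", report.fit_rep),
                  ("combined (A+R)", report.fit_combined)]:
    print(f"{name}: H = {fit.params.H:.3f} +/- {fit.se_H:.3f}, "
          f"K = {fit.params.K:.3f} ug/ml")
print(f"calculated: add = {report.calc_add:.2f}, "
      f"multiply = {report.calc_mult:.2f}")
```

prints (about half a minute at full scale):

```
activator-only: H = 1.554 +/- 0.020, K = 0.575 ug/ml
repressor-only: H = 1.815 +/- 0.012, K = 0.595 ug/ml
combined (A+R): H = 2.135 +/- 0.033, K = 0.853 ug/ml
calculated: add = 3.40, multiply = 2.88
```

Reading: the estimated 2-state chains retain the observed single-factor
Hill coefficients (1.6 and 1.8), and the competing 3-state chain —
simulated with the same kind of switching probabilities under binding
contingency — yields a visibly steeper combined response than either
factor alone, the package's central qualitative prediction.  The fitted
half-maximal dose K is in µg/ml; standard errors come from the curvature
of the fit.  How steep the combined curve comes out depends on parts of
the parameter space the single-factor data genuinely do not constrain
(see the limitations section of `docs/methods.md`).

The same pipeline is available from the shell:

```
mcmgene predict --seed 1 --out results/
mcmgene report --prediction results/prediction_report.csv
```

along with `estimate`, `simulate` and `dose-response` subcommands for
the individual stages; every run writes CSVs (column schemas in
`mcmgene.config.OUTPUT_SCHEMAS`) plus a checksummed `run_record.json`.

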