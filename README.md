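# chf-telehealth

A Markov cohort model of congestive heart failure (CHF) progression with
an economic layer for evaluating home telehealth programs, written for
health-economics analysts and telehealth program designers who want to
know **when, and for whom, remote monitoring becomes cost saving**.

## The model

CHF patients are tracked through six states in monthly cycles: five
living states defined by the count of prior CHF hospital admissions
(H0, H1, H2, H3, H4+) plus an absorbing death state. Within a cycle a
patient in state *H* is hospitalized with probability *p*<sub>hosp</sub>(*H*)
(0.008 → 0.180 across states in the NYHA II/III stratum); death then
occurs with probability 0.100 given an admission and 0.007 otherwise.
Survivors of an admission advance one state; there is no recovery.

A telehealth program is described by five parameters: the detection
sensitivity SEN and specificity SPE of home exacerbation monitoring, and
proportional reductions in mortality (24% base case), hospitalization
(28%) and hospital length of stay (25%). Detection gates the clinical
effect — an undetected exacerbation receives no early intervention — so
the hazards of the telehealth arm are

> *p*′ = *p* · (1 − SEN · reduction)

Costs (2013 USD, payer perspective) accrue per cycle and are discounted
at 3%/year: $12,000 per admission (length-of-stay-reduced in the
telehealth arm), $1,700/year CHF outpatient and $10,000/year non-CHF
care for every survivor, plus — telehealth arm only — a $220/month
monitoring (TEST) bundle and a $187 early-intervention (TREAT) episode
for every positive test, true positives at rate SEN among exacerbating
patients and false positives at rate 1 − SPE among the rest.

Outcomes per initial patient: discounted total cost, discounted life
years, and admission counts; the incremental value is telehealth minus
usual care (negative cost = saving). A vectorized microsimulation draws
individual trajectories under the identical event logic and serves as a
Monte-Carlo oracle for the deterministic expectations.

## Worked example

```python
import chf_telehealth as ct

bundle = ct.builtin_defaults()                # published parameterization
tp = bundle.transition("NYHA II or III")
base = bundle.scenarios["base"]
c2 = bundle.cohorts["C2"]                     # 30/30/40% with 1/2/3 prior admissions

r = ct.compare_arms(c2, base, bundle.costs, tp, 12, bundle.options)
print(f"usual care: ${r.usual.cost:,.0f}, {r.usual.life_years:.2f} LY, "
      f"{r.usual.admissions:.2f} admissions")
print(f"telehealth: {r.saving:+,.0f} saving, {r.incremental.life_years:+.2f} LY, "
      f"{r.incremental.admissions:+.2f} admissions")
print("break-even fee:",
      round(ct.break_even_fee(c2, base, bundle.costs, tp, 12, bundle.options)))
```

prints

```
usual care: $25,071, 0.88 LY, 1.23 admissions
telehealth: +2,818 saving, +0.03 LY, -0.27 admissions
break-even fee: 474
```

i.e. for an intermediate-risk cohort the program saves about $2.8k per
patient in its first year while adding 0.03 discounted life years and
averting 0.27 admissions, and it remains cost saving up to a monthly
monitoring fee of about $474. The same pipeline run on the low-risk
cohort C1 shows a cost *increase* (≈ $2,457/patient-year): risk
stratification decides whether telehealth pays for itself.

The same analyses are available from the shell:

```sh
chf-telehealth basecase --out results/basecase
chf-telehealth sensitivity --mode breakeven --out results/breakeven
chf-telehealth validate
chf-telehealth microsim --cohort C2 --n 200000 --seed 1 --out results/microsim
```

Parameters can be overridden with `--config`; see
`examples/config.yaml` for the full schema. Every output directory gets
a `manifest.json` with a hash of the resolved parameters, so identical
inputs are verifiably identical runs.

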