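# hipcea

A Markov cohort cost-effectiveness model comparing **hemiarthroplasty (HA)**
with **internal fixation (IF)** for nondisplaced femoral neck fractures in
elderly patients, from a payer perspective in 2020 US dollars. It is aimed at
health economists and orthopaedic researchers who want a transparent,
scriptable, fully tested implementation of this decision problem — including
deterministic and probabilistic sensitivity analysis — rather than a
point-and-click decision tree.

## The model

A theoretical cohort of 80-year-old patients receives either IF or HA.
Five states are tracked over a 5-year horizon with one-year cycles:

- `PRIMARY_IF` / `PRIMARY_HA` — alive with the initial implant;
- `CONVERTED_HA` — alive with a hemiarthroplasty received as salvage of a
  failed fixation (it can fail again, at the HA failure rate);
- `CONVERTED_THA` — alive with a salvage total hip arthroplasty (assumed not
  to fail within the horizon);
- `DEAD` — absorbing.

Each cycle applies age-specific background mortality from a life table, then
implant failure (an IF failure is salvaged with HA or THA with equal
probability; any HA failure is salvaged with THA), then the perioperative
mortality of that cycle's conversion surgery. Survivors accrue their health
state utility *u* for the year; new converts also incur a one-off disutility
of −0.15 and the conversion cost. Costs *C* and QALYs *E* are discounted at
3% per year, and the strategies are compared through

ICER = ΔC / ΔE  (HA − IF),

judged against a willingness-to-pay (WTP) threshold of $11,083/QALY (the
2020 Chinese per-capita GDP). A strategy is *dominant* if it is both cheaper
and more effective; otherwise it is cost-effective when the net monetary
benefit WTP·ΔE − ΔC is positive. Parameter uncertainty is propagated with
method-of-moments Beta (probabilities, utilities) and Gamma (costs)
distributions, each with SD = 10% of the mean.

## Worked example

```python
from hipcea import ModelParams, default_lifetable, run_cohort, compute_icer

params = ModelParams()            # base case
table = default_lifetable()       # bundled Chinese 2020 census fixture
r_if = run_cohort("IF", params, table)
r_ha = run_cohort("HA", params, table)
inc = compute_icer(r_if, r_ha, wtp=params.wtp)
print(r_if.discounted_qaly, r_ha.discounted_qaly, inc.icer)
```

or, from the shell:

```sh
cea run --out out/base
```

which prints

```json
{
  "delta_cost": 1922.799330159949,
  "delta_qaly": 0.15779119375985573,
  "icer": 12185.72015550044,
  "classification": "not_cost_effective"
}
```

With the bundled life table, IF yields 2.41 discounted QALYs at $11,781 and
HA 2.57 QALYs at $13,703: HA buys 0.158 extra QALYs for $1,923, i.e.
$12,186 per QALY — just above the $11,083 threshold. The verdict is highly
sensitive to the assumed background mortality (see `docs/methods.md`): with
lower old-age mortality, the extra QALYs grow and HA becomes cost-effective.
The two procedure prices are the most influential single inputs
(`cea tornado`), and `cea thresholds` reports, for example, that HA becomes
cost-effective below an HA price of about $12,275 and dominant below about
$10,526.

Other subcommands: `cea twoway` (price–price cost-effectiveness region),
`cea psa --n 10000 --seed 1` (Monte Carlo probabilistic sensitivity
analysis with cost-effectiveness acceptability curves). All outputs are
plain CSV/JSON plus a `manifest.json` that makes any run exactly
reproducible.

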