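# osteosim

A mechanistic simulator of bone remodeling and osteoporosis
pharmacotherapy for postmenopausal women, aimed at modelers and
quantitative pharmacologists who want to explore, calibrate and rank
drug dosing regimens — including sequential and parallel combinations —
before (or instead of) testing them in a trial.

## The model in brief

A single *representative bone remodeling unit* carries eight dynamic
components: pre-osteoclasts, osteoclasts, pre-osteoblasts, osteoblasts,
osteocytes, sclerostin, bone density ρ and bone mineral content *m*;
bone mineral density is BMD = ρ·*m*.  Precursor pools form at constant
rates and feed the mature pools through regulated differentiation;
osteocytes secrete sclerostin; bone density gains and losses are
proportional to osteoblast and osteoclast densities.  Regulation acts
through normalized Hill functions of estrogen (an age-dependent logistic
input encoding menopause), sclerostin, and a "resorption signal"
proportional to the instantaneous resorption rate, so that the
premenopausal drug-free state is an exact all-ones fixed point.

Five drugs in four classes couple into this core through linear
compartment pharmacokinetics and Emax/Hill pharmacodynamics:

* **denosumab** (RANKL antibody) — blocks osteoclastogenesis; its
  cessation releases an accumulated precursor pool (rebound),
* **romosozumab / blosozumab** (sclerostin antibodies) — reduce free
  sclerostin, disinhibiting formation,
* **alendronate** (bisphosphonate) — bone-bound depot that raises
  osteoclast apoptosis and lowers resorption efficiency,
* **teriparatide** (PTH analog, anabolic regimes) — boosts osteoblast
  recruitment.

Clinical observables are derived per trajectory: relative total-hip BMD
and baseline-normalized changes of the turnover markers CTX (resorption)
and P1NP/BSAP (formation).  A calibration harness fits the 31 free
parameters to *hybrid aging/treatment datasets* (treatment series
rescaled onto a population BMD-vs-age curve), and a regimen-analysis
module scores and ranks alternative medication sequences.  See
`docs/methods.md` for equations, parameter rationale and limitations.

## Worked example: ranking drug sequences

The clinically studied scheme alendronate → romosozumab → denosumab
(70 mg weekly, 140 mg monthly, 60 mg per 6 months; one year each,
starting at age 67) is one of six possible orderings of the same three
drugs at identical total dose.  Rank them all:

```bash
osteosim rank-sequences --drugs A,R,D --start-age 67 --out sequences.csv
```

```
sequence  max_bmd_gain  residual_bmd_10y  rank_by_max_gain  rank_by_residual
     ADR      1.095686          1.048884                 4                 6
     ARD      1.105840          1.049797                 1                 5
     DAR      1.098070          1.065660                 3                 3
     DRA      1.092403          1.076095                 5                 1
     RAD      1.099787          1.055840                 2                 4
     RDA      1.091697          1.075786                 6                 2
```

`max_bmd_gain` is the highest BMD reached during treatment relative to
BMD at treatment start (ARD peaks at +10.6 %); `residual_bmd_10y` is the
BMD ten years after treatment end on the same scale.  The two rankings
disagree: ARD and RAD win short-term but end denosumab last and pay for
it with a strong post-cessation resorption rebound, while DRA and RDA
finish on alendronate, whose skeletal depot damps the rebound and
preserves the most bone (+7.6 %) a decade later.  Peak BMD gain is a poor
proxy for lasting benefit.

The same machinery is available from Python:

```python
from osteosim import reference_parameters, run_sequence_experiment
table = run_sequence_experiment(reference_parameters())
```

Other entry points: `osteosim simulate` (life-course trajectory to CSV),
`osteosim calibrate` (fit free parameters to a dataset directory),
`osteosim make-fixtures` (generate synthetic study datasets).

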