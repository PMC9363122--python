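# Methods

## Model

`osteosim` describes bone turnover through a single *representative bone
remodeling unit* (BRU) with eight dynamic components: pre-osteoclasts
$u$, osteoclasts $c$, pre-osteoblasts $v$, osteoblasts $b$, osteocytes
$y$, sclerostin $s$, bone density $\rho$ and bone mineral content (BMC)
$m$.  Bone mineral density is the product $\mathrm{BMD} = \rho\, m$.
Time is subject age in years; all rates are per year.

Cell pools and sclerostin are nondimensionalized so the premenopausal,
drug-free homeostatic state is exactly $1$ in every component.  Only
relative BMD and baseline-normalized turnover-marker changes are observable
in population-average clinical data, so absolute densities are
unidentifiable and nothing is lost by this scaling.  The fixed point pins
the precursor source rates, the mature-pool apoptosis rates and the
sclerostin secretion rate (e.g. $\beta_u = d_c + \delta_u$); these are
derived quantities, not free parameters.

With normalized Hill multipliers
$\phi^\pm(x; K, n) = H^\pm(x)/H^\pm(1)$, where
$H^+(x) = x^n/(K^n + x^n)$ and $H^- = 1 - H^+$, the dynamics are

$$
\begin{aligned}
\dot u &= \beta_u - d_c\,\phi^+(s_e; K_{sc})\,e_{\mathrm{diff}}\, u - \delta_u u\\
\dot c &= d_c\,\phi^+(s_e; K_{sc})\,e_{\mathrm{diff}}\, u
          - \delta_c\,\phi^+(E; K_{ce})\,e_{\mathrm{apo}}\, c\\
\dot v &= \beta_v - d_b\,\phi_b\, v - \delta_v v, \qquad
\phi_b = \phi^-(s_e; K_{bs})\,\phi^+(R; K_{bR})\,e_{\mathrm{ob}}\\
\dot b &= d_b\,\phi_b\, v - \delta_b b\\
\dot y &= \delta_y (b - y)\\
\dot s &= \sigma_s\,\phi^-(E; K_{se})\, y - \delta_s s\\
\dot \rho &= a\,b\,\phi^-(s_e; K_{bs})
             - a\,c\,e_{\mathrm{res}}\,g(\rho)\\
\dot m &= \lambda\,(m^\ast(\text{drugs}) - m)
\end{aligned}
$$

where $E$ is the relative estrogen level, $s_e = s\cdot e_{\mathrm{scl}}$
the free sclerostin after antibody binding, $R$ the resorption signal and
$e_\bullet$ the drug-effect multipliers (all $1$ without drugs).  The
couplings implement: sclerostin promotes osteoclastogenesis and inhibits
both osteoblast recruitment and osteoblastic bone formation; estrogen
promotes osteoclast apoptosis and represses sclerostin secretion; the
resorption signal couples resorption to subsequent formation.  The
RANK–RANKL–OPG axis is represented implicitly through these couplings
rather than as explicit molecular species.

The **resorption signal** is treated as quasi-static (fast equilibration
of matrix-released factors): $R$ is algebraically proportional to the
instantaneous resorption rate and normalized to $1$ at homeostasis, i.e.
$R = c\, e_{\mathrm{res}}\, g(\rho)$.

The factor $g(\rho) = \tfrac{\rho}{\rho + K_\rho}(1 + K_\rho)$ with
$K_\rho = 0.01$ smoothly switches resorption off as $\rho \to 0$.  It
equals $1$ at the reference state and is numerically irrelevant in the
physiological range; it exists so that no state component can be driven
negative (every pool's outflow vanishes with the pool).

**BMC** relaxes at rate $\lambda$ toward a target $m^\ast$ that is $1$
without drugs and is shifted upward by antiresorptives (denosumab,
alendronate), standing in for promotion of secondary mineralization.

**Estrogen** is an exogenous input, not a state: a logistic decline from
the premenopausal plateau ($1$) to a floor of $0.1$, centered at the
population-average menopause age of 51 with a transition width of 2
years.  These four numbers are fixed physiology, not calibration targets.

**Bone turnover markers** map monotonically from the model's fluxes:
CTX from the resorption rate $a\,c\,e_{\mathrm{res}}\,g(\rho)$, P1NP and
BSAP from the formation rate $a\,b\,\phi^-(s_e)$, each as
$(x/x_{\mathrm{baseline}})^{q} - 1$ with a per-marker exponent $q$
(defaults $1$, $1$, $0.7$; the sub-unit BSAP exponent reflects that
enzyme marker's flatter dynamic range).  This is the minimal monotone
("elementary") map consistent with baseline-normalized reporting; the
exponents are free parameters so calibration can reshape it.

## Drug modules

Each dose is an instantaneous bolus into a depot compartment
(subcutaneous for the antibodies and teriparatide; oral with
bioavailability 0.006 for alendronate), followed by linear first-order
absorption and elimination.  Alendronate additionally exchanges with a
bone-bound compartment (uptake 100/yr from the central compartment,
release 0.7/yr), which is the site of its action.  Pharmacodynamic
effects are Emax/Hill functions of the relevant compartment amount, all
neutral at zero drug, combined multiplicatively when several drugs hit
the same target:

| drug | class | PD target(s) |
|---|---|---|
| denosumab | RANKL antibody | pre-osteoclast→osteoclast differentiation ↓; BMC target ↑ |
| romosozumab, blosozumab | sclerostin antibody | free sclerostin seen by regulation ↓ |
| alendronate | bisphosphonate | osteoclast apoptosis ↑, resorption efficiency ↓; BMC target ↑ |
| teriparatide | PTH analog | osteoblast recruitment ↑ (anabolic regimes only) |

Antibody binding of sclerostin is modeled algebraically (binding is fast
relative to turnover): regulation sees $s_e = s\cdot e_{\mathrm{scl}}$
rather than an extra clearance term in the sclerostin ODE.  Teriparatide's
catabolic continuous-administration regime is deliberately out of scope;
its elimination constant (1000/yr) is an effect-compartment smoothing of
the much faster serum kinetics, chosen so that daily dosing produces the
sustained anabolic drive relevant on the model's time scales.

Denosumab's PK/PD pair (elimination 9.7/yr, i.e. the clinical ~26-day
terminal half-life, with a low EC50 of 0.5 mg) reproduces the hallmark
clinical profile: near-complete CTX suppression after each 60 mg dose,
partial recovery at the end of the 6-month interval, and — because the
blocked differentiation lets the precursor pool accumulate severalfold —
a post-cessation surge of osteoclasts with transient above-baseline
resorption (the rebound), followed by loss of much of the accrued BMD.

## Reference parameter set

The reference configuration (in `reference_parameters()`) plays the role
of a calibrated parameter table.  Its values were fixed once against
physiological anchors, in this order of priority:

* homeostatic skeletal turnover of 6 %/yr (the resorption flux at the
  reference state), consistent with predominantly cortical skeletal mass;
* cell-kinetic time scales: osteoclast lifespan ~2 weeks, pre-osteoclast
  ~6 weeks, osteoblast/pre-osteoblast ~3 months, osteocyte ~10 years,
  sclerostin ~1 week, mineralization relaxation ~1.2 years;
* untreated aging: total-hip BMD declining to ~0.76 of its age-25 value
  by age 85 (~0.65 %/yr postmenopausal loss), with a modest
  postmenopausal elevation of resorption over formation;
* characteristic magnitudes of drug responses reported in the pivotal
  trials of each drug class: denosumab 60 mg Q6M ≈ +2.5 %/yr hip BMD,
  CTX −90 % peak / −30 % trough, P1NP ≈ −40 %; alendronate 70 mg weekly
  ≈ +4–5 % hip BMD over 3 years with CTX ≈ −50 % and persistent residual
  suppression after discontinuation; romosozumab 210 mg monthly ≈ +7 %
  hip BMD in one year with P1NP ≈ +100 % early and CTX mildly negative;
  teriparatide 20 µg daily ≈ +2 %/yr hip BMD with strongly positive
  P1NP.

Exactly 31 entries carry the free flag (cell rates, regulatory
thresholds, marker exponents, drug PD constants and the bisphosphonate
bone-exchange rates); PK absorption/elimination constants and the
estrogen curve are fixed at literature-anchored values.  With this set
the emergent life-course-average turnover (mean resorption flux over
bone density, ages 25–90) is ≈ 6.8 %/yr — an output of the model, not an
input.

## Hybrid datasets and calibration

Hybrid aging/treatment datasets follow the merging convention: decadal
aging bins are reduced to bin-center anchors rescaled to the earliest
bin (an open-ended "80 and older" bin is centered as if it had the
preceding bin's width); the treatment series is rescaled so its baseline
equals the *linearly interpolated* anchor value at the treatment start
age (study mean baseline age rounded to full years); BTM series become
fractional changes from the baseline visit.

The objective simulates each dataset's regimen from the premenopausal
steady state at age 25, plus one untreated life course per aging grid
(the aging anchors describe untreated population aging and must not be
evaluated on a treated trajectory).  Residuals are unweighted for BMD
and down-weighted by 0.2 for BTM points — BMD is the primary target and
is measured far more precisely than the noisy marker assays; the weight
is exposed in `CalibrationConfig`.  The optimizer is SciPy's bounded
trust-region least squares with Jacobian-based variable scaling (the
free parameters span five orders of magnitude) and a seeded
Latin-hypercube multi-start (default 32 starts, seed 42).  Near-zero BTM
observations (|change| < 0.05) are excluded from MAPE reporting, whose
percentage errors would be dominated by the small denominators; they
still enter the least-squares objective.

## Synthetic data generator

`osteosim.fixtures` emulates the *structure* of published study-average
series: an aging table of decadal bin means (ages 20–80+), and treatment
tables of total-hip BMD at clinic visits plus CTX/P1NP baseline-change
series, with independent additive Gaussian noise per visit (sd 0.004 on
relative BMD, 0.05 on BTM fractional change — typical standard errors of
study-population means).  Noise is independent across visits because the
series are population averages; within-subject autocorrelation is not
modeled.  The default calibration collection holds four monotherapy
studies (denosumab, alendronate, romosozumab, blosozumab); the held-out
validation collection holds combination schemes (the
alendronate→romosozumab→denosumab sequence, and parallel
teriparatide+denosumab followed by denosumab).  Teriparatide appears
only in the validation collection: its daily bolus schedule costs
hundreds of integration segments per simulation, which matters inside an
iterated objective but not for a single validation run.

Because the generator uses the model itself, these datasets carry none
of a real trial's structural misfit, digitization error, cohort
heterogeneity or secular drift.  Goodness-of-fit numbers on them
demonstrate pipeline correctness, identifiability and numerical health —
not clinical validity of the model.

One convention matters for exactness: a treatment start age that falls
*between* aging bin centers makes the hybrid baseline anchor a linear
interpolation of a (slightly curved) model trajectory, so even noise-free
data differ from model output by ~1e-4.  The parameter-recovery harness
therefore starts its synthetic study at a bin-center age (65), where the
anchor is exact and the generating parameters are the exact optimum;
recovery of five perturbed parameters then succeeds to ~1e-5 relative.

## Sequence experiment

`osteosim.regimens` permutes one-year monotherapy blocks — alendronate
70 mg weekly, romosozumab 140 mg monthly, denosumab 60 mg per 6 months —
back-to-back from age 67, so all six sequences (ARD, ADR, DAR, DRA, RAD,
RDA) administer identical totals of every drug.  Each sequence is scored
by (i) the maximum BMD during treatment and (ii) the BMD ten years after
treatment end, both relative to BMD at treatment start.  Ranks are
descending, with ties broken by the other criterion and then by label.
With the reference parameters the two rankings disagree: sequences
ending in denosumab (ARD, RAD) achieve the largest peak gains but suffer
the strongest cessation rebound, while sequences ending in alendronate
(DRA, RDA) retain the most bone at ten years because the bone-bound
bisphosphonate keeps osteoclast apoptosis elevated through the rebound
window.

## Numerics

* Integrator: LSODA (stiff-capable, adaptive), rtol 1e-8 / atol 1e-10.
  Doses are impulses, so integration is segmented at dose times and the
  depot jumps are applied between segments; output is sampled from the
  dense solution on a ~weekly grid augmented with any exact evaluation
  ages (clinic visits, bin centers), so compared values are never
  two-stage interpolations.
* The steady-state initializer solves the six-component cell/sclerostin
  fixed point by root finding (residual < 1e-10/yr); at the premenopausal
  reference it returns the exact all-ones state.  Away from estrogen = 1,
  bone density has no finite steady state (it drifts at the constant rate
  set by the cell imbalance) and is held at its supplied value.
* Trajectory states are clipped at zero on output; the floor factor
  $g(\rho)$ and the proportional-outflow structure keep the dynamics
  nonnegative up to solver tolerance.
* Determinism: no hidden randomness anywhere; fixture noise and
  multi-start sampling use explicit `numpy` generators seeded from the
  caller.

## Problem sizes

Default spans and grids were chosen so that a full life-course
simulation costs well under a second and the complete pipeline (six
synthetic studies, six sequence simulations, oracle comparisons and a
five-parameter recovery fit) runs in a few minutes on one CPU: life
courses are simulated over ages 25–90 on a 0.02-year output grid, the
recovery fit uses a single two-year denosumab study, and the fixed-step
RK4 oracle runs a three-year window at step 1e-4 years.

## Known limitations

* No spatial structure: one representative BRU, no cortical/trabecular
  split, no BRU migration or bone geometry.
* The RANK–RANKL–OPG system, TGFβ-family factors and calcium/PTH/vitamin-D
  homeostasis are implicit in the coupling functions, not mechanistic.
* Teriparatide's serum CTX rise under clinical dosing is underrepresented
  (the model's only route from anabolic drive to resorption is the slow
  osteocyte–sclerostin loop).
* Postmenopausal BTM elevation is milder than typical clinical
  observations; aging enters calibration only through relative BMD.
* Population-average description only: no between-subject variability,
  immunogenicity, renal function or adherence effects.
* Drug interactions are purely multiplicative on shared targets; no
  mechanistic synergy/antagonism beyond state-mediated effects.
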