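# Methods

## The virtual patient

The patient is the Hovorka nonlinear compartmental model of glucose–insulin
dynamics in type 1 diabetes, with the published nominal parameter set
scaled to a 70 kg adult. State (11 compartments):

- $S_1, S_2$ (mU): two serial subcutaneous insulin depots with time
  constant $t_{max,I} = 55$ min; infused insulin (basal + bolus) enters
  $S_1$, and the absorbed flux $S_2 / t_{max,I}$ feeds plasma.
- $I$ (mU/L): plasma insulin, eliminated at $k_e = 0.138$ /min over the
  insulin distribution volume $V_I = 0.12$ L/kg.
- $x_1, x_2, x_3$: remote insulin actions on glucose transport, disposal,
  and endogenous glucose production (EGP), first-order activations
  ($k_{a1,2,3} = 0.006, 0.06, 0.03$ /min) toward $S_{IT} I$, $S_{ID} I$,
  $S_{IE} I$ with sensitivities $51.2, 8.2, 520 \times 10^{-4}$ per mU/L.
- $D_1, D_2$ (mmol): two serial gut compartments with $t_{max,G} = 40$ min;
  a meal of $m$ g carbohydrate enters as a 1-minute impulse of
  $A_G \cdot m \cdot 1000/180.16$ mmol with bioavailability $A_G = 0.8$.
- $Q_1, Q_2$ (mmol): accessible and non-accessible glucose pools
  ($k_{12} = 0.066$ /min, $V_G = 0.16$ L/kg), with EGP
  $0.0161 (1 - x_3)$ mmol/kg/min, insulin-independent uptake
  $F_{01} = 0.0097$ mmol/kg/min (scaled below 4.5 mmol/L), and renal
  clearance above 9 mmol/L.
- $C$ (mmol/L): interstitial glucose equilibrating with plasma at
  $k_{int} = 0.073$ /min. The sensed BG $g_t$ (mg/dL, $\times 18.016$,
  clipped to $[0, 500]$) reads this CGM-analogue compartment by default; a
  config switch (`sensor_compartment: plasma`) reads plasma instead. No
  sensor noise is modelled.

With these values the fasting steady state at a 6.43 mU/min infusion sits
at 108 mg/dL — the benchmark's optimal basal rate $b^*$ falls directly out
of the physiology rather than being imposed.

### Integration

A fixed-step classical RK4 scheme with 1-minute outer steps and 6 inner
sub-steps. The scheme is deterministic (bit-identical trajectories for
identical inputs); a refinement test holds the default grid to within
0.1 mg/dL of a 10× finer grid one hour into a 60 g meal. Compartments are
clipped at zero after each outer step as a guard against numerical
undershoot under extreme insulin; the clip is inactive in all benchmark
scenarios.

### Basal calibration

`find_steady_state` solves the fasting equilibrium in closed form down to a
scalar glucose balance (root-bracketed Brent), then root-finds the infusion
rate whose equilibrium BG equals the 108 mg/dL target over
$[0, 50]$ mU/min. Heavy infusion fully suppresses EGP, in which case the
equilibrium collapses to zero glucose; that branch is handled explicitly so
the outer root-finder always has a bracket.

### Insulin-to-carb ratio

The bolus calculator needs an ICR (g of carbohydrate per U of insulin),
which the benchmark does not publish. `calibrate_icr` bisects for the
smallest ICR (largest bolus, hence smallest post-meal excursion) such that
a nominal 60 g meal bolused at mealtime on top of $b^*$ causes no
hypoglycemia (BG ≥ 70 mg/dL) over the following 8 h. Because the operating
environment doses from carb counts corrupted by up to +30%, the default
(`mode="robust"`) sizes the calibration bolus from the worst-case
overestimated count, so no realizable bolus for that meal can cause
hypoglycemia; this lands at **27.22 g/U** for the packaged patient,
agreeing with the clinical "500 rule" estimate when basal is taken as half
the total daily dose (500 / (2 × 9.26 U/day) ≈ 27). The perfect-count
variant (`mode="nominal"`, 20.94 g/U) is retained but produces substantial
late post-prandial hypoglycemia under meal variation — it minimizes the
excursion of the calibration meal at the cost of an unsafe operating
profile, which is why it is not the default. The packaged patient ships
with the robust value frozen in its YAML config; a test asserts the frozen
value reproduces the calibration.

## Meal scenarios

Four meals per day at 8:00/12:00/18:00/22:00 with bases 40/80/60/30 g;
per meal the generator draws amount noise U(−20, 20) g (clipped at 0),
timing jitter U(−30, +30) min, and a multiplicative counting error
U(−0.3, +0.3) on the announced carbs, in that fixed order from a
`numpy` generator seeded per scenario — generation is a pure function of
(seed, config). Episodes run 2160 min from midnight, so the ~14 h after
supper are meal-free. The fixed test set uses consecutive sub-seeds
(master + i); training streams use a different master seed, which keeps the
two disjoint by construction. Bolus skipping (experiment 3) independently
flags each meal with probability 0.1, leaving amounts and times untouched.

What the generator does **not** emulate: snacks, exercise, stress, sleep
physiology, day-to-day insulin-sensitivity drift, CGM noise and dropouts,
or pump faults. Passing results therefore speak to controller behaviour
under meal-timing/size uncertainty and carb-counting error only, not to
robustness on real patient data.

## Environment semantics

- The chosen basal rate is held constant for the full 30-min step; the
  integrator sees a constant infusion except at a meal minute, when the
  bolus (estimated carbs / ICR, in U → mU over one minute) is added as an
  impulse. Boluses are environment-managed: the agent never chooses them
  (hybrid closed loop).
- The reward formula takes a single BG value; we evaluate it at the
  decision instant (the last minute of the step) but scan all 30 samples
  of the step for the bounds check — any sample outside [70, 180] turns
  the step's reward into −1000. The punishment is emitted at most once per
  step, and episodes never terminate early on a breach.
- Observations are normalized for the networks as BG/100 and insulin/$b^*$,
  concatenated to a 34-vector; the map is invertible.

## Controllers

All seven variants share one skeleton (replay buffer, target network hard
copied every 1000 steps, Adam at $10^{-3}$, one gradient step per
environment step once the buffer holds 1000 transitions, discount 0.99,
batch 128 — experiment 2 uses 512). Architectures: plain 4-layer
64-unit ReLU nets for DQN/DDQN; two fully separate such blocks ending in
value and advantage streams (combined as $Q = V + A - \bar A$) for the
dueling, prioritized, and noisy variants; a 4-layer net whose last two
layers are noisy for the categorical variant; and a shared linear input
layer feeding two 3-noisy-layer streams for Rainbow. Weight
initialization is fan-in uniform, seeded.

Choices where the protocol is silent, following the original algorithms:
PER uses proportional priorities with $\alpha = 0.6$, $\beta$ annealed
0.4 → 1 over training, $\epsilon_{prio} = 10^{-6}$, new transitions at max
priority; the categorical head uses 51 atoms on $[-1000, 10]$ so the
punishment is representable (a narrower support would collapse all mass
onto its lowest atom); Rainbow uses 3-step returns; noisy layers use
factorized Gaussian noise with $\sigma_0 = 0.5$, resampled once per
training batch, and per action selection during training; evaluation is
greedy with noise zeroed. ε-greedy exploration is applied to every
variant, including the noisy ones. The mean over the schedule's $10^5$
training steps is ≈ 0.30 — the schedule constants, not any verbal gloss of
them, are what the code and tests pin down.

Two deliberate deviations from a blanket protocol statement: the
distributional variants (categorical, Rainbow) are trained with
cross-entropy against the projected target distribution rather than a
squared error, because an MSE between probability vectors does not define
the distributional Bellman update; and their PER priorities are the
per-sample cross-entropy instead of |TD error|.

## Evaluation

TIR/TAR/TBR are computed on the minute-wise mean BG trace across the
100 test episodes (primary, matching how the benchmark tables are built);
the episode-averaged TIR is reported alongside. Bounds are inclusive —
70 and 180 count as in range, consistent with the reward's range test.
μ/σ are per-episode statistics averaged unweighted across episodes; σ_A is
the population (N-denominator) SD of the 72 basal actions per episode.
Constant sequences short-circuit to an SD of exactly 0.0 to avoid the
~$10^{-16}$ floating-point residue of the two-pass formula. A convenient
identity when reading TIR: 1 percentage point = 14.4 min per
24 h-equivalent day.

## Problem sizes

The packaged tests and the acceptance script run the deterministic
pipeline at full scale (100-episode test sets, 24 h steady-state
verification) and the learning pipeline at desk scale: the tabular
policy-recovery oracle trains for 4000 steps on a 5-state chain MDP
against brute-force value iteration, and the scaled training check runs
noisy DQN for $2 \times 10^4$ environment steps (the benchmark's full runs
are $10^5$ steps per agent). At that scale the noisy-net agent already
matches the baseline's time in range (96.9% vs 96.1% on the packaged
seeds) with TBR < 1%; full-length orderings across all seven variants are
expected to remain training-noise sensitive, as the benchmark itself
reports.

## Known limitations

- Single virtual patient; no parameter variability or cohorts.
- The ICR is a package calibration, not a published value; the baseline's
  mean BG is sensitive to it (±1 g/U of ICR moves μ by roughly
  3–4 mg/dL), so per-episode mean BG should be compared across controllers
  within this package rather than against external absolute values.
- No CGM error model: the sensed signal is the noiseless interstitial
  state.
- The NumPy training loop is single-threaded and CPU-bound; a full
  $10^5$-step run of one agent takes on the order of fifteen minutes of
  CPU, and the experiment driver exposes `--steps` for shorter runs.
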