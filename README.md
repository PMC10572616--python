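# glucorl

An in-silico benchmark for closed-loop blood-glucose control in type 1
diabetes (T1D). The package bundles three things:

1. **A virtual patient** — the Hovorka compartmental model of
   glucose–insulin physiology (subcutaneous insulin absorption, plasma
   insulin, three insulin-action states, gut carbohydrate absorption,
   two-pool glucose kinetics, and an interstitial/CGM compartment) for a
   70 kg adult with T1D, advanced deterministically at 1-minute resolution.
2. **A gym-style control environment** — a hybrid closed loop in which an
   agent picks a basal insulin rate every 30 min from a small discrete menu
   while the environment delivers meal boluses computed from announced
   (error-corrupted) carbohydrate counts.
3. **Seven deep Q-learning controllers** — DQN, double DQN, dueling
   DQN/DDQN, prioritized-replay DQN, noisy-net DQN, categorical (51-atom)
   DQN, and Rainbow — implemented on small fully connected networks with a
   NumPy backprop engine, plus the evaluation protocol that scores them.

It is intended for researchers studying reinforcement learning for the
artificial pancreas who want a fully deterministic, dependency-light
re-implementation of this benchmark.

## The control problem

The agent observes the state $s_t = [G_t, I_t]$: the previous 30 one-minute
BG samples $G_t = [g_{t-29}, \dots, g_t]$ (mg/dL, clipped to $[0, 500]$) and
the 4 most recent basal actions $I_t$. Every 30 min it selects a basal rate
from $A_1 = \{0, b^*, 3b^*\}$ or $A_2 = \{0, b^*/2, b^*, 2b^*, 3b^*\}$,
where $b^*$ is the patient-specific optimal basal rate — the constant
infusion that holds BG at the 108 mg/dL reference in steady state
(6.43 mU/min for the packaged patient). Episodes last 1.5 days
(36 h = 2160 min = 72 steps).

The reward is a Gaussian bump around the reference while BG stays in the
normoglycemic range $[g_\ell, g_h] = [70, 180]$ mg/dL,

$$R(g_t) = e^{-\tfrac{1}{2}(g_t - b_r)^2 / 900}, \qquad b_r = 108\ \text{mg/dL},$$

and a punishment of $-1000$ whenever any BG sample of the step leaves the
range. Exploration during training is decaying ε-greedy,
$\varepsilon(t) = \varepsilon_F + (\varepsilon_0 - \varepsilon_F)
e^{-t/\eta}$ with $\varepsilon_0 = 1$, $\varepsilon_F = 0.01$,
$\eta = 3 \times 10^4$.

Each simulated day carries four meals (breakfast 40 g at 8:00, lunch 80 g
at 12:00, dinner 60 g at 18:00, supper 30 g at 22:00), with U(−20, 20) g
amount noise, ±30 min timing jitter, and a ±30% multiplicative
carbohydrate-counting error on the announced carbs that feed the bolus
calculator. Controllers are scored on a fixed 100-episode test set by
TIR/TAR/TBR — the percentage of time the minute-wise **mean** BG trace
spends inside / above / below [70, 180] mg/dL — plus per-episode BG mean
(μ), BG SD (σ), and basal-action SD (σ_A).

## Worked example

Calibrate the packaged 70 kg patient and run the clinical baseline
(constant $b^*$ plus automatic meal boluses) on a seeded 100-episode test
set:

```console
$ glucorl calibrate
b* = 6.4299 mU/min
ICR = 27.2187 g/U

$ glucorl baseline --seed 20000 --episodes 100 --out results/
TIR 96.11%  TAR 3.89%  TBR 0.00%  mu 117.92  sd 32.15  sd_action 0.00
```

Reading the numbers: the basal search lands on $b^* \approx 6.43$ mU/min —
holding that rate with no meals keeps the patient pinned at 108 mg/dL
indefinitely. The insulin-to-carb ratio (ICR) of ~27 g/U is the largest
mealtime bolus that can never cause hypoglycemia for a nominal 60 g meal
even under the worst-case +30% carb-count overestimate. Under that therapy
the mean BG trace stays in range 96.11% of the time, exceeds 180 mg/dL
after the larger meals (TAR 3.89%), and never goes hypoglycemic
(TBR 0.00%); σ_A is exactly 0 because the baseline never varies its basal
rate.

Training and evaluating a controller works the same way:

```bash
glucorl train --algorithm noisy_dqn --steps 20000 --seed 1 --out results/
glucorl evaluate --checkpoint results/noisy_dqn.npz --seed 20000 --out results/
glucorl experiment --id 1 --algorithm baseline --algorithm dqn --out results/exp1
```

A 20 000-step noisy-net run (seed 1) evaluated on the seed-20000 test set
reaches TIR 96.94% with TBR 0.79% — already edging out the baseline by
trading some hyperglycemia for slightly lower mean BG (μ ≈ 111 mg/dL), the
same qualitative behaviour the full-length benchmark reports for this
variant.

Everything is also available as a library; see `glucorl.patient`,
`glucorl.meals`, `glucorl.env`, `glucorl.agents`, `glucorl.evaluation`,
and `glucorl.experiments`.

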