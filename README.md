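# bondosc

Energy-based analysis of biochemical oscillators: build bond-graph
(thermodynamically parameterized) mass-action reaction networks, break the
product feedback loop, linearize about the loop-broken steady state, and
predict oscillation from classical frequency-response analysis — validated
by nonlinear limit-cycle simulation.

## Who this is for

Systems and synthetic biologists who want a *simulation-free* first answer
to "will this network oscillate, and which parameters control that?" —
and control engineers who want biochemical networks exposed as loop gains,
Bode data and root loci.

## The method

A network of species stores (`phi = RT ln(Kx)`) and mass-action reactions

    v_r = kappa_r ( prod_react (K_i x_i)^s_i - prod_prod (K_j x_j)^s_j )

produces a product species P that feeds back on the network.  Because the
closed-loop equilibrium of an oscillator is unstable, P is clamped as a
chemostat, the stable open loop is relaxed, and the clamped amount is
root-found so the net product flux vanishes.  Linearizing there with the
product duplicated into feedback-side and output-side ports gives a
two-port

    [f_f]   [g11 g12] [x_f]
    [f_o] = [g21 g22] [x_o]

from which the loop gain and its active/passive decomposition follow:

    L0 = -(g11+g12+g21+g22),   L = L0/s,
    Lact = -g21/s  (forward amplification),
    Lpas = -(g11+g12+g22)/s    (admittances + reverse gain = retroactivity).

The phase margin `theta_pm = 180deg + angle(L(j w_c))` at the gain
crossover `|L(j w_c)| = 1` is the scalar oscillation indicator: negative
margin means the closed loop is unstable, and a complex right-half-plane
pole pair of `1 + L = 0` means the instability is oscillatory — the linear
signature of a limit cycle, which nonlinear simulation then confirms.
Oscillation lives in the tension between `Lact` (destabilizing
amplification, grown by cooperativity and chain length) and `Lpas`
(stabilizing retroactivity, grown by degradation).

Two classic oscillators ship as builders: a Goodwin-like negative-feedback
enzyme chain and the Sel'kov glycolytic (positive-feedback) oscillator.
Arbitrary networks are accepted as declarative YAML/JSON model files.

## Worked example

```python
import numpy as np
from bondosc import (build_illustrative, solve_closed_loop, split_loop,
                     phase_margin, closed_loop_poles, integrate_nonlinear,
                     limit_cycle_stats)

net, loop = build_illustrative()          # 3-stage chain, cooperativity 2
ss = solve_closed_loop(net, loop)         # loop-broken steady state
print({k: round(ss.amounts[k], 3) for k in net.dynamic_species})

d = split_loop(net, loop, ss)             # two-port + loop gains
rep = phase_margin(d.L)
print(f"theta_pm = {rep.phase_margin:.1f} deg at {rep.evaluated_at:.2f} rad/s"
      f" -> {rep.verdict}")

poles = closed_loop_poles(d.L)
print("unstable pair:", np.round(poles[poles.real > 0], 3))

x0 = dict(ss.amounts); x0["P"] *= 1.001   # nudge off the equilibrium
traj = integrate_nonlinear(net, x0, t_end=40.0, n_samples=4000)
st = limit_cycle_stats(traj, "P")
print(f"limit cycle: {st.detected}, period {st.period:.3f} s")
```

Output:

```
{'E1': 0.168, 'E2': 0.283, 'E3': 0.794, 'P': 5.936}
theta_pm = -34.6 deg at 10.44 rad/s -> unstable-oscillatory
unstable pair: [1.326+10.324j 1.326-10.324j]
limit cycle: True, period 0.690 s
```

Read: the steady product amount is 5.936; the loop gain crosses unity at
10.44 rad/s with a −34.6° phase margin, so the equilibrium is unstable with
a complex growing mode (growth 1.33/s, frequency 10.32 rad/s); the
nonlinear trajectory saturates into a limit cycle whose period (0.69 s,
i.e. 9.1 rad/s) sits close to that linear frequency.

The same pipeline is scriptable from a shell:

```sh
bondosc margins --builder illustrative --outdir out/      # margins.json + bode.csv
bondosc sweep --builder illustrative \
    --param1 Kact=0.2,1,5 --param2 kappa_rf=1,10,100 --outdir out/
bondosc simulate --builder selkov --t-end 150 --outdir out/
```

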