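# cultsim

Compartmental dynamics of cultural transmission under population turnover
and behavioral conservatism.

## The problem

Does replacing experienced group members with naïve newcomers speed up or
slow down the spread of a better way of doing things?  Turnover removes
knowledgeable individuals — but if the established members are behaviorally
conservative (they rarely attend to what others do), the newcomers may be
the only ones actually learning, and turnover can *accelerate* cultural
evolution.  `cultsim` is for modellers of social learning and animal
culture who want to explore that trade-off quantitatively.

## The model

A well-mixed population faces a task with an inefficient and an efficient
solution.  Fractions n(t), i(t), e(t) are naïve, inefficient, and efficient
(n + i + e = 1).  Three continuous-time processes act:

- **innovation**: i → e at per-capita rate μ;
- **turnover**: every compartment → n at per-capita rate m (death/birth or
  emigration/immigration of naïve recruits);
- **social learning**: mass-action encounters at the product of
  frequencies.  Naïve individuals always attempt to learn; knowledgeable
  ones attempt only with probability 1 − c (c = behavioral conservatism).
  Attempts on an efficient (inefficient) demonstrator succeed at rate s_e
  (s_i), with s_e > s_i as the standing assumption.

```
n' =  m i + m e − n e s_e − n i s_i
i' = −μ i − m i + n i s_i + (1−c) e i s_i − (1−c) i e s_e
e' =  μ i − m e + n e s_e − (1−c) e i s_i + (1−c) i e s_e
```

There is no cultural loss (e never spontaneously reverts to i), so the
inefficient solution always goes extinct when μ > 0.  Key closed-form
results the package computes and verifies numerically:

- equilibrium efficient share `e* = 1 − m/s_e` for m ≤ s_e; for m > s_e the
  efficient solution goes extinct and only naïve individuals remain;
- a majority (e* ≥ 1/2) requires m ≤ s_e/2 — social learning at least
  **twice** as fast as turnover;
- the time t_h for e(t) to reach one half can *decrease* with turnover when
  c is high: the package locates the critical curve c(m) where
  ∂t_h/∂m = 0.

A drift-exact finite-population continuous-time Markov chain (Gillespie
simulation) serves as an independent stochastic oracle for the mean-field
ODE and demonstrates finite-size trait loss.

## Worked example

Simulate the canonical configuration (μ = 0.01, s_i = 0.1, s_e = 0.5,
c = 0.75, starting from an all-inefficient population), with and without
turnover:

```
$ cultsim equilibrium --m 0.1 --c 0.75 --se 0.5
e* = 0.8  regime = persistence  state = (n=0.2, i=0, e=0.8)  residual = 0  [analytic]

$ cultsim critical-ratio --c 0.75 --se 0.5
critical se/m ratio at e* = 0.5: 2.000000

$ cultsim critical-curve --se 0.5 --m-grid 0.02:0.1:5 --out curve.csv
wrote 5 curve points to curve.csv (0 m values without a root)
$ cat curve.csv
m,c
0.02,0.52023925781250002
0.040000000000000001,0.56955566406250002
0.059999999999999998,0.62893066406249998
0.080000000000000002,0.70139160156250002
0.10000000000000001,0.79147949218750013
```

Reading: with turnover m = 0.1 the efficient solution ends up in 80% of the
population (e* = 1 − 0.1/0.5 = 0.8); a majority requires learning to run at
least twice as fast as turnover; and at m = 0.05 any conservatism above
c ≈ 0.60 puts the population in the regime where *more* turnover means
*faster* adoption.  In the library:

```python
>>> from cultsim import ModelParams, DEFAULT_INITIAL, time_to_threshold
>>> p = ModelParams(mu=0.01, m=0.1, c=0.75, se=0.5, si=0.1)
>>> time_to_threshold(p, DEFAULT_INITIAL).t_h          # with turnover
18.747296203516196
>>> import dataclasses
>>> time_to_threshold(dataclasses.replace(p, m=0.0), DEFAULT_INITIAL).t_h
22.590060440161732
```

The efficient solution reaches half the population ~17% sooner with
turnover m = 0.1 than in a group of fixed membership, even though every
newcomer arrives knowing nothing.

Other subcommands: `simulate` (trajectory CSV), `sweep-th` and `sweep-eq`
(long-format grid CSVs with a reachability column), `abm` (one exact
stochastic sample path), `robustness` (equilibrium independence from the
starting condition).  All accept a flat YAML config via `--config`, with
flags taking precedence.

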