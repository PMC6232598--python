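# bibswarm

Bayesian / inverse-Bayesian (BIB) inference for nonstationary discrete
environments, and an agent-based swarm model in which every individual
runs a BIB inference loop over its local crowding level.

The package is aimed at researchers in collective animal behaviour and
agent-based modelling who want (a) a small, fully seeded implementation
of the BIB hypothesis-update scheme, (b) a trajectory-analysis pipeline
(polarization, local-density symbolisation, prediction scoring) for
tracked 2-D group data, and (c) the swarm simulator that couples a
Vicsek-style alignment rule to per-agent density inference.

## The model

An agent holds hypotheses *h₀ … h_{m−1}* over a finite data alphabet
*d₀ … d_{n−1}*.  Each hypothesis is a likelihood row *P(d | h)*; the
belief *Pᵗ(h)* is updated by Bayes' rule after every observed symbol:

    P^{t+1}(h) = P(d | h) Pᵗ(h) / Σ_k P(d | h_k) Pᵗ(h_k)

Plain Bayesian (B) inference keeps the rows fixed.  *Inverse-Bayesian*
(IB) inference additionally rewrites the hypothesis set itself: at each
step the least probable hypothesis *h_s = argmin Pᵗ(h)* is, with
probability 1 − Pᵗ(h_s), replaced by the empirical symbol frequency
*fᵗ(d)* of the last *M* observations, and the fresh hypothesis restarts
from the uniform prior share.  The combination (B + probabilistic IB)
is the BIB system; decisions are read off the currently most probable
hypothesis, *P(d | h_max)*.

In the swarm model each of *N* agents observes a relative-density
symbol *d ∈ {0,1,2,3}* computed from its neighbour counts within radii
*r* and *2r* (d = min(3, INT(4·n_r/n_2r)), d = 0 for an empty
neighbourhood), Bayes-updates its belief, anticipates its next position
through an alignment rule (the sum of its neighbours' unit velocity
vectors within radius *R*), and then moves to whichever of 72 candidate
positions on the circle of radius *u* around the anticipated position
has anticipated density closest to its currently preferred symbol
*d_max*.  Polarization ψ — the norm of the mean unit-velocity vector —
summarises the group state.

## Worked example

Track a categorical source whose P(d₀) follows a sine curve, with a
Bayes-only agent and a BIB agent:

```python
import bibswarm as bs

env = bs.make_sin_env(n=4, b=0.5, A=0.4, T_per=3000, T=5000, seed=1)
for mode in ("b", "bib"):
    res = bs.run_tracking(env, M=100, mode=mode)
    print(mode, round(res.error, 3))
```

prints

```
b 0.247
bib 0.037
```

The Bayes-only agent locks onto the hypothesis favoured by the long-run
symbol majority and its mean absolute tracking error is dominated by
the sine's amplitude; the BIB agent keeps substituting its worst
hypothesis with the recent window frequency and follows the drift.
The same contrast from the command line:

```
$ bibswarm toy-track --horizon 500 --m 50 --seed 7 --out-dir demo
0.044557
```

which also writes `demo/toy_track_bib.csv` with per-step truth and
prediction.  A swarm run (30 agents, 300 steps) and the number of
polarization collapse/re-formation cycles it produced:

```
$ bibswarm simulate --n 30 --r 15 --big-r 15 --steps 300 --seed 7 --out-dir demo
0
```

The trajectory CSV it writes (`id,frame,x,y`) feeds straight back into
`bibswarm analyze`, which computes the polarization series, each
individual's density-symbol stream, the per-symbol predictions
*P(d | h_max)* for both inference modes and the future frequency
*Fᵗ(d)* benchmark.

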