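# egosign

Balance and status dynamics on signed directed networks, from the ego
perspective.

Signed social networks — who likes, trusts, respects, or disparages whom —
are shaped by two competing drives. *Structural balance* pushes triads of
relations towards consistency ("a friend of my friend is my friend");
*status theory* reads a positive directed link as deference and demands a
consistent ranking. `egosign` implements an agent-based model that unifies
the two: a focal agent repeatedly inspects one **ego-based triad** (its two
out-links `A→B`, `A→C` plus the inner link `B→C`), evaluates it by status
with probability `q` and by balance otherwise, and, if the triad is
unstable, flips one of its *own* links — the negative one with probability
`p_ST` (status) or `p_SBT` (balance) when the two focal links disagree.

The package is for computational social scientists who want to simulate
the model, analyse it exactly, and calibrate it against observed signed
networks (SNAP-style `source target sign` edge lists):

* `egosign.signed_graph` — signed digraph container, edge-list I/O,
  synthetic generators (complete, random, triangle-rich).
* `egosign.triad_logic` — the eight ego-triad classes
  `{BH0, UH0, UN1, UH1, BH1, BN1, BH2, UH2}`, exact census, group
  deviations, and the 16-class unsigned 3-node pattern accounting.
* `egosign.abm_dynamics` — the Monte-Carlo engine: triad sampling on
  complete and general graphs, link pruning, trajectories, paradise
  absorption.
* `egosign.mean_field` — exact analytics. Under independent Bernoulli(ρ)
  signs the drift of the positive-link density factors as
  `(1−ρ)·Q(ρ)` with

  ```
  Q(ρ) = [2(1−q)(2p_SBT−1)] ρ² − [2(1−q) + (1−2p_ST) q] ρ + (1−q)
  ```

  so ρ=1 (the all-positive *paradise* state) is always a fixed point and
  the quasistationary densities are the roots of `Q`. The module
  classifies root stability, locates the separatrix in bistable regimes,
  and detects continuous vs. discontinuous (fold) transitions. With
  balance alone (`q=0`) paradise is reached only for `p_SBT > 0.75`;
  sweeping `p_SBT` the transition is continuous for `p_ST > 0.5` and
  discontinuous for `p_ST < 0.5`.
* `egosign.fitting` — grid-search calibration of `(q, p_SBT, p_ST)` to an
  observed network's triad-deviation profile.
* `egosign.cli` — the `egosign` command with `generate`, `census`,
  `simulate`, `phase`, `phase-sweep`, and `fit` subcommands; every run
  writes a JSON manifest for bit-for-bit replay.

## Worked example

Phase portrait at the balance-only critical point — a double root at ρ=1:

```console
$ egosign phase --q 0 --psbt 0.75 --pst 0.5
{
  "q": 0.0, "psbt": 0.75, "pst": 0.5,
  "roots": [1.0],
  "stability": ["stable"],
  "separatrix": null,
  "regime": "paradise"
}
```

Simulate a complete graph of 50 agents at the symmetric point
`q = p_SBT = p_ST = 0.5`, where `Q` reduces to `−ρ + 1/2`:

```console
$ egosign simulate --topology complete --n 50 --q 0.5 --psbt 0.5 --pst 0.5 \
    --seed 3 --out traj.tsv
absorbed=none stationary=True rho=0.497265306122 se=0.00181925132688 steps=245000
```

The quasistationary density 0.497 ± 0.002 matches the analytic root 0.5:
signs keep flipping, but half the links stay positive. `traj.tsv` holds
the per-sweep density; rerunning with the same seed reproduces it
byte-for-byte.

In Python, the same machinery:

```python
from egosign import ModelParams, quasistationary_roots

portrait = quasistationary_roots(ModelParams(q=0.5, p_sbt=0.92, p_st=0.2))
print(portrait.regime)          # "bistable"
print(portrait.separatrix)      # 0.8333… — initial densities above it
                                # flow to paradise, below it to ρ≈0.714
```

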