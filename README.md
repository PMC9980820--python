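# boldsim

Individual-based simulations of a small animal group leaving a safe refuge
for a foraging site, built to ask one question: **when individuals pay
attention to each other, how much of their consistent "personality"
variation in boldness survives in the group's observable behaviour?**

## The model

A group of *n* individuals lives on a one-dimensional axis with a refuge at
position 0 and a foraging site everywhere beyond *d*<sub>food</sub>
distance units. Individual *i* (its place in a boldness hierarchy) has

* a constant personal speed *s*<sub>*i*</sub> ~ U(0.95, 1.0), drawn once;
* a personal outward-probability increment
  ω<sub>*i*</sub> = (*i* − 1) · ω<sub>difference</sub>, so the hierarchy is
  a ladder of boldness (an alternative one-based convention,
  ω<sub>*i*</sub> = *i* · ω<sub>difference</sub>, is discussed in
  `docs/methods.md`);
* a time-dependent probability of moving outward
  *p*<sub>*i*,*t*</sub> = *p*<sub>baseline</sub> + *t* · ω<sub>*i*</sub>
  (the per-period recursion *p* ← *p* + ω, never clamped).

Each period every individual makes one decision, in a freshly randomised
order. An individual at the foraging site never moves again; one behind
the refuge is forced a step outward; otherwise it steps outward with
probability *p*<sub>*i*,*t*</sub>, and on failure performs the group's
social action:

| rule | failed-draw behaviour |
|---|---|
| `central` | step toward the mean position of the other group members |
| `nearest_neighbour` | step toward the closest neighbour (random among ties) |
| `majority` | step toward the side holding more colleagues |
| `non_social` | stay put |

A run ends at the first period after which everyone is at the foraging
site. Recorded per individual: the **leave time** (first passage of a
10-unit threshold), the **arrival time** (first passage of
*d*<sub>food</sub>) and their difference, the **travel time**.

On top of the simulator the package provides the replication machinery —
deterministic single-parameter sweeps over ω<sub>difference</sub>,
*p*<sub>baseline</sub>, *d*<sub>food</sub> and *n* with per-run seeds
derived from a master seed — and the analysis layer: within-run min–max
rescaling of event times, a one-way ANOVA of per-run measures on the swept
parameter, a mixed repeated-measures ANOVA (parameter between runs,
identity within runs; a large identity F means individuals are easy to
tell apart from timing alone), and a per-identity ordering-difference
metric in [−1, 1] between seed-paired social and non-social runs.

## Worked example

Two hundred replicate groups per rule at the baseline parameters
(*n* = 10, *p*<sub>baseline</sub> = ω<sub>difference</sub> = 0.001,
*d*<sub>food</sub> = 100, one-based indexing):

```python
import numpy as np, pandas as pd
from boldsim import SimulationConfig, run_simulation

rows = []
for rule in ("non_social", "nearest_neighbour", "majority", "central"):
    logs = [run_simulation(SimulationConfig(rule=rule, seed=s,
                                            omega_indexing="one_based"))
            for s in range(200)]
    rows.append(dict(
        rule=rule,
        end_time=np.mean([l.end_time for l in logs]),
        leave_time=np.mean([l.leave_time.mean() for l in logs]),
        travel_time=np.mean([l.travel_time.mean() for l in logs]),
        leave_latency=np.mean([(l.leave_time - l.leave_time.min()).mean()
                               for l in logs]),
    ))
print(pd.DataFrame(rows).set_index("rule").round(1))
```

```
                   end_time  leave_time  travel_time  leave_latency
rule
non_social            451.9        73.0        156.7           30.2
nearest_neighbour     283.1        61.1        138.8           21.7
majority              168.2        45.7        119.2            3.2
central               162.3        49.4        111.2            2.4
```

Reading the table: groups that ignore each other take the longest to get
everyone across (`end_time`), and attention to the whole group (`majority`,
`central`) compresses departure latencies by an order of magnitude — the
group moves as one. The centroid rule departs later than the majority rule
but crosses faster, so it minimises time exposed in the open.

The same machinery from the shell:

```bash
boldsim simulate --rule central --seed 1 --replicates 5 --out runs/
boldsim sweep --parameter omega_difference --protocol full-group \
              --replicates 200 --out sweep/
boldsim analyze sweep/results.csv --out analysis/
```

Every command writes a `manifest.yaml` that, together with the package
version, reproduces its outputs byte for byte.

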