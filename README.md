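# socsel

Social selection analysis for wild animal populations tracked with
RFID-tagged individuals at automated feeding stations.

In many social species an individual's fitness depends not only on its
own phenotype but on the phenotypes of the conspecifics it associates
with. The motivating system is a woodland songbird population in which
birds arriving late into the study area are less likely to acquire a
breeding territory — unless they associate with birds that arrived even
later. `socsel` implements the full chain of analysis needed to measure
that kind of socially modulated selection from raw detection streams:

1. **Gathering events** — time-stamped feeder reads are segmented into
   flock visits (an inter-detection-gap rule, or a 1-D Gaussian mixture
   with BIC model selection), giving a binary group-by-individual (GBI)
   matrix under the gambit of the group.
2. **Association network** — the simple ratio index
   `w_AB = x / (x + y)` (x = events with both, y = events with exactly
   one) yields a weighted network whose edges estimate the probability
   that two birds forage in the same flock.
3. **Weighted assortativity** — the interaction covariance `C^I` of
   arrival time is the edge-weight-weighted Pearson correlation `r̂`
   between the trait values at the two ends of every (doubly oriented)
   edge, with a delete-one-edge jackknife SE and a data-stream
   permutation null that swaps individuals between events while holding
   every event size and every individual's observation count fixed.
4. **Selection gradients and decomposition** — with binary fitness
   `w_i` (bred / floater), logistic regression
   `w_i ~ α + β_N z_i + β_S z̄_i` estimates the nonsocial gradient on
   the bird's own standardized arrival time `z_i` and the social
   gradient on the weighted mean arrival time of its associates
   `z̄_i = Σ_k ω_ik z_k / Σ_k ω_ik`. Total selection decomposes as

   ```
   s = P β_N + C^I β_S        (P = 1 for a standardized trait)
   ```

   so positive assortment (`C^I > 0`) with a positive social gradient
   can offset negative selection on the trait itself.
5. **Breeding geography** — connected vs non-connected dyad breeding
   distances (Welch t-test), the OLS slope of breeding distance on edge
   weight against a nestbox-randomization null, and a per-individual
   competition index (time-weighted local birds-per-nestbox).
6. **Brood effects** — variance in arrival time partitioned among natal
   brood, year, and residual by a crossed random-intercepts Gaussian
   model fitted with parameter-expanded EM.

A fully seeded synthetic-data generator (`socsel.simulate`) produces
winters with known ground truth — two-wave arrivals, density-dependent
spatial settlement that assorts the arrival phenotype, bursty flock
visits, logistic territory outcomes — so every stage can be validated
by parameter recovery.

## Worked example

```python
import json
from socsel import SimulationConfig, run_all

cfg = SimulationConfig(n_individuals=400, n_feeders=25, seed=42)
report = run_all(cfg, n_perm=200, n_rand=1000, n_nestboxes=600)
print(json.dumps(report["summary"], indent=2))
```

prints (abridged):

```json
{
  "n_juveniles": 198,
  "pct_juveniles": 49.5,
  "n_on_territory": 62,
  "beta_N": -1.72,  "se_N": 0.51,  "p_N": 0.00066,
  "beta_S": 3.67,   "se_S": 1.42,  "p_S": 0.0098,
  "C_I": 0.261,
  "term_nonsocial": -1.72,
  "term_social": 0.955,
  "s_total": -0.764
}
```

Reading it: the winter network is positively assorted by arrival time
(`C_I = r̂ = 0.261`, permutation p ≈ 0.005 at 200 permutations), late
arrival is selected against (`β_N < 0`), but associating with late
arrivers raises the probability of acquiring a territory (`β_S > 0`),
so the social term `C^I β_S = 0.955` offsets part of the nonsocial term
and total selection is `s = -0.764`. The same report carries the
spatial stages (connected dyads bred 296 m apart on average vs 791 m
for non-connected dyads; breeding distance fell 1588 m per unit edge
weight, randomization p = 0.001) and the brood stage (13% of arrival
variance attributed to natal brood, 0.07% to year, truth 12% / 2.7%).

The same stages are scriptable from a shell:

```bash
socsel simulate --seed 1 --out run/
socsel events --detections run/detections.csv --out run/events.csv
socsel network --events run/events.csv --out run/edges.csv
socsel run-all --seed 1 --out run/full/
```

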