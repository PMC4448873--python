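# flocknet

**Fission–fusion social structure from automated detection streams.**

Wintering birds such as great tits forage in loose flocks whose membership
turns over within minutes. Grids of RFID-equipped feeders produce
timestamped streams of individual visits from which those flocks — and the
season-long social network they add up to — can be reconstructed. The hard
question is *why* the network is phenotypically structured: do individuals
actively choose (or avoid) groupmates of a given sex, age or origin
(**social** effects), or do phenotypes simply settle unevenly in space so
that co-occurrence follows geography (**spatial** effects)?

`flocknet` implements a complete, reproducible pipeline for that question:

1. **simulate** — a synthetic study design (feeder grid, two-day sampling
   periods, bursty visitation) with *planted* social preferences, spatial
   segregation and a known group-size asymptote, so every later stage can
   be validated against ground truth;
2. **infer-groups** — segmentation of each feeder-day's detection times by
   a one-dimensional Gaussian mixture (EM, BIC-selected number of bursts),
   yielding the group-by-individual matrix;
3. **network** — simple-ratio association indices
   SRI = x/(x + y_A + y_B) ∈ [0, 1] and Newman's weighted assortativity
   r = (Σᵢeᵢᵢ − Σᵢaᵢbᵢ)/(1 − Σᵢaᵢbᵢ) for discrete and continuous traits;
4. **group-stats** — lagged group stability
   S(τ, X) = G_jk/(G_j!k + G_k!j + G_jk), group-size classes (≥5% of
   memberships per class), composition proportions, binomial composition
   probabilities C(n,k)pᵏ(1−p)ⁿ⁻ᵏ and kurtosis size-assortment, and
   within-sex body-size PC1;
5. **null-test** — two contrasting permutation null models: a node-label
   (phenotypic) shuffle and a spatio-temporally restricted data-stream
   swap chain that conserves group sizes, individual observation counts
   and group locations/periods. Outside both ⇒ social; outside the
   node-label null only ⇒ spatial; inside both ⇒ none;
6. **saturation** — linear versus logistic
   (y = K/(1 + exp(−(x − x₀)/s))) fits of group size on local population
   size, compared by AIC, exposed as a `SaturationModel.fit()` →
   `SaturationResults.summary()` pair.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Simulate a population of 80 birds on 6 feeders over 2 sampling periods
with a planted preference for mixed-sex groups (same-sex weight 0.25),
infer groups, and test each trait against both null models:

```python
from flocknet.pipeline import RunConfig, run_pipeline

cfg = RunConfig.from_dict({
    "out_dir": "demo",
    "seed": 42,
    "simulation": {"n_individuals": 80, "n_feeders": 6, "n_periods": 2,
                   "social_preference": {"same_sex": 0.25}},
    "node_iterations": 200,
    "stream_iterations": 20_000,
    "sample_every": 200,
})
report = run_pipeline(cfg)
print(report.body["nulls"]["sex"])
```

Output (abridged):

```
infer: 2971 detections -> 194 groups
sizes: mean 5.13, max 21, typical 8.37
sex:       observed r = -0.111  verdict = social
           node envelope   [-0.060, +0.063]
           stream envelope [-0.070, -0.030]
residency: observed r = -0.052  verdict = none
```

The observed sex assortativity (−0.111) lies below both the node-label
envelope and the data-stream envelope, so the mixed-sex structure cannot
be explained by phenotype geography or by observation patterns — it is
attributed to social grouping decisions, exactly the effect that was
planted. Residency, which was left neutral, stays inside both envelopes.

The same pipeline is available from the shell:

```bash
flocknet simulate --seed 42 --out-dir demo --n-individuals 80 --n-feeders 6 --n-periods 2
flocknet infer-groups --detections demo/detections.csv \
    --out demo/groups.csv --meta demo/groups_meta.csv --seed 42
flocknet null-test --groups demo/groups.csv --meta demo/groups_meta.csv \
    --phenotypes demo/phenotypes.csv --trait sex --seed 42 --out demo/sex.json
```

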