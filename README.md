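# quollscr

Spatial capture-recapture (SCR) density estimation for camera-trap
surveys of individually identifiable animals, built around the workflow
used to monitor spotted-tailed quolls (*Dasyurus maculatus*) with
baited camera traps: manual photo-identification of individuals from
their unique pelage patterns, collapse of image sequences into
independent detection events, standardised 42-night surveys of
noon-to-noon occasions, and a maximum-likelihood SCR fit per survey
with AICc comparison of behavioural-response encounter models.

## The model

Each animal has a latent activity centre $s$; centres follow a
homogeneous Poisson process with intensity $D$ (animals km⁻²).  A
camera (proximity detector) $k$ detects an animal centred at $s$ on
occasion $t$ with probability

$$p(s,t,k) = g_0(t,k)\,\exp\!\left(-\frac{d(k,s)^2}{2\sigma^2}\right),$$

the half-normal detection function, where $g_0$ is the baseline
encounter probability (logit link) and $\sigma$ (metres) the spatial
scale of detection.  The number of detected individuals $n$ is Poisson
with mean $\Lambda = D \sum_s p_\cdot(s)\,a$ over a discretised habitat
mask (grid cells of area $a$ within a buffer of the detectors; the
buffer is iterated to $4\hat\sigma$), and each detected animal
contributes its mask-integrated history probability.  Six encounter
models act on $\mathrm{logit}(g_0)$: null (`0`), learned response `b`,
site-specific learned response `bk`, transient responses `B`/`Bk`, and
a linear time trend `T`; models are ranked by AICc with
$n$ = detected individuals.

A synthetic-data generator produces both detection histories and raw
timestamped 10-image trigger sequences (with retrigger bursts,
non-identifiable sequences, and single-side "semi" profiles) under the
same model, so the entire pipeline can be validated against known
ground truth.

## Worked example

```python
import quollscr as q

# simulate one survey at the default design: 25 cameras on a 5x5 grid
# at 500 m, 42 noon-to-noon occasions, D = 0.4 / km^2, g0 = 0.08,
# sigma = 500 m
cfg = q.SimulationConfig(seed=1)
capthist, truth = q.simulate_capthist(cfg)
print(capthist)

res = q.fit_with_autobuffer(capthist, cfg.detectors, "0")
print(res.summary())
```

prints

```
CaptHist(individuals=6, occasions=42, detectors=25, detections=38)
Spatial capture-recapture fit
================================================================
model: 0    detected individuals: 6    occasions: 42    detectors: 25
mask: 2092 cells, spacing 124 m, buffer 1986 m
logL = -200.5162    K = 3    AICc = 419.032
converged: True (|grad| = 1.00e-06)

       estimate        se       lcl      ucl
D      0.387556  0.168797  0.171229 0.877185
g0    0.0613877 0.0163742 0.0361181 0.102458
sigma   496.013   66.5617   381.301  645.236

D: animals per km^2 (lognormal 95% CI); sigma in metres.
```

`D` is the density estimate (here 0.39 animals km⁻² against a true
value of 0.4, with an asymmetric lognormal 95% CI respecting $D>0$),
`g0` the baseline nightly encounter probability at a camera placed on
the activity centre, and `sigma` the half-normal movement scale.  The
mask buffer converged to $4\hat\sigma \approx 1986$ m (the true
$4\sigma$ is 2000 m).

For a full site analysis from raw CSVs (detection table + detector
layout), use the pipeline or the CLI:

```sh
quollscr simulate --seed 7 --out sim_site
quollscr compare sim_site/detections.csv sim_site/detectors.csv \
    --start "2020-07-01 12:00:00"
quollscr run-all --config site.yaml
```

`run-all` writes per-survey capture files, an AICc model-comparison
table, a per-survey density table (individuals, independent events,
re-detection shares, best model, density with CI), cross-survey density
summaries, cumulative detection curves and a JSON run log.

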