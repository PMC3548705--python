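# seco — Separation–Concordance maps for reproducible k-means

k-means only guarantees a local optimum, so the standard practice of
running many random initialisations and keeping the lowest
within-cluster sum of squares (WSS) quietly assumes that near-optimal WSS
values all describe the same partition.  As the number of clusters k
grows, that assumption breaks: runs with practically identical WSS can
differ markedly in cluster composition, and the "best" partition stops
being reproducible between batches of initialisations.

`seco` implements the Separation–Concordance (SeCo) framework for
selecting a partition that is both well separated and stable:

1. fit an ensemble of `n_total` seeded k-means runs (batch Lloyd
   iteration plus on-line refinement) for each candidate k;
2. rank runs by the separation score **ΔSSQ = TSS − WSS** and retain the
   top fraction *f* (defaults: 500 runs, top decile → 50 retained);
3. score every retained run by **med(CV)** — the median of its pairwise
   Cramér's V, `V = sqrt(χ² / (N · min(P−1, Q−1)))`, against the other
   retained runs;
4. plot the retained (ΔSSQ, med(CV)) points — the **SeCo map** — and
5. select the run with the highest med(CV) (the *dual-measure* choice),
   rather than ΔSSQ alone (the *single-measure* convention).

The package ships the accompanying evaluation machinery: a 10-component
trivariate Gaussian-mixture benchmark generator with printed-parameter
fidelity checks via Dasgupta's c-separation index, reference-partition
derivation and projection, optimal-matching accuracy, ensemble affinity,
a repeated-selection benchmarking protocol, and a partition tree that
traces cohort membership flow across consecutive k.

Intended users: anyone who clusters continuous data with k-means and
needs the partition to be defensible under re-analysis — e.g. disease
sub-typing or expression profiling, where an unstable cluster assignment
invalidates downstream inference.

## Worked example

```python
import numpy as np
import seco

# 2,000 points from the built-in benchmark mixture
spec = seco.table1_spec()
X, true_cohorts = seco.sample_mixture(spec, 2000, 42)

cfg = seco.SeCoConfig(n_total=100, fraction_f=0.10,
                      k_range=[8, 9, 10], master_seed=7)
seco_map = seco.build_seco_map(X, cfg)

for k, points in seco_map.points.items():
    med = [p.med_cv for p in points]
    print(f"k={k:2d}  retained={len(points)}  "
          f"med(CV) range {min(med):.4f}..{max(med):.4f}")

chosen = seco_map.selected()[10]
print(f"selected run {chosen.run_id}: wss={chosen.wss:.2f}, "
      f"delta_ssq={chosen.delta_ssq:.2f}")
```

Output:

```
k= 8  retained=10  med(CV) range 0.9759..0.9920
k= 9  retained=10  med(CV) range 0.9682..0.9954
k=10  retained=10  med(CV) range 0.8211..0.9347
selected run 51: wss=1839.50, delta_ssq=10496.62
```

Read: at every candidate k the top decile of 100 runs is retained; the
med(CV) range shows how mutually consistent those well-separated runs
are.  Here k = 8 and k = 9 are stable (all retained runs agree at
V > 0.96) while at k = 10 runs with near-identical ΔSSQ disagree
markedly (V down to 0.82) — exactly the degeneracy the map exposes, and
the situation where choosing by ΔSSQ alone is not reproducible.  The
selected solution is the most stable of the well-separated runs at
k = 10; its ΔSSQ says how much of the total variance the partition
explains.

The same pipeline is available from the shell:

```bash
seco simulate -n 2000 --seed 42 --out data/sim.csv
seco map --input data/sim.csv --k-range 2:12 --n-total 100 \
         --seed 7 --out-dir out/ --plot
seco select --input data/sim.csv -k 10 --n-total 100 --seed 7 --out-dir out/
```

Short narrative scripts, one per capability, live in `examples/`.

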