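"""Compare single-measure (best SSQ) and dual-measure (SeCo) selection.

Derives a reference partition on a 4,000-point mixture sample (best WSS of
100 runs at k = 10), projects it onto a sparse 500-point sample, then
repeats the whole selection pipeline 8 times per method and reports the
accuracy and affinity of the selected partitions against the reference.
Scaled down from the full protocol (500 runs, 100 repetitions) to stay
quick; the code paths are identical.
"""

import numpy as np

import seco
from seco import mixture

spec = seco.table1_spec()
X_big, _ = mixture.sample_mixture(spec, 4000, 1)
reference = mixture.derive_reference_partition(X_big, 900, k=10, n_runs=100)

X_small, _ = mixture.sample_mixture(spec, 500, 2)
ref_small = mixture.project_reference(reference, X_small)

cfg = seco.SeCoConfig(n_total=100, fraction_f=0.10, k_range=[10],
                      master_seed=5000)
results = seco.benchmark_both(X_small, ref_small, 10, 8, cfg)

for method, res in results.items():
    print(f"{method:>6}: accuracy {res.accuracy_mean:.4f} "
          f"(sd {res.accuracy_sd:.4f})  affinity {res.affinity:.4f}  "
          f"mean CV vs reference {np.mean(res.cv_values):.4f}")

print("\nAccuracy: optimal-matching agreement with the reference partition.")
print("Affinity: how consistently each point lands in the same cohort")
print("across the repeated selections (1.0 = never swaps).  Compare the")
print("two rows: the dual measure trades at most a sliver of accuracy for")
print("stability; at this reduced scale the two methods often coincide,")
print("and differences grow with the degeneracy of the SSQ landscape.")
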