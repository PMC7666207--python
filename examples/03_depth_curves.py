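"""Sequencing-saturation and gene-detection curves under read thinning.

Thins the simulated reads to a grid of target depths and reports, at each
depth, the sequencing saturation (1 - UMIs/reads), total genes detected,
and median genes/UMIs per cell — the standard per-sample sequencing
metrics as a function of mean reads per cell.
"""

import pandas as pd

import scdepth
from scdepth.subsample import compute_depth_metrics, fraction_for_target_depth, subsample_reads

cfg = scdepth.GeneratorConfig(n_genes=1000, n_cells=600, seed=2)
cm, reads, _ = scdepth.generate_dataset(cfg)
realized = reads.total_reads / cm.n_cells
print(f"full dataset: {realized:,.0f} mean reads/cell\n")

rows = []
for target in list(range(20_000, 100_001, 20_000)) + [int(realized)]:
    f = fraction_for_target_depth(reads, target)
    t_cm, t_reads = subsample_reads(cm, reads, f, seed=target)
    m = compute_depth_metrics(t_cm, t_reads)
    rows.append({"target_depth": target, **m.as_dict()})

table = pd.DataFrame(rows).round({"sequencing_saturation": 3, "mean_reads_per_cell": 0})
print(table.to_string(index=False))
# Saturation rises steeply then plateaus: beyond the knee of the curve,
# additional reads mostly re-sequence molecules that are already counted,
# which is why read depth can be cut with little downstream cost.
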