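#!/usr/bin/env python
"""Ks divergence, NJ tree, and the age of the oldest duplication.

On the simulated family from results/run/: builds the gap-free codon
alignment of active indel-free main-family loci, computes the
Nei-Gojobori (Jukes-Cantor) Ks matrix, dates the oldest duplication by
the Ks ratio against a simulated sister-species ortholog calibrated at
19.6 Mya, and writes an NJ tree with bootstrap support.  Then repeats
the dating over 20 replicate families to measure recovery of the true
deepest split.
"""

import pandas as pd

from amplicony import evolution, experiments
from amplicony.config import RunConfig
from amplicony.pipeline import run_evolve

OUTDIR = "results/run"


def main() -> None:
    cfg = RunConfig(seed=1, bootstrap_reps=200)
    summary = run_evolve(cfg, OUTDIR)
    print("single-family Ks summary:")
    for key in ("mean_ks", "max_ks", "most_distant_taxon",
                "interspecies_ks_mean", "duplication_age_mya"):
        if key in summary:
            val = summary[key]
            print(f"  {key}: {val:.4f}" if isinstance(val, float)
                  else f"  {key}: {val}")
    print(f"  (matrix: {OUTDIR}/ks_matrix.tsv, tree: {OUTDIR}/tree.nwk)")

    # worked example of the dating arithmetic itself
    age = evolution.estimate_duplication_age(0.0443, 0.1517, 19.6)
    print(f"\ndating arithmetic check: 0.0443/0.1517 x 19.6 = {age:.2f} Mya")

    rec = experiments.dating_recovery(n_seeds=20, seed0=0)
    rows = [{"estimated_age": r.estimated_age, "true_age": r.true_age,
             "n_active": r.n_active} for r in rec["results"]]
    pd.DataFrame(rows).to_csv("results/dating_recovery.tsv", sep="\t",
                              index=False)
    print(
        f"\nrecovery over {rec['n']} replicate families: mean estimate "
        f"{rec['mean_estimated_age']:.2f} Mya vs mean true deepest split "
        f"{rec['mean_true_age']:.2f} Mya (ratio {rec['ratio']:.3f})"
    )


if __name__ == "__main__":
    main()
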