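#!/usr/bin/env python
"""Locus-specific expression from unique 36 bp read pairs.

Runs the quantification on the star-divergence family (every locus
carries private variation, so unique assignment is informative):
collapse identical transcripts, align pairs with <= 2 mismatches per
mate, keep both-end-unique concordant pairs, tier them into the A/B/C
mismatch categories, and normalise by copy number, length ratio and
unique sites.  Reports the Spearman correlation against the simulated
truth levels.  Also quantifies the genealogical family from
results/run/ (if present) to show how near-identical recent duplicates
defeat unique assignment.
"""

from pathlib import Path

from amplicony import experiments
from amplicony.config import RunConfig
from amplicony.pipeline import run_quantify

OUTDIR = Path("results")


def main() -> None:
    result = experiments.expression_recovery(seed=1, n_pairs=10_000,
                                             error_rate=0.001)
    result["table"].to_csv(OUTDIR / "expression_counts.tsv", sep="\t",
                           index=False)
    result["summary"].to_csv(OUTDIR / "expression_summary.tsv", sep="\t",
                             index=False)
    print("star-divergence family (10,000 pairs, 0.1% error):")
    print(result["summary"].round(4).to_string(index=False))
    for fam, rho in result["spearman_A"].items():
        print(f"  {fam}: Spearman(normalised A, truth) = {rho:.3f}")

    run_dir = OUTDIR / "run"
    if (run_dir / "transcripts.fasta").exists():
        table = run_quantify(RunConfig(seed=1), run_dir)
        assigned = int(table.countA.sum())
        print(
            f"\ngenealogical family for comparison: {assigned} of 20000 "
            f"pairs uniquely assigned across {len(table)} references "
            "(recent duplicates are indistinguishable at 36 bp)"
        )


if __name__ == "__main__":
    main()
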