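# amplicony

Simulation and analysis of **ampliconic Y-chromosome multi-copy gene
families** — gene families that amplified by repeated block duplication in
the male-specific region of the Y chromosome, where copies are born by
duplication and die by pseudogenization ("birth-and-death" evolution).
The package is aimed at molecular-evolution researchers who want a tested,
reusable implementation of the analyses such families call for, exercised
end to end on synthetic data with known ground truth:

* **Pseudogene/active classification** of amplified copies against a
  reference CDS: splice-aware transcript assembly (GT–AG check), ORF
  finding, indel/frameshift detection by global alignment, premature-stop
  localisation, and structural typing (full-length, insertion-frameshifted,
  deletion-frameshifted).
* **Locus-specific expression** of near-identical paralogs from 2 × 36 bp
  paired reads: identical loci collapsed into unique references, pairs kept
  only when both mates hit a single reference concordantly with ≤ 2
  mismatches per mate, tiered into mismatch categories, and normalised for
  copy number, length and unique-site content.
* **Ks-based duplication dating**: Nei–Gojobori synonymous divergence with
  Jukes–Cantor correction and pairwise deletion, calibrated against a
  species split.
* **Neighbor-joining phylogenetics** with codon-bootstrap support.
* **Ampliconic repeat structure**: exact-word dot-plots, direct/inverted
  repeat arm detection with arm-to-arm identities, and stringent
  overlap-based contig assembly.

## The statistics at the core

For an aligned codon pair, Nei–Gojobori counting assigns each codon
position a synonymous-site fraction (synonymous one-step changes / 3),
averages the synonymous and nonsynonymous difference counts `Sd`, `Nd`
over all minimal substitution pathways that avoid stop codons, and
corrects the proportions for multiple hits with Jukes–Cantor:

```
ps = Sd / S          dS = -(3/4) ln(1 - 4 ps / 3)        (undefined for ps >= 3/4)
```

Because synonymous changes are approximately neutral, `dS` (= Ks) is a
molecular clock.  With a calibrated species split at `t` Mya whose mean
interspecies Ks is `k_between`, the oldest duplication among extant active
copies dates to

```
age = k_within_max / k_between x t
```

Expression of a collapsed reference is normalised as

```
normalized = raw_count / copy_number x average_length / length x 1 / unique_sites
```

where `unique_sites` counts the read-pair placements on the reference whose
implied 36-mers include sequence private to that reference.

A copy is called **active** when its predicted peptide reaches
`max(200 aa, 40% of the reference peptide)`, and **pseudogene** otherwise;
frameshifts are indels of length not divisible by 3 inside the CDS.

## Worked example

The numbered scripts under `analysis/` run the whole study and write their
tables under `results/`:

```
python analysis/01_simulate.py          # family + truth + reads
python analysis/02_classify_loci.py     # active/pseudogene calls
python analysis/03_quantify_expression.py
python analysis/04_date_duplications.py
python analysis/05_characterize_repeats.py
```

`04_date_duplications.py` prints, for the default simulated family:

```
dating arithmetic check: 0.0443/0.1517 x 19.6 = 5.72 Mya

recovery over 20 replicate families: mean estimate 12.73 Mya vs mean true
deepest split 11.61 Mya (ratio 1.096)
```

The first line is the headline dating arithmetic: a family whose most
distant active locus reaches Ks 0.0443 while the interspecies mean is
0.1517, under a 19.6 Mya calibration, has been amplifying for about
5.7 My.  The second line shows the whole pipeline (simulate → extract
active gap-free CDS → Ks matrix → calibrated ratio) recovering the true
oldest duplication of replicate families to within ~10%.

`03_quantify_expression.py` prints, for a 40-locus family with levels
spanning up to 60-fold and 10,000 read pairs at 0.1% error:

```
  A-like: Spearman(normalised A, truth) = 0.949
  B-like: Spearman(normalised A, truth) = 0.988
```

i.e. the unique-pair counting recovers the simulated per-locus levels
almost perfectly, and the measured family-mean ratio (~0.18) reflects the
one-sixth scaling of the second family.  The same script also quantifies
the genealogical family, where recently duplicated near-identical copies
attract almost no uniquely assignable pairs — the intrinsic limit of
36 bp reads on fresh duplicates.

The same machinery is available as one executable:

```
amplicony all --seed 1 --outdir runs/demo
```

with subcommands `simulate / annotate / quantify / evolve / repeats / all`
and flags `--config` (YAML overriding any default) and `--seed`.

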