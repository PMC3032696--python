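"""Stage drivers tying the modules into one reproducible run.

Each stage reads its inputs from and writes its outputs to a run
directory, records a config snapshot plus per-stage summaries in
``run.log``, and is deterministic given (config, seed): rerunning with
the same seed gives byte-identical tabular outputs.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import evolution, expression, genes, repeats, simulate
from .config import RunConfig
from .io import (
    SequenceRecord,
    parse_read_pairs,
    parse_sequences,
    write_features,
    write_read_pairs,
    write_sequences,
)

log = logging.getLogger("amplicony")

STAGES = ("simulate", "annotate", "quantify", "evolve", "repeats", "all")


def _setup(config: RunConfig, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    logfile = str((outdir / "run.log").resolve())
    if not any(
        isinstance(h, logging.FileHandler) and h.baseFilename == logfile
        for h in log.handlers
    ):
        handler = logging.FileHandler(logfile)
        handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("config: %s", asdict(config))
    return outdir


def run_simulate(
    config: RunConfig,
    outdir: str | Path,
    params: simulate.FamilyParams | None = None,
    n_pairs: int = 20000,
    error_rate: float = 0.001,
) -> None:
    """Generate the family, expression levels, reads, and amplicon contig."""
    outdir = _setup(config, outdir)
    params = params or simulate.FamilyParams(seed=config.seed)
    truth, records = simulate.simulate_family(params)
    simulate.assign_expression(truth, seed=config.seed + 1)
    transcripts = simulate.transcripts_from_family(truth, records)
    pairs, sources = simulate.simulate_read_pairs(
        transcripts, truth, n_pairs, error_rate, config, seed=config.seed + 2
    )

    write_sequences(records, outdir / "loci.fasta")
    write_sequences(transcripts, outdir / "transcripts.fasta")
    write_read_pairs(pairs, outdir / "reads_1.fastq", outdir / "reads_2.fastq")
    sources.to_csv(outdir / "truth_read_sources.tsv", sep="\t", index=False)

    rows = []
    for t in truth:
        rows.append({
            "locus_id": t.locus_id,
            "parent_id": t.parent_id or "",
            "birth_time": round(t.birth_time, 6),
            "family": t.family,
            "n_indels": len(t.indel_events),
            "cds_indels": sum(bool(ev[3]) for ev in t.indel_events),
            "is_active": t.is_active,
            "expression_level": round(t.expression_level, 6),
            "intron_start": t.model.intron_start,
            "intron_end": t.model.intron_end,
            "cds_offset_in_exon2": t.model.cds_offset_in_exon2,
            "cds_start": t.cds_start,
            "cds_end": t.cds_end,
        })
    pd.DataFrame(rows).to_csv(outdir / "truth_loci.tsv", sep="\t", index=False)

    # reference CDS records (ancestral genes, re-derived from the seed)
    block = params.ancestral_block or simulate.make_ancestral_block(
        seed=np.random.default_rng(params.seed).integers(2**31)
    )
    refs = []
    for tag, gene in zip("BA", block):
        cds = gene.record.sequence[gene.cds_start : gene.cds_end]
        refs.append(SequenceRecord(f"reference_{tag}", cds))
    write_sequences(refs, outdir / "reference_cds.fasta")

    # small ampliconic contig: two blocks, one repeated forward (DR) and
    # once reverse-complemented (IR)
    spacer = 500
    block_seqs = []
    by_id = {r.id: r.sequence for r in records}
    for bid in sorted({t.locus_id[1:] for t in truth})[:2]:
        if f"B{bid}" in by_id and f"A{bid}" in by_id:
            block_seqs.append(SequenceRecord(
                f"unit{bid}",
                by_id[f"B{bid}"]
                + simulate.random_dna(spacer, config.seed + 3)
                + by_id[f"A{bid}"],
            ))
    if block_seqs:
        u0 = block_seqs[0].id
        order = [(u0, "forward")]
        if len(block_seqs) > 1:
            order.append((block_seqs[1].id, "forward"))
        order += [(u0, "forward"), (u0, "revcomp")]
        plan = simulate.AmpliconPlan(order, [800] * (len(order) + 1))
        contig, feats = simulate.layout_amplicon(
            block_seqs, plan, seed=config.seed + 4
        )
        write_sequences([contig], outdir / "amplicon.fasta")
        write_features(feats, outdir / "amplicon.gff3", "gff3")

    n_active = sum(t.is_active for t in truth)
    log.info(
        "simulate: %d loci (%d active), %d read pairs",
        len(truth), n_active, len(pairs),
    )


def _load_truth(outdir: Path) -> pd.DataFrame:
    return pd.read_csv(outdir / "truth_loci.tsv", sep="\t")


def run_annotate(config: RunConfig, outdir: str | Path) -> pd.DataFrame:
    """Assess every locus transcript against its family reference CDS."""
    outdir = _setup(config, outdir)
    truth = _load_truth(outdir)
    loci = {r.id: r for r in parse_sequences(outdir / "loci.fasta")}
    refs = {r.id: r for r in parse_sequences(outdir / "reference_cds.fasta")}
    thresholds = genes.ClassifierThresholds(
        config.active_min_aa, config.active_min_fraction
    )
    rows = []
    for row in truth.itertuples():
        model = genes.GeneModel(
            intron_start=int(row.intron_start),
            intron_end=int(row.intron_end),
            cds_offset_in_exon2=int(row.cds_offset_in_exon2),
        )
        ref = refs[f"reference_{row.family[0]}"]
        transcript, splice_ok = genes.splice_transcript(
            loci[row.locus_id].sequence, model
        )
        assessment = genes.assess_coding(
            transcript, ref.sequence, model, locus_id=row.locus_id
        )
        ref_aa = len(ref.sequence) // 3 - 1
        status = genes.classify_locus(assessment, ref_aa, thresholds)
        rows.append({
            "locus_id": row.locus_id,
            "family": row.family,
            "splice_consensus": splice_ok,
            "n_indels": len(assessment.indels),
            "frameshift": assessment.frameshift,
            "premature_stop_start": assessment.premature_stop_start or "",
            "peptide_aa": assessment.peptide_aa,
            "structural_type": assessment.structural_type,
            "status": status,
            "truth_active": bool(row.is_active),
        })
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "assessments.tsv", sep="\t", index=False)
    agree = (
        (table.status == "active") == table.truth_active
    ).mean()
    log.info(
        "annotate: %d loci, %d active calls, %.1f%% agreement with truth",
        len(table), (table.status == "active").sum(), 100 * agree,
    )
    return table


def run_quantify(config: RunConfig, outdir: str | Path) -> pd.DataFrame:
    """Collapse, align, count and normalise locus-specific expression."""
    outdir = _setup(config, outdir)
    transcripts = parse_sequences(outdir / "transcripts.fasta")
    pairs = parse_read_pairs(outdir / "reads_1.fastq", outdir / "reads_2.fastq")
    truth = _load_truth(outdir)
    family_map = dict(zip(truth.locus_id, truth.family))
    table = expression.quantify(transcripts, pairs, config, family_map)
    table.to_csv(outdir / "counts.tsv", sep="\t", index=False)
    levels = dict(zip(truth.locus_id, truth.expression_level))
    summary = expression.summarize_expression(table, truth_levels=levels)
    summary.to_csv(outdir / "expression_summary.tsv", sep="\t", index=False)
    log.info(
        "quantify: %d unique references, %d pairs counted (category A)",
        len(table), int(table.countA.sum()),
    )
    return table


def run_evolve(
    config: RunConfig,
    outdir: str | Path,
    max_tree_taxa: int = 15,
    max_ks_taxa: int = 30,
    params: simulate.FamilyParams | None = None,
) -> dict:
    """Ks matrix of active main-family loci, duplication age, NJ tree."""
    outdir = _setup(config, outdir)
    truth = _load_truth(outdir)
    loci = {r.id: r for r in parse_sequences(outdir / "loci.fasta")}
    params = params or simulate.FamilyParams(seed=config.seed)

    # gap-free codon alignment: active loci whose CDS carries no indel
    active = truth[
        (truth.family == "B-like") & truth.is_active & (truth.cds_indels == 0)
    ]
    cds = {
        row.locus_id: loci[row.locus_id].sequence[row.cds_start : row.cds_end]
        for row in active.itertuples()
    }
    lengths = pd.Series({k: len(v) for k, v in cds.items()})
    modal = lengths.mode().iloc[0]
    taxa = sorted(k for k in cds if len(cds[k]) == modal)
    if len(taxa) < 3:
        raise ValueError("need >=3 comparable active loci for the Ks stage")
    if len(taxa) > max_ks_taxa:  # evenly spaced subsample, deterministic
        step = len(taxa) / max_ks_taxa
        taxa = [taxa[int(k * step)] for k in range(max_ks_taxa)]
    aln = evolution.CodonAlignment(taxa, [cds[k] for k in taxa])
    matrix = evolution.ks_matrix(aln)
    pd.DataFrame(matrix.values, index=taxa, columns=taxa).to_csv(
        outdir / "ks_matrix.tsv", sep="\t"
    )
    summary = evolution.ks_summary(matrix)

    # interspecies calibration against a simulated sister-species ortholog
    block = params.ancestral_block or simulate.make_ancestral_block(
        seed=np.random.default_rng(params.seed).integers(2**31)
    )
    out_cds = simulate.simulate_outgroup_cds(block[0], params,
                                             seed=config.seed + 5)
    inter = [
        evolution.ng_pair(out_cds, cds[t]).dS
        for t in taxa
        if len(out_cds) == len(cds[t])
    ]
    inter = [d for d in inter if d is not None]
    age = None
    if inter:
        mean_inter = float(np.mean(inter))
        age = evolution.estimate_duplication_age(
            summary["most_distant_max_ks"], mean_inter, config.calibration_time
        )
        summary["interspecies_ks_mean"] = mean_inter
        summary["duplication_age_mya"] = age
    pd.DataFrame([summary]).to_csv(outdir / "ks_summary.tsv", sep="\t",
                                   index=False)

    tree_taxa = taxa[:max_tree_taxa]
    sub = evolution.CodonAlignment(tree_taxa, [cds[k] for k in tree_taxa])
    tree, boot_log = evolution.bootstrap_support(
        sub, n_reps=config.bootstrap_reps, seed=config.seed, distance="jc"
    )
    (outdir / "tree.nwk").write_text(tree.newick() + "\n")
    log.info(
        "evolve: %d taxa, mean Ks %.4f, max Ks %.4f, age %s Mya, "
        "bootstrap %s",
        len(taxa), summary["mean_ks"], summary["max_ks"],
        f"{age:.2f}" if age is not None else "n/a", boot_log,
    )
    return summary


def run_repeats(config: RunConfig, outdir: str | Path) -> pd.DataFrame:
    """Dot-plot the amplicon contig, call DR/IR arms, demo assembly."""
    outdir = _setup(config, outdir)
    contig = parse_sequences(outdir / "amplicon.fasta")[0]
    matches = repeats.dotplot_matches(
        contig.sequence, contig.sequence, w=config.dotplot_word
    )
    pairs = repeats.detect_arm_pairs(
        matches, w=config.dotplot_word, min_arm=2000, max_gap=500
    )
    repeats.annotate_identities(contig.sequence, pairs)
    rows = [{
        "armA_start": p.arm_a[0], "armA_end": p.arm_a[1],
        "armB_start": p.arm_b[0], "armB_end": p.arm_b[1],
        "orientation": p.orientation,
        "identity": round(p.identity, 2) if p.identity is not None else "",
        "tier": repeats.classify_tier(p) or "",
    } for p in pairs]
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "repeat_pairs.tsv", sep="\t", index=False)

    overlap = min(config.assembly_min_overlap, max(1000, len(contig) // 5))
    tiles = simulate.tile_sequence(contig.sequence, 4, overlap)
    contigs, edges = repeats.assemble_overlaps(
        tiles, min_overlap=overlap, min_identity=config.assembly_min_identity
    )
    reassembled = max(contigs, key=lambda c: len(c.sequence))
    ok = reassembled.sequence == contig.sequence
    pd.DataFrame([{
        "members": ",".join(m[0] for m in c.members),
        "length": len(c.sequence),
    } for c in contigs]).to_csv(outdir / "assembly_layout.tsv", sep="\t",
                                index=False)
    log.info(
        "repeats: %d arm pairs (%d DR, %d IR); tiling reassembly %s",
        len(pairs),
        sum(p.orientation == "DR" for p in pairs),
        sum(p.orientation == "IR" for p in pairs),
        "exact" if ok else "FAILED",
    )
    return table


def run_pipeline(
    config: RunConfig, subcommand: str, outdir: str | Path, **kwargs
) -> None:
    """Dispatch one stage (or all of them in order)."""
    if subcommand not in STAGES:
        raise ValueError(
            f"unknown subcommand {subcommand!r}; choose from {STAGES}"
        )
    if subcommand in ("simulate", "all"):
        run_simulate(config, outdir, **kwargs)
    if subcommand in ("annotate", "all"):
        run_annotate(config, outdir)
    if subcommand in ("quantify", "all"):
        run_quantify(config, outdir)
    if subcommand in ("evolve", "all"):
        run_evolve(config, outdir)
    if subcommand in ("repeats", "all"):
        run_repeats(config, outdir)
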