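"""End-to-end screen orchestration.

Stages run in order: simulate (optional) -> junction detection -> RPM
quantification + differential expression -> circORF annotation -> pathway
GSEA -> prioritisation.  Every intermediate is written to the output
directory in plain-text formats, and a machine-readable JSON report with
per-stage summaries and provenance (config hash, seed, version) closes the
run.  Re-running into a non-empty directory refuses unless forced, so runs
never mix silently.

A single global seed is fanned out to stage-specific child seeds via
``numpy.random.SeedSequence([seed, stage_index])`` (documented, stable
derivation), keeping stages independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .config import ScreenConfig
from .detect import run_detection, DetectionResult
from .errors import StageError
from .expression import rpm_scale, fpkm_scale, de_test, ExpressionMatrix
from .gsea import GeneSet, pearson_profile, gsea_permutation, prioritize
from .orfs import CircSequence, enumerate_rolling_orfs, best_junction_orf, OrfScreenRecord
from .synthetic import (SimulationTruth, GenomeRef, build_demo, match_junction_to_exons,
                        write_gff3, read_gff3)
from . import io as cio

STAGE_SEED = {"simulate": 0, "detect": 1, "de": 2, "orfs": 3, "gsea": 4}


def child_seed(seed: int, stage: str, extra: int = 0) -> int:
    """Stable per-stage child seed below 2^31."""
    ss = np.random.SeedSequence([seed, STAGE_SEED[stage], extra])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class ScreenReport:
    seed: int
    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)
    candidate_table: list = field(default_factory=list)
    hits: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True, default=str)
            fh.write("\n")


def _config_hash(config: ScreenConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _candidate_name(junction) -> str:
    return f"{junction.chrom}:{junction.acceptor_pos}-{junction.donor_pos}:{junction.strand}"


def circ_sequence_for_candidate(junction, genes, genome: GenomeRef) -> str:
    """Spliced circle sequence for a called junction.

    Uses the annotation when the junction matches exon boundaries of a
    gene (concatenating the exon block in transcript order); otherwise
    falls back to the genomic span, oriented to the junction strand.
    """
    blk = match_junction_to_exons(genes, junction.chrom, junction.strand,
                                  junction.acceptor_pos, junction.donor_pos)
    if blk is not None:
        gene, i, j = blk
        return "".join(gene.exon_sequence(genome, k) for k in range(i, j + 1))
    seq = genome.fetch(junction.chrom, junction.acceptor_pos, junction.donor_pos)
    if junction.strand == "-":
        from .seqtools import revcomp
        seq = revcomp(seq)
    return seq


def run_screen(config: ScreenConfig, outdir: str | os.PathLike,
               force: bool = False) -> ScreenReport:
    """Run the full screen and write all artefacts under ``outdir``."""
    outdir = str(outdir)
    if os.path.isdir(outdir) and os.listdir(outdir) and not force:
        raise StageError(f"output directory {outdir} is not empty; pass force to overwrite")
    os.makedirs(outdir, exist_ok=True)
    report = ScreenReport(config.seed, _config_hash(config), __version__)

    # ---------------------------------------------------------- inputs
    if config.simulate is not None:
        sim = config.simulate
        demo = build_demo(seed=child_seed(config.seed, "simulate"),
                          n_chrom=sim.n_chrom, chrom_length=sim.chrom_length,
                          gc=sim.gc, n_genes=sim.n_genes, n_decoys=sim.n_decoys,
                          n_long_orf_upregulated=sim.n_long_orf_upregulated,
                          n_pairs=sim.n_pairs, read_len=sim.read_len,
                          depth=sim.depth, err=sim.err,
                          positive_lfc=sim.positive_lfc, nk_set_size=sim.nk_set_size,
                          target_r=sim.target_r, corr_noise_sd=sim.corr_noise_sd,
                          n_expr_genes=sim.n_expr_genes)
        genome, truth = demo.genome, demo.truth
        genes = truth.genes
        sample_reads = demo.readsim.reads
        gene_matrix, gene_lengths = demo.gene_matrix, demo.gene_lengths
        gene_sets = demo.gene_sets
        pathway_name = config.gsea.pathway or demo.pathway
        cio.write_fasta(genome.chroms, os.path.join(outdir, "genome.fa"))
        write_gff3(genes, os.path.join(outdir, "genes.gff3"))
        truth.to_json(os.path.join(outdir, "truth.json"))
        demo.readsim.write_fastq_dir(os.path.join(outdir, "reads"))
        cio.write_bed6(
            [(c.chrom, c.acceptor_pos, c.donor_pos, c.circ_id,
              sum(demo.readsim.junction_counts[c.circ_id].values()), c.strand)
             for c in truth.circs],
            os.path.join(outdir, "planted_junctions.bed"))
        gene_matrix.to_tsv(os.path.join(outdir, "gene_counts.tsv"))
        cio.write_tsv(gene_lengths.rename("length").to_frame(),
                      os.path.join(outdir, "gene_lengths.tsv"))
        cio.write_gmt(gene_sets, os.path.join(outdir, "gene_sets.gmt"))
        report.stages["simulate"] = {
            "n_genes": len(genes), "n_circles": len(truth.circs),
            "n_samples": len(truth.samples),
            "reads_per_sample": sim.depth,
        }
        catalogue = None
    else:
        p = config.paths
        genome = GenomeRef(cio.read_fasta(p.genome_fasta))
        genes = read_gff3(p.annotation_gff) if p.annotation_gff else []
        sample_reads = {s: list(cio.read_fastq(path)) for s, path in sorted(p.reads.items())}
        gene_matrix = ExpressionMatrix.from_tsv(p.gene_matrix, "count") if p.gene_matrix else None
        gene_lengths = (cio.read_tsv(p.gene_lengths)["length"]
                        if p.gene_lengths else None)
        gene_sets = cio.read_gmt(p.gene_sets_gmt) if p.gene_sets_gmt else {}
        pathway_name = config.gsea.pathway or (next(iter(gene_sets)) if gene_sets else None)
        catalogue = None
        if p.junction_catalogue_bed:
            bed = cio.read_bed(p.junction_catalogue_bed)
            catalogue = {(r.chrom, r.strand, int(r.start), int(r.end))
                         for r in bed.itertuples()}
        truth = None

    # ---------------------------------------------------------- detect
    transcripts = {g.gene_id: g.spliced_sequence(genome) for g in genes}
    det: DetectionResult = run_detection(
        sample_reads, genome.chroms, transcripts,
        k=config.detect.anchor_k, m=config.detect.mismatches,
        span_cap=config.detect.span_cap, min_unique=config.detect.min_unique,
        catalogue=catalogue)
    support = det.support_matrix()
    cio.write_bed6(
        [(c.junction.chrom, c.junction.acceptor_pos, c.junction.donor_pos,
          _candidate_name(c.junction), c.total_support, c.junction.strand)
         for c in det.candidates],
        os.path.join(outdir, "candidates.bed"))
    cio.write_tsv(support, os.path.join(outdir, "junction_support.tsv"),
                  comments=["unit: distinct back-spliced reads per sample"])
    report.stages["detect"] = {
        "n_candidates": len(det.candidates),
        "mapped_totals": det.mapped_totals,
        "min_unique": config.detect.min_unique,
    }

    # ----------------------------------------------- quantify + DE
    if not det.candidates:
        report.stages["de"] = {"note": "no candidates called"}
        report.to_json(os.path.join(outdir, "report.json"))
        cio.write_tsv(pd.DataFrame(), os.path.join(outdir, "candidates_final.tsv"))
        return report
    rpm = rpm_scale(support, det.mapped_totals)
    rpm.to_tsv(os.path.join(outdir, "circ_rpm.tsv"))
    groups = {s: ("tumour" if s.startswith("T") else "normal") for s in rpm.samples}
    de = de_test(rpm, groups, paired=config.de.paired,
                 pseudocount=config.de.pseudocount, lfc_cut=config.de.lfc_cut,
                 p_cut=config.de.p_cut, adjust=config.de.adjust)
    cio.write_tsv(de, os.path.join(outdir, "circ_de.tsv"),
                  comments=[de.attrs.get("test", "")])
    report.stages["de"] = {
        "n_tested": int(len(de)),
        "n_up": int((de["call"] == "up").sum()),
        "n_down": int((de["call"] == "down").sum()),
        "thresholds": {"lfc_cut": config.de.lfc_cut, "p_cut": config.de.p_cut,
                       "adjusted": config.de.adjust},
    }

    # ---------------------------------------------------------- ORFs
    orf_records: dict[str, OrfScreenRecord] = {}
    orf_rows = []
    up_set = set(de.index[de["call"] == "up"])
    for cand in det.candidates:
        name = _candidate_name(cand.junction)
        seq = circ_sequence_for_candidate(cand.junction, genes, genome)
        orfs = enumerate_rolling_orfs(CircSequence(seq, name),
                                      max_passes=config.orfs.max_passes)
        best = best_junction_orf(orfs)
        rec = OrfScreenRecord(name, best, upregulated=name in up_set)
        orf_records[name] = rec
        if best is not None:
            orf_rows.append({"circ_id": name, "circ_nt": len(seq),
                             "start_offset": best.start_offset,
                             "nt_length": best.nt_length, "aa_length": best.aa_length,
                             "passes": best.passes,
                             "spans_junction": best.spans_junction,
                             "exceeds_360": best.exceeds_360,
                             "peptide": best.peptide,
                             "unique_cterm": best.unique_cterm})
    cio.write_tsv(pd.DataFrame(orf_rows).set_index("circ_id") if orf_rows else pd.DataFrame(),
                  os.path.join(outdir, "circ_orfs.tsv"))
    n_short = sum(1 for r in orf_records.values()
                  if r.spans_junction and r.best_orf.aa_length < config.orfs.max_aa)
    report.stages["orfs"] = {
        "n_with_junction_orf": sum(1 for r in orf_records.values() if r.spans_junction),
        "n_short": n_short, "max_aa": config.orfs.max_aa,
    }

    # ---------------------------------------------------------- GSEA
    gsea_results = {}
    if gene_matrix is not None and pathway_name:
        members = tuple(gene_sets[pathway_name])
        pathway = GeneSet(pathway_name, members, provenance="config")
        totals = gene_matrix.values.sum(axis=0)
        fpkm = fpkm_scale(gene_matrix, gene_lengths, totals)
        screen_circs = sorted(
            name for name, rec in orf_records.items()
            if rec.upregulated and rec.spans_junction
            and rec.best_orf.aa_length < config.orfs.max_aa)
        for idx, name in enumerate(screen_circs):
            ranked = pearson_profile(rpm.values.loc[name], fpkm)
            gsea_results[name] = gsea_permutation(
                ranked, pathway, n_perm=config.gsea.n_perm,
                weight=config.gsea.weight,
                seed=child_seed(config.seed, "gsea", idx))
        report.stages["gsea"] = {
            "pathway": pathway_name, "n_tested": len(gsea_results),
            "n_perm": config.gsea.n_perm, "weight": config.gsea.weight,
            "null": "gene-set permutation (random same-size sets)",
        }
    else:
        pathway = None
        report.stages["gsea"] = {"note": "no gene matrix or pathway provided"}

    # ---------------------------------------------------- prioritise
    if pathway is not None:
        table = prioritize(de, orf_records, gsea_results, pathway,
                           gsea_p_cut=config.gsea.p_cut)
    else:
        table = pd.DataFrame(columns=["circ_id", "log2fc", "de_pvalue", "orf_aa",
                                      "es", "nes", "gsea_p", "pathway", "hit"])
    cio.write_tsv(table, os.path.join(outdir, "candidates_final.tsv"), index=False)
    report.candidate_table = table.to_dict(orient="records")
    report.hits = list(table.loc[table["hit"], "circ_id"]) if len(table) else []
    if truth is not None:
        pos = truth.circ_by_id("circ_pos") if any(
            c.circ_id == "circ_pos" for c in truth.circs) else None
        if pos is not None:
            report.stages["truth"] = {"planted_positive": _candidate_name_from_key(pos)}
    report.to_json(os.path.join(outdir, "report.json"))
    return report


def _candidate_name_from_key(circ) -> str:
    return f"{circ.chrom}:{circ.acceptor_pos}-{circ.donor_pos}:{circ.strand}"
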