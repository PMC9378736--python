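"""Synthetic dataset generator with known ground truth.

Builds a toy genome carrying multi-exon genes whose exon boundaries are
flanked by canonical GT/AG splice dinucleotides (on the template strand),
plants circular RNAs made by backsplicing contiguous exon blocks, simulates
single-end reads from both linear transcripts and rolling circular
templates, and simulates paired tumour/normal expression matrices with
planted fold changes and gene sets correlated with a chosen circRNA's
abundance.  Every generator is byte-reproducible given (parameters, seed).

Coordinates are 0-based half-open throughout.  A backsplice junction is
recorded as ``(acceptor_pos, donor_pos)`` with ``acceptor_pos < donor_pos``
on the genome; the circular sequence starts at the acceptor-side base
(junction at offset 0).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ParameterError, CapacityError
from .expression import ExpressionMatrix
from .seqtools import revcomp

BASES = "ACGT"


# ======================================================================
# Domain types
# ======================================================================

@dataclass
class GenomeRef:
    """Named chromosome sequences (alphabet ACGT)."""

    chroms: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.chroms) == 0:
            raise ParameterError("genome must contain at least one chromosome")
        for name, seq in self.chroms.items():
            if not seq:
                raise ParameterError(f"chromosome {name!r} is empty")

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.chroms[chrom][start:end]


@dataclass
class GeneModel:
    """A gene: ordered exons (transcript order, 5'->3') on one chromosome.

    For + strand genes transcript order equals genomic order; for - strand
    genes exons are stored in descending genomic order.  Intervals are
    0-based half-open on the forward genome strand.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    is_coding: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ParameterError(f"{self.gene_id}: strand must be + or -")
        if any(not (0 <= s < e) for s, e in self.exons):
            raise ParameterError(f"{self.gene_id}: exon interval out of range")
        ivs = sorted(self.exons)
        if any(a[1] > b[0] for a, b in zip(ivs, ivs[1:])):
            raise ParameterError(f"{self.gene_id}: overlapping exons")
        genomic = sorted(self.exons) if self.strand == "+" else sorted(self.exons, reverse=True)
        if list(self.exons) != genomic:
            raise ParameterError(f"{self.gene_id}: exons not in transcript order for strand {self.strand}")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)

    def exon_sequence(self, genome: GenomeRef, i: int) -> str:
        s, e = self.exons[i]
        seq = genome.fetch(self.chrom, s, e)
        return seq if self.strand == "+" else revcomp(seq)

    def spliced_sequence(self, genome: GenomeRef) -> str:
        return "".join(self.exon_sequence(genome, i) for i in range(self.n_exons))

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class PlantedCirc:
    """A circRNA planted by backsplicing a contiguous exon block.

    ``sequence`` is the spliced circle starting at the acceptor-side base;
    ``acceptor_pos < donor_pos`` delimit the genomic span of the block.
    ``abundances`` maps sample name to true relative abundance.
    """

    circ_id: str
    gene_id: str
    chrom: str
    strand: str
    exon_from: int
    exon_to: int
    sequence: str
    acceptor_pos: int
    donor_pos: int
    abundances: dict[str, float]

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def junction_key(self) -> tuple[str, str, int, int]:
        return (self.chrom, self.strand, self.acceptor_pos, self.donor_pos)


@dataclass
class SimulationTruth:
    """Everything the generators planted, for recovery tests.

    Serialisable to JSON; regeneration from the same seed is byte-identical.
    """

    seed: int
    samples: list[str]
    genes: list[GeneModel]
    circs: list[PlantedCirc]
    linear_abundances: dict[str, dict[str, float]]
    de_features: dict[str, float] = field(default_factory=dict)
    corr_sets: list[dict] = field(default_factory=list)

    def circ_by_id(self, circ_id: str) -> PlantedCirc:
        return next(c for c in self.circs if c.circ_id == circ_id)

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "seed": self.seed,
            "samples": self.samples,
            "genes": [asdict(g) for g in self.genes],
            "circs": [asdict(c) for c in self.circs],
            "linear_abundances": self.linear_abundances,
            "de_features": self.de_features,
            "corr_sets": self.corr_sets,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "SimulationTruth":
        with open(path) as fh:
            d = json.load(fh)
        genes = [GeneModel(g["gene_id"], g["chrom"], g["strand"],
                           [tuple(x) for x in g["exons"]], g["is_coding"]) for g in d["genes"]]
        circs = [PlantedCirc(**{**c, "exon_from": int(c["exon_from"]), "exon_to": int(c["exon_to"])})
                 for c in d["circs"]]
        return cls(d["seed"], d["samples"], genes, circs, d["linear_abundances"],
                   d.get("de_features", {}), d.get("corr_sets", []))


# ======================================================================
# Genome and gene construction
# ======================================================================

def make_genome(n_chrom: int, chrom_length: int, gc: float, seed: int) -> GenomeRef:
    """Random genome with the requested GC content.

    Bases are drawn i.i.d. with P(G)=P(C)=gc/2, so the realised GC fraction
    of each chromosome lies within binomial noise of ``gc``.
    """
    if chrom_length < 10_000:
        raise ParameterError("chrom_length must be >= 10000")
    if not 0.0 < gc < 1.0:
        raise ParameterError("gc must be strictly between 0 and 1")
    if n_chrom < 1:
        raise ParameterError("n_chrom must be >= 1")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    base_arr = np.frombuffer(BASES.encode(), dtype=np.uint8)
    chroms = {}
    for i in range(n_chrom):
        draws = rng.choice(4, size=chrom_length, p=p)
        chroms[f"chr{i + 1}"] = base_arr[draws].tobytes().decode()
    return GenomeRef(chroms)


def _write_dinuc(buf: bytearray, pos: int, dinuc: str) -> None:
    buf[pos] = ord(dinuc[0])
    buf[pos + 1] = ord(dinuc[1])


def make_genes(genome: GenomeRef,
               n_genes: int,
               exons_per_gene: tuple[int, int] = (3, 5),
               exon_len: tuple[int, int] = (90, 260),
               seed: int = 0,
               intron_len: tuple[int, int] = (60, 160),
               spacing: int = 30) -> list[GeneModel]:
    """Place non-overlapping multi-exon genes and rewrite splice flanks.

    Every exon boundary is rewritten so the template strand reads AG
    immediately upstream of each exon and GT immediately downstream
    (GT..AG across each intron).  Terminal exons also receive outer flanks
    so any contiguous exon block can serve as a backsplice circle while
    satisfying the GT/AG flank rule used by the detector.  Mutates the
    genome in place.  Raises :class:`CapacityError` when the genes do not
    fit.
    """
    rng = np.random.default_rng(seed)
    if n_genes == 0:
        return []
    bufs = {name: bytearray(seq, "ascii") for name, seq in genome.chroms.items()}
    chrom_names = list(genome.chroms)
    cursors = {name: 10 for name in chrom_names}
    genes: list[GeneModel] = []
    ci = 0
    for gi in range(n_genes):
        n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        ex_lens = rng.integers(exon_len[0], exon_len[1] + 1, size=n_ex)
        in_lens = rng.integers(intron_len[0], intron_len[1] + 1, size=max(n_ex - 1, 0))
        strand = "+" if rng.random() < 0.5 else "-"
        span = int(ex_lens.sum() + in_lens.sum())
        placed = False
        for _ in range(len(chrom_names)):
            chrom = chrom_names[ci % len(chrom_names)]
            start = cursors[chrom]
            if start + span + spacing + 10 <= len(genome.chroms[chrom]):
                cursors[chrom] = start + span + spacing
                ci += 1
                placed = True
                break
            ci += 1
        if not placed:
            raise CapacityError(
                f"insufficient genome space: placed {gi} of {n_genes} genes")
        exons_genomic: list[tuple[int, int]] = []
        pos = start
        for k, L in enumerate(ex_lens):
            exons_genomic.append((pos, pos + int(L)))
            pos += int(L) + (int(in_lens[k]) if k < n_ex - 1 else 0)
        buf = bufs[chrom]
        for s, e in exons_genomic:
            if strand == "+":
                _write_dinuc(buf, s - 2, "AG")   # acceptor flank, template strand
                _write_dinuc(buf, e, "GT")       # donor flank
            else:
                _write_dinuc(buf, s - 2, "AC")   # revcomp(GT): donor flank on -
                _write_dinuc(buf, e, "CT")       # revcomp(AG): acceptor flank on -
        exons = exons_genomic if strand == "+" else exons_genomic[::-1]
        genes.append(GeneModel(f"g{gi + 1:04d}", chrom, strand, [tuple(x) for x in exons]))
    for name in chrom_names:
        genome.chroms[name] = bufs[name].decode()
    return genes


def make_circ(genome: GenomeRef, gene: GeneModel, exon_from: int, exon_to: int,
              abundances: dict[str, float], circ_id: str | None = None) -> PlantedCirc:
    """Backsplice a contiguous exon block of ``gene`` into a circle.

    The spliced circular sequence equals the concatenation of exons
    ``exon_from..exon_to`` in transcript order; the junction joins the end
    of ``exon_to`` back to the start of ``exon_from``.
    """
    if not (0 <= exon_from <= exon_to < gene.n_exons):
        raise ParameterError(f"exon indices out of range for {gene.gene_id}")
    seq = "".join(gene.exon_sequence(genome, i) for i in range(exon_from, exon_to + 1))
    if len(seq) < 40:
        raise ParameterError(f"circle too short ({len(seq)} nt < 40)")
    block = gene.exons[exon_from:exon_to + 1]
    if gene.strand == "+":
        acceptor, donor = block[0][0], block[-1][1]
    else:
        acceptor, donor = block[-1][0], block[0][1]
    return PlantedCirc(circ_id or f"circ_{gene.gene_id}_{exon_from}_{exon_to}",
                       gene.gene_id, gene.chrom, gene.strand, exon_from, exon_to,
                       seq, acceptor, donor, dict(abundances))


def match_junction_to_exons(genes: list[GeneModel], chrom: str, strand: str,
                    acceptor_pos: int, donor_pos: int):
    """Locate the gene and exon block matching a called junction.

    Returns ``(gene, exon_from, exon_to)`` or ``None`` when no annotated
    gene has exon boundaries at both junction ends.
    """
    for gene in genes:
        if gene.chrom != chrom or gene.strand != strand:
            continue
        if strand == "+":
            starts = {s: i for i, (s, _) in enumerate(gene.exons)}
            ends = {e: i for i, (_, e) in enumerate(gene.exons)}
            i, j = starts.get(acceptor_pos), ends.get(donor_pos)
        else:
            ends = {e: i for i, (_, e) in enumerate(gene.exons)}
            starts = {s: i for i, (s, _) in enumerate(gene.exons)}
            i, j = ends.get(donor_pos), starts.get(acceptor_pos)
        if i is not None and j is not None and i <= j:
            return gene, i, j
    return None


# ======================================================================
# Read simulation
# ======================================================================

@dataclass
class ReadSim:
    """Simulated reads plus the simulator's own junction bookkeeping."""

    reads: dict[str, list[tuple[str, str]]]          # sample -> [(name, seq)]
    junction_counts: dict[str, dict[str, int]]       # circ_id -> sample -> crossing reads
    read_len: int

    def write_fastq_dir(self, outdir: str | os.PathLike) -> dict[str, str]:
        from .io import write_fastq
        os.makedirs(outdir, exist_ok=True)
        paths = {}
        for sample, recs in self.reads.items():
            p = os.path.join(str(outdir), f"{sample}.fastq")
            write_fastq(recs, p)
            paths[sample] = p
        return paths


def _inject_errors(seqs: list[str], err: float, rng: np.random.Generator) -> list[str]:
    if err <= 0 or not seqs:
        return seqs
    out = []
    base_arr = np.frombuffer(BASES.encode(), dtype=np.uint8)
    for s in seqs:
        arr = np.frombuffer(s.encode(), dtype=np.uint8).copy()
        mask = rng.random(arr.size) < err
        n_err = int(mask.sum())
        if n_err:
            # substitute with a uniformly random *different* base
            idx = np.flatnonzero(mask)
            shift = rng.integers(1, 4, size=n_err)
            cur = np.searchsorted(base_arr, arr[idx])
            arr[idx] = base_arr[(cur + shift) % 4]
        out.append(arr.tobytes().decode())
    return out


def simulate_reads(truth: SimulationTruth, genome: GenomeRef, read_len: int = 150,
                   depth: int = 10_000, err: float = 0.0, seed: int = 0,
                   anchor_k: int = 20) -> ReadSim:
    """Draw single-end reads from linear transcripts and circular templates.

    Per sample, ``depth`` reads are allocated multinomially across
    templates in proportion to planted abundances.  Circles are treated as
    rolling templates (the circle unrolled as many times as needed), so
    reads may cross the backsplice junction; read names encode the
    ground-truth origin and start offset.  Linear transcripts shorter than
    the read length are never sampled.
    """
    if read_len < 2 * anchor_k:
        raise ParameterError(f"read_len must be >= {2 * anchor_k} (two anchors)")
    rng = np.random.default_rng(seed)
    gene_map = {g.gene_id: g for g in truth.genes}
    lin_templates = []
    for gid in sorted(truth.linear_abundances):
        seq = gene_map[gid].spliced_sequence(genome)
        if len(seq) >= read_len:
            lin_templates.append((gid, seq))
    reads: dict[str, list[tuple[str, str]]] = {}
    jcounts: dict[str, dict[str, int]] = {c.circ_id: {} for c in truth.circs}
    for sample in truth.samples:
        weights = [truth.linear_abundances[gid].get(sample, 0.0) for gid, _ in lin_templates]
        weights += [c.abundances.get(sample, 0.0) for c in truth.circs]
        w = np.asarray(weights, dtype=float)
        recs: list[tuple[str, str]] = []
        if depth > 0 and w.sum() > 0:
            counts = rng.multinomial(depth, w / w.sum())
        else:
            counts = np.zeros(len(w), dtype=int)
        serial = 0
        # linear templates
        for (gid, seq), n in zip(lin_templates, counts[:len(lin_templates)]):
            if n == 0:
                continue
            starts = rng.integers(0, len(seq) - read_len + 1, size=n)
            seqs = [seq[s:s + read_len] for s in starts]
            seqs = _inject_errors(seqs, err, rng)
            for s, rseq in zip(starts, seqs):
                recs.append((f"{sample}|lin|{gid}|{int(s)}|{serial}", rseq))
                serial += 1
        # circular templates (rolling)
        for circ, n in zip(truth.circs, counts[len(lin_templates):]):
            sc = jcounts[circ.circ_id]
            sc[sample] = 0
            if n == 0:
                continue
            L = circ.length
            unrolled = circ.sequence * (read_len // L + 2)
            starts = rng.integers(0, L, size=n)
            seqs = [unrolled[s:s + read_len] for s in starts]
            seqs = _inject_errors(seqs, err, rng)
            for s, rseq in zip(starts, seqs):
                crossing = int(s) + read_len > L
                sc[sample] += int(crossing)
                recs.append((f"{sample}|circ|{circ.circ_id}|{int(s)}|{serial}", rseq))
                serial += 1
        reads[sample] = recs
    return ReadSim(reads, jcounts, read_len)


def crossing_counts_from_names(reads: dict[str, list[tuple[str, str]]],
                               truth: SimulationTruth, read_len: int) -> dict[str, dict[str, int]]:
    """Recompute per-circle junction-crossing read counts from read names."""
    lens = {c.circ_id: c.length for c in truth.circs}
    out: dict[str, dict[str, int]] = {c.circ_id: {s: 0 for s in reads} for c in truth.circs}
    for sample, recs in reads.items():
        for name, _ in recs:
            smp, kind, origin, start, _serial = name.split("|")
            if kind == "circ" and int(start) + read_len > lens[origin]:
                out[origin][sample] += 1
    return out


# ======================================================================
# Expression simulation
# ======================================================================

def simulate_expression(n_genes: int,
                        n_samples: int,
                        circ_profile,
                        corr_set: list[str] | None = None,
                        target_r: float = 0.0,
                        noise_sd: float = 0.0,
                        de_spec: dict[str, float] | None = None,
                        seed: int = 0,
                        baseline_log2: tuple[float, float] = (7.0, 1.2),
                        pair_sd: float = 0.3,
                        sample_sd: float = 0.25) -> tuple[ExpressionMatrix, pd.Series, dict]:
    """Gene expression matrix with planted correlation and fold changes.

    Samples form ``n_samples/2`` tumour/normal pairs (T01..,N01..).  Genes
    in ``corr_set`` are generated as ``a * circ_profile + noise`` with
    ``sign(a) = sign(target_r)`` and |a| calibrated so the expected sample
    Pearson r equals ``target_r`` (exactly +-1 when ``noise_sd`` is 0 and
    |target_r| is 1; exactly +-1 in the noise_sd -> 0 limit).  Each
    correlated gene is shifted additively to be nonnegative, which leaves
    Pearson r unchanged.  Other genes follow a log-normal baseline with a
    shared within-pair effect; features in ``de_spec`` get the stated
    log2 fold change added to tumour samples.

    Returns ``(gene matrix, circ abundance vector, truth dict)``.
    """
    if n_samples < 4:
        raise ParameterError("n_samples must be >= 4")
    if n_samples % 2:
        raise ParameterError("n_samples must be even (paired tumour/normal design)")
    if abs(target_r) > 1:
        raise ParameterError("|target_r| must be <= 1")
    circ = np.asarray(circ_profile, dtype=float)
    if circ.size != n_samples:
        raise ParameterError("circ_profile length must equal n_samples")
    if np.ptp(circ) == 0:
        raise ParameterError("circ_profile is constant: correlation undefined")
    n_pairs = n_samples // 2
    samples = [f"T{i + 1:02d}" for i in range(n_pairs)] + [f"N{i + 1:02d}" for i in range(n_pairs)]
    gene_ids = [f"g{i + 1:04d}" for i in range(n_genes)]
    corr_set = list(corr_set or [])
    de_spec = dict(de_spec or {})
    for gid in corr_set + list(de_spec):
        if gid not in set(gene_ids):
            raise ParameterError(f"unknown gene id {gid!r}")

    rng = np.random.default_rng(seed)
    base = rng.normal(baseline_log2[0], baseline_log2[1], size=n_genes)
    pair_eff = rng.normal(0.0, pair_sd, size=(n_genes, n_pairs))
    noise = rng.normal(0.0, sample_sd, size=(n_genes, n_samples))
    logx = base[:, None] + np.hstack([pair_eff, pair_eff]) + noise
    for gid, lfc in de_spec.items():
        logx[gene_ids.index(gid), :n_pairs] += lfc
    vals = np.power(2.0, logx)

    sd_c = circ.std(ddof=1)
    for gid in corr_set:
        gi = gene_ids.index(gid)
        eps = rng.normal(0.0, 1.0, size=n_samples)
        if noise_sd == 0.0 or abs(target_r) == 1.0:
            v = np.sign(target_r) * circ if target_r != 0 else noise_sd * eps
        else:
            a = target_r / np.sqrt(1.0 - target_r ** 2) * noise_sd / sd_c
            v = a * circ + noise_sd * eps
        if v.min() < 0:
            v = v - v.min()
        vals[gi] = v

    matrix = ExpressionMatrix(pd.DataFrame(vals, index=gene_ids, columns=samples), "count")
    truth = {
        "samples": samples,
        "groups": {s: ("tumour" if s.startswith("T") else "normal") for s in samples},
        "corr_set": corr_set,
        "target_r": target_r,
        "noise_sd": noise_sd,
        "de_spec": de_spec,
        "seed": seed,
    }
    return matrix, pd.Series(circ, index=samples, name="circ"), truth


# ======================================================================
# Demo dataset (the full screen's study conditions)
# ======================================================================

@dataclass
class DemoDataset:
    genome: GenomeRef
    truth: SimulationTruth
    readsim: ReadSim
    gene_matrix: ExpressionMatrix
    gene_lengths: pd.Series
    gene_sets: dict[str, list[str]]
    pathway: str
    positive_circ: str


def _best_junction_aa(sequence: str) -> int | None:
    """aa length of the longest junction-spanning rolling ORF, or None."""
    from .orfs import CircSequence, enumerate_rolling_orfs, best_junction_orf
    orfs = enumerate_rolling_orfs(CircSequence(sequence, "tmp"))
    best = best_junction_orf(orfs)
    return None if best is None else best.aa_length


def build_demo(seed: int = 0,
               n_chrom: int = 3,
               chrom_length: int = 120_000,
               gc: float = 0.45,
               n_genes: int = 210,
               n_decoys: int = 200,
               n_long_orf_upregulated: int = 2,
               n_pairs: int = 6,
               read_len: int = 150,
               depth: int = 28_000,
               err: float = 0.002,
               positive_lfc: float = 2.0,
               nk_set_size: int = 27,
               target_r: float = -0.6,
               corr_noise_sd: float = 0.3,
               n_expr_genes: int = 1000) -> DemoDataset:
    """Generate the full screening dataset with one planted positive.

    One circle is upregulated (log2FC ``positive_lfc``), carries a
    junction-spanning ORF shorter than 100 aa, and anti-correlates with a
    planted NK-like marker gene set; ``n_decoys`` background circles have
    no planted differential expression; a couple of upregulated decoys are
    chosen (by rejection sampling) to lack any junction-spanning ORF under
    100 aa, so they fall to the ORF length screen.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(6)]
    genome = make_genome(n_chrom, chrom_length, gc, seeds[0])
    genes = make_genes(genome, n_genes, seed=seeds[1])
    rng = np.random.default_rng(seeds[2])
    samples = [f"T{i + 1:02d}" for i in range(n_pairs)] + [f"N{i + 1:02d}" for i in range(n_pairs)]

    def random_block(min_len=180, max_len=450):
        gene = genes[int(rng.integers(len(genes)))]
        i = int(rng.integers(gene.n_exons))
        j = int(rng.integers(i, gene.n_exons))
        block_len = sum(e - s for s, e in gene.exons[i:j + 1])
        if not min_len <= block_len <= max_len:
            return None
        return gene, i, j

    used: set[tuple[str, int, int]] = set()

    def draw_block(accept, tries=4000):
        for _ in range(tries):
            blk = random_block()
            if blk is None:
                continue
            gene, i, j = blk
            key = (gene.gene_id, i, j)
            if key in used:
                continue
            if accept(gene, i, j):
                used.add(key)
                return gene, i, j
        raise CapacityError("could not draw a qualifying exon block")

    # positive: carries a junction-spanning ORF under 100 aa (small-peptide candidate)
    def pos_ok(gene, i, j):
        seq = "".join(gene.exon_sequence(genome, k) for k in range(i, j + 1))
        aa = _best_junction_aa(seq)
        return aa is not None and 30 <= aa < 100

    # upregulated decoys: every junction-spanning ORF >= 100 aa or none at all
    def long_ok(gene, i, j):
        seq = "".join(gene.exon_sequence(genome, k) for k in range(i, j + 1))
        aa = _best_junction_aa(seq)
        return aa is None or aa >= 100

    circs: list[PlantedCirc] = []
    jitter = lambda n: np.power(2.0, rng.normal(0.0, 0.25, size=n))

    gene_p, i_p, j_p = draw_block(pos_ok)
    base = 0.8
    pos_ab = {}
    jt = jitter(2 * n_pairs)
    for k, s in enumerate(samples):
        scale = 2.0 ** positive_lfc if s.startswith("T") else 1.0
        pos_ab[s] = float(base * scale * jt[k])
    positive = make_circ(genome, gene_p, i_p, j_p, pos_ab, circ_id="circ_pos")
    circs.append(positive)

    for d in range(n_long_orf_upregulated):
        try:
            gene, i, j = draw_block(long_ok, tries=2000)
        except CapacityError:
            break
        ab = {}
        jt = jitter(2 * n_pairs)
        for k, s in enumerate(samples):
            scale = 2.0 ** positive_lfc if s.startswith("T") else 1.0
            ab[s] = float(1.0 * scale * jt[k])
        circs.append(make_circ(genome, gene, i, j, ab, circ_id=f"circ_uplong{d + 1:02d}"))

    for d in range(n_decoys):
        gene, i, j = draw_block(lambda *_: True)
        b = float(np.power(2.0, rng.normal(0.0, 0.3)))
        jt = jitter(2 * n_pairs)
        ab = {s: float(b * jt[k]) for k, s in enumerate(samples)}
        circs.append(make_circ(genome, gene, i, j, ab, circ_id=f"circ_decoy{d + 1:03d}"))

    lin_ab = {}
    for g in genes:
        b = float(np.power(2.0, rng.normal(0.0, 0.6)))
        jt = jitter(2 * n_pairs)
        lin_ab[g.gene_id] = {s: float(b * jt[k]) for k, s in enumerate(samples)}

    truth = SimulationTruth(seed, samples, genes, circs, lin_ab,
                            de_features={"circ_pos": positive_lfc,
                                         **{c.circ_id: positive_lfc for c in circs
                                            if c.circ_id.startswith("circ_uplong")}})
    readsim = simulate_reads(truth, genome, read_len=read_len, depth=depth,
                             err=err, seed=seeds[3])

    expr_gene_ids = [f"g{i + 1:04d}" for i in range(n_expr_genes)]
    nk_members = list(rng.choice(expr_gene_ids, size=nk_set_size, replace=False))
    circ_profile = np.array([pos_ab[s] for s in samples])
    gene_matrix, _, expr_truth = simulate_expression(
        n_expr_genes, 2 * n_pairs, circ_profile, corr_set=nk_members,
        target_r=target_r, noise_sd=corr_noise_sd * float(np.std(circ_profile, ddof=1)),
        seed=seeds[4])
    truth.corr_sets.append({"name": "NK_CELL_CYTOTOXICITY_SYNTHETIC",
                            "members": nk_members, "target_r": target_r,
                            "noise_sd": corr_noise_sd})
    gene_lengths = pd.Series(
        rng.integers(500, 4000, size=n_expr_genes).astype(float), index=expr_gene_ids)
    gene_sets = {"NK_CELL_CYTOTOXICITY_SYNTHETIC": nk_members}
    return DemoDataset(genome, truth, readsim, gene_matrix, gene_lengths,
                       gene_sets, "NK_CELL_CYTOTOXICITY_SYNTHETIC", "circ_pos")


def make_rolling_orf_circle(length: int = 253, orf_aa: int = 92, seed: int = 20) -> str:
    """Construct a synthetic circle with a junction-spanning ORF of given size.

    Returns a random circular sequence of ``length`` nt whose ORF starting
    at offset 0 reads exactly ``orf_aa`` sense codons before the first
    in-frame stop; when ``3 * orf_aa + 3 > length`` the ORF spans the
    junction (and, for lengths not divisible by 3, finishes in a shifted
    frame).  This is a constructed stand-in for worked-example circles
    such as a 253-nt two-exon circRNA translated into a 92-aa peptide; it
    is synthetic sequence, not a natural one.
    """
    if not 0 < 3 * orf_aa <= 3 * length:
        raise ParameterError("orf_aa must fit within three passes of the circle")
    stops = ("TAA", "TAG", "TGA")
    rng = np.random.default_rng(seed)
    seq = list("ATG") + [str(b) for b in rng.choice(list(BASES), size=length - 3)]
    # plant the stop at ORF nt offset 3*orf_aa (possibly on a later pass)
    for k, ch in enumerate("TAA"):
        seq[(3 * orf_aa + k) % length] = ch
    # remove premature in-frame stops by recoding their first base
    for _ in range(10 * length):
        rep = "".join(seq) * 3
        bad = next((q for q in range(0, 3 * orf_aa, 3) if rep[q:q + 3] in stops), None)
        if bad is None:
            break
        pos = bad % length
        seq[pos] = "C" if seq[pos] != "C" else "G"
    else:
        raise ParameterError("could not construct a stop-free reading frame")
    return "".join(seq)


# ======================================================================
# GFF3 round trip
# ======================================================================

def write_gff3(genes: list[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            fh.write(f"{g.chrom}\tcircscreen\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id};coding={int(g.is_coding)}\n")
            for k, (es, ee) in enumerate(g.exons):
                fh.write(f"{g.chrom}\tcircscreen\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t"
                         f"ID={g.gene_id}.e{k + 1};Parent={g.gene_id};exon_number={k + 1}\n")


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    import gffutils
    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True)
    genes = []
    for g in db.features_of_type("gene", order_by="start"):
        exons = [(f.start - 1, f.end) for f in db.children(g, featuretype="exon", order_by="start")]
        if g.strand == "-":
            exons = exons[::-1]
        coding = g.attributes.get("coding", ["1"])[0] == "1"
        genes.append(GeneModel(g.id, g.seqid, g.strand, exons, coding))
    return genes
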