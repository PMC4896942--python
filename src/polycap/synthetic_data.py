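"""Synthetic polyploid target-capture data with known ground truth.

Every pipeline input can be generated here: bi-allelic locus read counts
with known allele dosage under ploidies 6/8/12, per-gene capture depths with
planted copy-number and absence events, probe sequences with controllable
GC and secondary structure, aligned CDS pairs with controlled synonymous
divergence, genotype matrices evolved down a known topology, gene models
with a matching genome, and a VCF subset for filter testing.  Identical
config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import divergence_phylo, probe_model
from .io_formats import GeneModel, GenomicInterval, write_fasta, write_tsv, write_vcf_subset
from .variant_filtering import VariantRecord

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_locus_counts",
    "simulate_gene_depths",
    "simulate_probes",
    "simulate_capture_observations",
    "simulate_cds_pair",
    "simulate_genotypes_on_tree",
    "simulate_genome_and_genes",
    "simulate_vcf_records",
    "realistic_dosage_weights",
    "run_simulation",
    "PRINTED_CAPTURE_COEFFICIENTS",
]

#: coefficients of the published capture-efficiency regression surface
#: (reads = 5.08*GC + 13.3*PMFE - 2.11*dimer - 10.67*hairpin + 164.46)
PRINTED_CAPTURE_COEFFICIENTS = {
    "gc": 5.08,
    "pmfe": 13.3,
    "dimer": -2.11,
    "hairpin": -10.67,
}
PRINTED_CAPTURE_INTERCEPT = 164.46

_BASES = np.array(list("ACGT"))
VALID_PLOIDIES = (2, 4, 6, 8, 10, 12)


@dataclass
class SimulationConfig:
    seed: int = 0
    accessions: Sequence[tuple[str, int]] = (("acc6", 6), ("acc8", 8), ("acc12", 12))
    n_loci: int = 1000
    mean_depth: float = 100.0
    error_rate: float = 0.01
    dosage_distribution: Sequence[float] | None = None  # weights over 0..m
    n_genes: int = 500
    cnv_fraction: float = 0.01
    cnv_log2_effect: float = 2.0
    pav_fraction: float = 0.01
    probe_count: int = 50
    probe_length: int = 120
    cds_pairs: Sequence[tuple[int, float]] = ((500, 0.05),)

    def __post_init__(self) -> None:
        for name, p in (("error_rate", self.error_rate),
                        ("cnv_fraction", self.cnv_fraction),
                        ("pav_fraction", self.pav_fraction)):
            if not (0 <= p <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.cnv_fraction + self.pav_fraction > 1:
            raise ValueError("cnv_fraction + pav_fraction must be <= 1")
        for name, m in self.accessions:
            if m % 2 != 0 or m < 2:
                raise ValueError(f"ploidy of {name} must be even and >= 2")
        if self.probe_length < 20:
            raise ValueError("probe_length must be >= 20")
        if self.dosage_distribution is not None:
            w = np.asarray(self.dosage_distribution, dtype=float)
            if (w < 0).any() or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
                raise ValueError("dosage_distribution weights must be >= 0 and sum to 1")


@dataclass
class GroundTruth:
    """Planted truth matching a simulation run; shapes follow the config."""

    dosage: pd.DataFrame | None = None          # locus x accession true dosage
    gene_copy_log2: pd.DataFrame | None = None  # gene x accession log2 multiplier
    gene_present: pd.DataFrame | None = None    # gene x accession presence
    cds_target_ks: dict[str, float] = field(default_factory=dict)
    tree_newick: str = ""

    def to_json(self) -> str:
        payload = {}
        if self.dosage is not None:
            payload["dosage"] = self.dosage.to_dict()
        if self.gene_copy_log2 is not None:
            payload["gene_copy_log2"] = self.gene_copy_log2.to_dict()
        if self.gene_present is not None:
            payload["gene_present"] = self.gene_present.to_dict()
        if self.cds_target_ks:
            payload["cds_target_ks"] = self.cds_target_ks
        if self.tree_newick:
            payload["tree_newick"] = self.tree_newick
        return json.dumps(payload, indent=1, sort_keys=True)


def realistic_dosage_weights(m: int) -> list[float]:
    """Dosage weights mirroring observed polyploid genotype composition.

    Homozygous reference most common, then homozygous alternate;
    heterozygotes total 25% with single-dose the most frequent het class.
    """
    w = np.zeros(m + 1)
    w[0], w[m] = 0.45, 0.30
    w[1], w[m - 1] = 0.10, 0.03
    middle = np.arange(2, m - 1)
    if len(middle):
        w[middle] = 0.12 / len(middle)
    return (w / w.sum()).tolist()


def _dosage_weights(config: SimulationConfig, m: int) -> np.ndarray:
    if config.dosage_distribution is None:
        return np.full(m + 1, 1.0 / (m + 1))
    w = np.zeros(m + 1)
    given = np.asarray(config.dosage_distribution, dtype=float)[: m + 1]
    w[: len(given)] = given
    if w.sum() <= 0:
        raise ValueError("dosage_distribution puts no mass on 0..ploidy")
    return w / w.sum()


def simulate_locus_counts(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Bi-allelic locus read counts with known dosage per accession.

    True dosage d is drawn from the dosage distribution, total reads from
    Poisson(mean_depth), and alternate reads from Binomial(n, f) with
    f = (d/m)(1-e) + (1-d/m)e.
    """
    rng = np.random.default_rng(config.seed)
    e = config.error_rate
    rows = []
    truth = {}
    positions = np.arange(1, config.n_loci + 1) * 100
    refs = rng.choice(_BASES, size=config.n_loci)
    alts = np.array(
        [rng.choice([b for b in "ACGT" if b != r]) for r in refs]
    )
    for name, m in config.accessions:
        weights = _dosage_weights(config, m)
        dosages = rng.choice(m + 1, size=config.n_loci, p=weights)
        totals = rng.poisson(config.mean_depth, size=config.n_loci)
        f = (dosages / m) * (1 - e) + (1 - dosages / m) * e
        alt_counts = rng.binomial(totals, f)
        truth[name] = dosages
        for i in range(config.n_loci):
            rows.append(
                {
                    "chrom": "chr1",
                    "pos": int(positions[i]),
                    "ref": refs[i],
                    "alt": alts[i],
                    "accession": name,
                    "ref_count": int(totals[i] - alt_counts[i]),
                    "alt_count": int(alt_counts[i]),
                }
            )
    counts = pd.DataFrame(rows)
    dosage_df = pd.DataFrame(truth, index=[f"chr1:{p}" for p in positions])
    return counts, GroundTruth(dosage=dosage_df)


def simulate_gene_depths(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-gene read counts per accession with planted CNV and PAV events.

    Baseline Poisson rates scale with gene length and a per-gene capture
    efficiency.  Events are planted in the first accession relative to all
    others: CNV genes get rate * 2**(+/- cnv_log2_effect) (random sign),
    PAV genes get zero reads there while keeping >= 10 expected reads
    elsewhere.
    """
    rng = np.random.default_rng(config.seed + 1)
    names = [name for name, _ in config.accessions]
    if len(names) < 2:
        raise ValueError("need >= 2 accessions for gene depth simulation")
    n = config.n_genes
    lengths = rng.integers(500, 5000, size=n)
    efficiency = rng.uniform(0.5, 1.5, size=n)
    base_rate = config.mean_depth * (lengths / 1000.0) * efficiency
    base_rate = np.maximum(base_rate, 15.0)  # PAV criteria need robust depth

    n_cnv = int(round(config.cnv_fraction * n))
    n_pav = int(round(config.pav_fraction * n))
    event_genes = rng.choice(n, size=n_cnv + n_pav, replace=False)
    cnv_genes, pav_genes = event_genes[:n_cnv], event_genes[n_cnv:]
    cnv_signs = rng.choice([-1.0, 1.0], size=n_cnv)

    log2_mult = pd.DataFrame(0.0, index=[f"gene{i}" for i in range(n)], columns=names)
    present = pd.DataFrame(True, index=log2_mult.index, columns=names)
    target = names[0]
    log2_mult.loc[[f"gene{i}" for i in cnv_genes], target] = (
        cnv_signs * config.cnv_log2_effect
    )
    present.loc[[f"gene{i}" for i in pav_genes], target] = False

    table = pd.DataFrame({"gene_id": log2_mult.index, "length": lengths})
    for name in names:
        rate = base_rate * np.power(2.0, log2_mult[name].to_numpy())
        rate = rate * present[name].to_numpy()
        table[name] = rng.poisson(rate)
        # planted absences are exact zeros regardless of Poisson draw
        table.loc[~present[name].to_numpy(), name] = 0
    truth = GroundTruth(gene_copy_log2=log2_mult, gene_present=present)
    return table, truth


def _random_probe(rng: np.random.Generator, length: int, gc: float) -> str:
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    return "".join(rng.choice(_BASES, size=length, p=[p_at, p_gc, p_gc, p_at]))


_REVCOMP = str.maketrans("ACGT", "TGCA")


def plant_hairpin(
    rng: np.random.Generator, sequence: str, stem: int, loop: int
) -> str:
    """Embed stem + loop + reverse-complement(stem) at a random offset."""
    insert = "".join(rng.choice(_BASES, size=stem))
    loop_seq = "".join(rng.choice(_BASES, size=loop))
    motif = insert + loop_seq + insert[::-1].translate(_REVCOMP)
    if len(motif) > len(sequence):
        raise ValueError(
            f"probe length {len(sequence)} too short for stem {stem} + loop {loop}"
        )
    offset = int(rng.integers(0, len(sequence) - len(motif) + 1))
    return sequence[:offset] + motif + sequence[offset + len(motif):]


def simulate_probes(
    config: SimulationConfig,
    coefficients: dict[str, float] | None = None,
    intercept: float = PRINTED_CAPTURE_INTERCEPT,
    noise_sigma: float = 10.0,
    hairpin_fraction: float = 0.0,
    planted_stem: int = 10,
    planted_loop: int = 4,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Probe FASTA plus per-probe read counts on a linear feature surface.

    GC is drawn uniformly on 20-80%; expected counts follow the configured
    linear model over computed features (printed coefficients by default)
    plus Gaussian noise.
    """
    rng = np.random.default_rng(config.seed + 2)
    coefs = coefficients or PRINTED_CAPTURE_COEFFICIENTS
    sequences: dict[str, str] = {}
    feature_rows = []
    for i in range(config.probe_count):
        gc_target = rng.uniform(0.2, 0.8)
        seq = _random_probe(rng, config.probe_length, gc_target)
        if hairpin_fraction and rng.random() < hairpin_fraction:
            seq = plant_hairpin(rng, seq, planted_stem, planted_loop)
        probe_id = f"probe{i}"
        sequences[probe_id] = seq
        feats = probe_model.compute_features(seq, probe_id=probe_id)
        feature_rows.append(
            {
                "probe_id": probe_id,
                "gc": feats.gc,
                "tm": feats.tm,
                "pmfe": feats.pmfe,
                "phfe": feats.phfe,
                "hairpin": feats.hairpin,
                "dimer": feats.dimer,
            }
        )
    table = pd.DataFrame(feature_rows)
    expected = np.full(len(table), float(intercept))
    for name, coef in coefs.items():
        expected += coef * table[name].to_numpy()
    noise = rng.normal(0.0, noise_sigma, size=len(table)) if noise_sigma > 0 else 0.0
    table["read_count"] = expected + noise
    return sequences, table


def simulate_capture_observations(
    n: int,
    coefficients: dict[str, float] | None = None,
    intercept: float = PRINTED_CAPTURE_INTERCEPT,
    noise_sigma: float = 10.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature matrix + response drawn from the printed linear surface.

    Feature values are sampled from plausible marginal ranges (GC 20-80%,
    PMFE -40..0, hairpin/dimer 0..12) without the cost of sequence-level
    feature computation; use for regression-recovery experiments at large n.
    """
    rng = np.random.default_rng(seed)
    coefs = coefficients or PRINTED_CAPTURE_COEFFICIENTS
    X = pd.DataFrame(
        {
            "gc": rng.uniform(20, 80, size=n),
            "pmfe": rng.uniform(-40, 0, size=n),
            "dimer": rng.integers(0, 13, size=n).astype(float),
            "hairpin": rng.integers(0, 13, size=n).astype(float),
        }
    )
    y = np.full(n, float(intercept))
    for name, coef in coefs.items():
        y = y + coef * X[name].to_numpy()
    if noise_sigma > 0:
        y = y + rng.normal(0.0, noise_sigma, size=n)
    return X, y


# ---------------------------------------------------------------------------
# CDS pairs with controlled synonymous divergence
# ---------------------------------------------------------------------------

_FOURFOLD_PREFIXES = {
    "CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG",
}  # third position fully degenerate


def _random_cds(rng: np.random.Generator, length_codons: int) -> str:
    codons = []
    sense = [c for c in divergence_phylo.SENSE_CODONS]
    picks = rng.integers(0, len(sense), size=length_codons)
    for i in picks:
        codons.append(sense[i])
    return "".join(codons)


def simulate_cds_pair(
    length_codons: int, target_ks: float, seed: int = 0
) -> tuple[str, str]:
    """Ancestor CDS plus a copy diverged only at 4-fold degenerate sites.

    The number of synonymous substitutions is calibrated so the counting
    estimator's expected Ks matches ``target_ks`` (inverse Jukes-Cantor on
    the NG86 synonymous site count).  No indels; neither sequence contains
    internal stops.
    """
    if target_ks < 0:
        raise ValueError("target_ks must be >= 0")
    rng = np.random.default_rng(seed)
    ancestor = _random_cds(rng, length_codons)

    fourfold = [
        i
        for i in range(0, len(ancestor), 3)
        if ancestor[i : i + 2] in _FOURFOLD_PREFIXES
    ]
    syn_sites = sum(
        divergence_phylo.synonymous_sites(ancestor[i : i + 3])
        for i in range(0, len(ancestor), 3)
    )
    # invert the JC correction: p = (3/4)(1 - exp(-4 Ks / 3))
    p_target = 0.75 * (1.0 - math.exp(-4.0 * target_ks / 3.0))
    n_subs = int(round(p_target * syn_sites))
    if n_subs > len(fourfold):
        max_p = len(fourfold) / syn_sites
        max_ks = -0.75 * math.log(1.0 - 4.0 * max_p / 3.0)
        raise ValueError(
            f"target_ks {target_ks} unachievable; at most {max_ks:.4f} with "
            f"{len(fourfold)} four-fold degenerate sites"
        )
    derived = list(ancestor)
    chosen = rng.choice(len(fourfold), size=n_subs, replace=False)
    for idx in chosen:
        codon_start = fourfold[idx]
        third = codon_start + 2
        alternatives = [b for b in "ACGT" if b != ancestor[third]]
        derived[third] = alternatives[rng.integers(0, 3)]
    return ancestor, "".join(derived)


# ---------------------------------------------------------------------------
# Genotypes down a known topology
# ---------------------------------------------------------------------------


def simulate_genotypes_on_tree(
    newick: str, n_loci: int, seed: int = 0
) -> tuple[pd.DataFrame, GroundTruth]:
    """Binary genotype matrix evolved down a topology.

    Branch lengths are per-locus substitution (state-flip) probabilities.
    Returns a loci x accessions 0/1 table suitable for
    :func:`polycap.divergence_phylo.nj_tree_with_bootstrap`.
    """
    from .io_formats import read_newick

    tree = read_newick(newick)
    rng = np.random.default_rng(seed)
    states: dict[int, np.ndarray] = {id(tree): np.zeros(n_loci, dtype=int)}
    leaf_states: dict[str, np.ndarray] = {}
    for node in tree.preorder(include_self=False):
        p = float(node.length or 0.0)
        flips = rng.random(n_loci) < p
        state = states[id(node.parent)] ^ flips
        states[id(node)] = state
        if node.is_tip():
            leaf_states[node.name] = state
    table = pd.DataFrame(leaf_states, index=[f"locus{i}" for i in range(n_loci)])
    return table, GroundTruth(tree_newick=newick)


# ---------------------------------------------------------------------------
# Genome + gene models, VCF records
# ---------------------------------------------------------------------------


def simulate_genome_and_genes(
    n_genes: int = 20,
    seed: int = 0,
    exons_per_gene: tuple[int, int] = (1, 3),
    cds_codons: tuple[int, int] = (30, 120),
    intron_length: tuple[int, int] = (50, 200),
    spacer: int = 300,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Random genome with embedded multi-exon genes on both strands.

    CDS sequences start with ATG, end with a stop, and contain no internal
    stops on the coding strand; exon structure splits the CDS at random
    codon-boundary-free positions, so spliced-CDS reconstruction and strand
    handling get exercised.
    """
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    genome_parts: list[str] = []
    models: list[GeneModel] = []
    cursor = 0

    def emit(seq: str) -> None:
        nonlocal cursor
        genome_parts.append(seq)
        cursor += len(seq)

    for g in range(n_genes):
        emit("".join(rng.choice(_BASES, size=spacer)))
        n_codons = int(rng.integers(*cds_codons))
        body = _random_cds(rng, n_codons - 2)
        stop = ["TAA", "TAG", "TGA"][int(rng.integers(0, 3))]
        cds_seq = "ATG" + body + stop
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            genomic_cds = cds_seq[::-1].translate(_REVCOMP)
        else:
            genomic_cds = cds_seq
        n_exons = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        n_exons = min(n_exons, len(genomic_cds) // 10 or 1)
        cuts = sorted(
            rng.choice(np.arange(5, len(genomic_cds) - 5), size=n_exons - 1, replace=False)
        ) if n_exons > 1 else []
        pieces = np.split(np.arange(len(genomic_cds)), cuts)
        gene_start = cursor
        cds_intervals = []
        for pi, piece in enumerate(pieces):
            seg = genomic_cds[piece[0] : piece[-1] + 1]
            seg_start = cursor
            emit(seg)
            cds_intervals.append(
                GenomicInterval(chrom, seg_start, seg_start + len(seg), strand)
            )
            if pi < len(pieces) - 1:
                emit("".join(rng.choice(_BASES, size=int(rng.integers(*intron_length)))))
        gene_end = cursor
        model = GeneModel(
            gene_id=f"gene{g}",
            interval=GenomicInterval(chrom, gene_start, gene_end, strand),
            exons=list(cds_intervals),
            cds=list(cds_intervals),
        )
        models.append(model)
    emit("".join(rng.choice(_BASES, size=spacer)))
    return {chrom: "".join(genome_parts)}, models


def gene_models_to_gff3(models: Sequence[GeneModel]) -> str:
    """Serialize GeneModels back to GFF3 (1-based inclusive)."""
    lines = ["##gff-version 3"]
    for m in models:
        iv = m.interval
        lines.append(
            f"{iv.chrom}\tpolycap\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\tID={m.gene_id}"
        )
        tid = f"{m.gene_id}.1"
        lines.append(
            f"{iv.chrom}\tpolycap\tmRNA\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\tID={tid};Parent={m.gene_id}"
        )
        for kind, ivs in (("exon", m.exons), ("CDS", m.cds),
                          ("five_prime_UTR", m.utr5), ("three_prime_UTR", m.utr3)):
            for sub in ivs:
                phase = "0" if kind == "CDS" else "."
                lines.append(
                    f"{sub.chrom}\tpolycap\t{kind}\t{sub.start + 1}\t{sub.end}\t.\t{sub.strand}\t{phase}\tID={m.gene_id}.{kind};Parent={tid}"
                )
    return "\n".join(lines) + "\n"


def simulate_vcf_records(
    config: SimulationConfig,
    n_records: int = 200,
    genome: dict[str, str] | None = None,
) -> list[VariantRecord]:
    """Randomized VariantRecords spanning the hard-filter decision space.

    When ``genome`` is given, positions and reference bases are drawn from
    it so the records can also be annotated against matching gene models.
    """
    rng = np.random.default_rng(config.seed + 3)
    samples = tuple(name for name, _ in config.accessions)
    records = []
    chrom_name = next(iter(genome)) if genome else "chr1"
    chrom_seq = genome[chrom_name] if genome else ""
    if genome:
        positions = np.sort(
            rng.choice(len(chrom_seq), size=min(n_records, len(chrom_seq)), replace=False)
        )
        n_records = len(positions)
    for i in range(n_records):
        if genome:
            pos = int(positions[i]) + 1
            ref = chrom_seq[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
        else:
            pos = 100 + i * 10
            ref, alt = rng.choice(_BASES, size=2, replace=False)
        depths = rng.integers(0, 400, size=len(samples))
        counts = []
        for d in depths:
            alt_c = int(rng.integers(0, d + 1))
            counts.append((int(d) - alt_c, alt_c))
        records.append(
            VariantRecord(
                chrom=chrom_name,
                pos=pos,
                ref=str(ref),
                alts=(str(alt),),
                qual=float(rng.uniform(0, 200)),
                mq=float(rng.uniform(0, 60)),
                bq=float(rng.uniform(0, 40)),
                samples=samples,
                depths=tuple(int(d) for d in depths),
                allele_counts=tuple(counts),
                gqs=(None,) * len(samples),
                caller="sim",
            )
        )
    return records


def run_simulation(config: SimulationConfig, outdir: str | Path) -> dict[str, str]:
    """Generate the full input bundle under ``outdir``; returns file paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    counts, locus_truth = simulate_locus_counts(config)
    write_tsv(counts, out / "locus_counts.tsv")
    paths["locus_counts"] = str(out / "locus_counts.tsv")

    gene_table, gene_truth = simulate_gene_depths(config)
    write_tsv(gene_table, out / "gene_depths.tsv")
    paths["gene_depths"] = str(out / "gene_depths.tsv")

    sequences, probe_table = simulate_probes(config)
    write_fasta(sequences, out / "probes.fasta")
    write_tsv(probe_table, out / "probe_counts.tsv")
    paths["probes"] = str(out / "probes.fasta")
    paths["probe_counts"] = str(out / "probe_counts.tsv")

    genome, models = simulate_genome_and_genes(n_genes=min(config.n_genes, 50),
                                               seed=config.seed + 4)
    write_fasta(genome, out / "genome.fasta")
    (out / "genes.gff3").write_text(gene_models_to_gff3(models))
    paths["genome"] = str(out / "genome.fasta")
    paths["gff3"] = str(out / "genes.gff3")

    records = simulate_vcf_records(config, genome=genome)
    write_vcf_subset(records, out / "variants.vcf")
    paths["vcf"] = str(out / "variants.vcf")

    pairs_dir = out / "cds_pairs"
    pairs_dir.mkdir(exist_ok=True)
    for i, (length_codons, target_ks) in enumerate(config.cds_pairs):
        a, b = simulate_cds_pair(length_codons, target_ks, seed=config.seed + 5 + i)
        write_fasta({"seqA": a, "seqB": b}, pairs_dir / f"cds_pair_{i}.fasta")
        paths[f"cds_pair_{i}"] = str(pairs_dir / f"cds_pair_{i}.fasta")

    truth = GroundTruth(
        dosage=locus_truth.dosage,
        gene_copy_log2=gene_truth.gene_copy_log2,
        gene_present=gene_truth.gene_present,
        cds_target_ks={
            f"cds_pair_{i}": ks for i, (_, ks) in enumerate(config.cds_pairs)
        },
    )
    (out / "ground_truth.json").write_text(truth.to_json())
    paths["ground_truth"] = str(out / "ground_truth.json")
    return paths
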