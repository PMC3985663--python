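"""Synthetic genomes, planted antisense-L1 fusion transcripts and probe data.

The generator emulates the inputs of the RIFT assay — RefSeq-like gene
models, RepeatMasker-like L1 integrant annotations, normalized log2 exon
probe intensities, and aligned cDNA clones — with a known truth set of
planted antisense-L1 RIFTs, so every downstream stage can be tested without
external data.

Category counts (full-length fraction, caller-eligible fraction,
polymorphic fraction) are applied as exact rounded counts with
seed-shuffled assignment, so the composition of the synthetic genome is the
same for every seed; only placements, lengths and labels vary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import caller as _caller
from .models import (CallerParams, GeneModel, GenomeAnnotation, L1Integrant,
                     L1Reference, PlantedRIFT, ProbeMatrix, TranscriptClone)

logger = logging.getLogger(__name__)

# canonical antisense splice donors, written as they read on the antisense
# transcript (exonic 4-mer upper case + intronic 5-mer lower case), anchored
# at the L1 sense coordinate of the last exonic base
DONOR_GATG = ("GATGgtgag", 1838)
DONOR_TCAG = ("TCAGgtgtg", 1892)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic genome and probe data.

    Intensity units are log2; the background Normal(6, 1) calibrates the
    per-sample mean + 1 SD threshold to ~7.  ``signal_shift`` of 6 log2
    units (6 background SDs) gives unambiguous planted signal.  The default
    TSS windows per tissue are the observed 5' RACE ranges (testis
    2201-2244, kidney 2210-2306, brain 2210-2478, in L1 sense coordinates).
    """

    seed: int = 0
    # genome layout
    n_genes: int = 200
    n_l1: int = 60
    chrom: str = "chr1"
    chrom_length: int = 36_000_000
    exons_per_gene: int = 8
    exon_length: int = 200
    intron_length: int = 8_000
    gene_spacing: int = 110_000
    genome_offset: int = 50_000
    # probe/intensity model
    background_mean: float = 6.0
    background_sd: float = 1.0
    signal_shift: float = 6.0
    probes_per_exon: int = 4
    probe_length: int = 25
    # L1 population composition
    full_length_fraction: float = 0.6
    eligible_fraction: float = 0.35
    polymorphic_fraction: float = 0.5
    full_length_range: tuple[int, int] = (6_500, 7_000)
    short_length_range: tuple[int, int] = (1_000, 4_000)
    subfamily_mix: tuple[tuple[str, float], ...] = (
        ("L1Md_T", 0.5), ("L1Md_Gf", 0.2), ("L1Md_A", 0.2), ("L1Md_F", 0.1))
    l1_ref_length: int = 7_000
    # samples and truth
    strains: tuple[str, ...] = ("129S1", "129X1", "AJ", "B6", "DBA2J")
    tissues: tuple[str, ...] = ("testis", "brain", "kidney")
    n_rifts: Optional[int] = 20
    rift_tissue_weights: tuple[float, ...] = (0.7, 0.15, 0.15)
    spliced_fraction: float = 0.78
    tss_window: tuple[int, int] = (2201, 2244)
    tss_windows: tuple[tuple[str, tuple[int, int]], ...] = (
        ("testis", (2201, 2244)), ("kidney", (2210, 2306)),
        ("brain", (2210, 2478)))
    donor_choices: tuple[tuple[Optional[str], Optional[int], float], ...] = (
        ("GATGgtgag", 1838, 0.68), ("TCAGgtgtg", 1892, 0.20),
        (None, None, 0.12))
    # clone simulation
    clones_per_tissue: tuple[tuple[str, int], ...] = (
        ("testis", 19), ("kidney", 35), ("brain", 54))
    n_decoy_clones: int = 4
    unspliced_flank: int = 500

    def __post_init__(self) -> None:
        if self.n_genes < 0 or self.n_l1 < 0:
            raise ValueError("n_genes and n_l1 must be non-negative")
        for name in ("chrom_length", "exons_per_gene", "exon_length",
                     "intron_length", "probes_per_exon", "probe_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.background_sd < 0:
            raise ValueError("background_sd must be >= 0")
        if self.signal_shift < 0:
            raise ValueError("signal_shift must be >= 0")
        lo, hi = self.tss_window
        if not (1 <= lo <= hi <= self.l1_ref_length):
            raise ValueError("tss_window outside the L1 reference")
        for frac in ("full_length_fraction", "eligible_fraction",
                     "polymorphic_fraction", "spliced_fraction"):
            if not 0.0 <= getattr(self, frac) <= 1.0:
                raise ValueError(f"{frac} must be in [0, 1]")
        span_needed = self.genome_offset + self.n_genes * self.gene_stride \
            + 400_000 + 30_000 * self.n_l1
        if self.n_genes and span_needed > self.chrom_length:
            raise ValueError(
                f"chrom_length {self.chrom_length} too small for layout "
                f"(needs ~{span_needed})")

    @property
    def gene_span(self) -> int:
        return self.exons_per_gene * self.exon_length \
            + (self.exons_per_gene - 1) * self.intron_length

    @property
    def gene_stride(self) -> int:
        return self.gene_span + self.gene_spacing

    def tss_window_for(self, tissue: str) -> tuple[int, int]:
        for name, window in self.tss_windows:
            if name == tissue:
                return window
        return self.tss_window


def _rng(stage: int, config: GeneratorConfig) -> np.random.Generator:
    # independent, reproducible stream per generator stage
    return np.random.default_rng([stage, config.seed])


def gen_genome(config: GeneratorConfig) -> GenomeAnnotation:
    """Generate gene models and an L1 integrant population.

    Exactly ``round(full_length_fraction * n_l1)`` integrants are
    full-length; of those, ``round(eligible_fraction * n_l1)`` (capped by
    the full-length count and the gene count) satisfy every caller filter:
    full-length, active subfamily, intronic and antisense to their host
    gene.  The remaining full-length elements each fail exactly one filter
    (sense orientation, inactive subfamily, or distance), and
    ``round(polymorphic_fraction * n_eligible)`` eligible elements are
    polymorphic (present in a proper subset of strains).
    """
    rng = _rng(1, config)
    genes: list[GeneModel] = []
    for i in range(config.n_genes):
        gstart = config.genome_offset + i * config.gene_stride
        exons = tuple(
            (gstart + j * (config.exon_length + config.intron_length),
             gstart + j * (config.exon_length + config.intron_length)
             + config.exon_length)
            for j in range(config.exons_per_gene))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(gene_id=f"gene{i:04d}", chrom=config.chrom,
                               strand=strand, exons=exons))

    n_full = round(config.full_length_fraction * config.n_l1)
    n_eligible = min(round(config.eligible_fraction * config.n_l1),
                     n_full, config.n_genes)
    fail_modes = ["sense", "subfamily", "far"] if config.n_genes else ["far"]
    categories = ["eligible"] * n_eligible
    categories += [fail_modes[k % len(fail_modes)]
                   for k in range(n_full - n_eligible)]
    categories += ["short"] * (config.n_l1 - n_full)
    categories = list(rng.permutation(categories))

    n_intronic = sum(1 for c in categories if c in ("eligible", "sense",
                                                    "subfamily"))
    if n_intronic > config.n_genes:
        raise ValueError("more intronic L1s than genes available to host them")
    host_order = list(rng.permutation(config.n_genes)[:n_intronic])
    sub_names = [s for s, _ in config.subfamily_mix]
    sub_weights = np.array([w for _, w in config.subfamily_mix], dtype=float)
    sub_weights = sub_weights / sub_weights.sum()

    n_poly = (round(config.polymorphic_fraction * n_eligible)
              if len(config.strains) >= 2 else 0)
    eligible_seen = 0
    poly_slots = set(rng.choice(n_eligible, size=n_poly, replace=False)
                     ) if n_eligible else set()

    l1s: list[L1Integrant] = []
    far_count = 0
    all_strains = frozenset(config.strains)
    for i, cat in enumerate(categories):
        l1_id = f"L1_{i:04d}"
        present = all_strains
        if cat == "short":
            length = int(rng.integers(*config.short_length_range))
            g = int(rng.integers(0, max(config.n_genes, 1)))
            anchor = (genes[g].end if config.n_genes
                      else config.genome_offset + 30_000 * i)
            start = anchor + int(rng.integers(20_000, 40_000))
            strand = "+" if rng.random() < 0.5 else "-"
            subfamily = str(rng.choice(sub_names, p=sub_weights))
            full_length = False
        elif cat == "far":
            length = int(rng.integers(config.full_length_range[0],
                                      config.full_length_range[1] + 1))
            start = config.genome_offset + config.n_genes * config.gene_stride \
                + 300_000 + far_count * 30_000
            far_count += 1
            strand = "+" if rng.random() < 0.5 else "-"
            subfamily = str(rng.choice(sub_names, p=sub_weights))
            full_length = True
        else:  # intronic: eligible / sense / subfamily
            gene = genes[host_order.pop()]
            length = int(rng.integers(config.full_length_range[0],
                                      config.full_length_range[1] + 1))
            length = min(length, config.intron_length - 100)
            intron_j = int(rng.integers(2, config.exons_per_gene - 2))
            intron_start = gene.exons[intron_j][1]
            offset = int(rng.integers(0, config.intron_length - length + 1))
            start = intron_start + offset
            if cat == "sense":
                strand = gene.strand
                subfamily = str(rng.choice(sub_names, p=sub_weights))
            elif cat == "subfamily":
                strand = "-" if gene.strand == "+" else "+"
                subfamily = "Lx5"
            else:  # eligible
                strand = "-" if gene.strand == "+" else "+"
                subfamily = str(rng.choice(sub_names, p=sub_weights))
                if eligible_seen in poly_slots:
                    size = int(rng.integers(1, len(config.strains)))
                    chosen = rng.choice(len(config.strains), size=size,
                                        replace=False)
                    present = frozenset(config.strains[int(k)] for k in chosen)
                eligible_seen += 1
            full_length = True
        l1s.append(L1Integrant(l1_id=l1_id, chrom=config.chrom, start=start,
                               end=start + length, strand=strand,
                               subfamily=subfamily, full_length=full_length,
                               present_in=present))
    return GenomeAnnotation(genes=tuple(genes), l1s=tuple(l1s),
                            chrom_lengths={config.chrom: config.chrom_length})


def downstream_exons(gene: GeneModel, l1: L1Integrant) -> tuple[int, ...]:
    """Indices of the gene exons downstream of the L1 in transcription direction."""
    if gene.strand == "+":
        return tuple(i for i, (s, e) in enumerate(gene.exons) if s >= l1.end)
    return tuple(i for i, (s, e) in enumerate(gene.exons) if e <= l1.start)


def eligible_pairs(annotation: GenomeAnnotation,
                   params: CallerParams = CallerParams(),
                   ) -> list[tuple[GeneModel, L1Integrant]]:
    """(gene, L1) pairs where the L1 passes every caller filter for that gene."""
    pairs = []
    limit = int(params.gene_distance_kb * 1000)
    for gene in annotation.genes:
        for l1 in annotation.l1s:
            flags = _caller.l1_passes_static_filters(l1, gene, params)
            if not all(flags.values()):
                continue
            if _caller.interval_gap(l1.start, l1.end, gene.start, gene.end) > limit:
                continue
            if not downstream_exons(gene, l1):
                continue
            pairs.append((gene, l1))
    return pairs


def plant_rifts(annotation: GenomeAnnotation, config: GeneratorConfig,
                ) -> list[PlantedRIFT]:
    """Select eligible (gene, L1) pairs and define the truth set of RIFTs.

    Each planted RIFT gets a tissue (testis-weighted by default), an
    antisense TSS drawn uniformly in that tissue's window of L1 sense
    coordinates, and — if spliced — a splice donor at one of the two
    canonical coordinates (1838, 1892) or an "other" coordinate.
    """
    rng = _rng(4, config)
    pairs = eligible_pairs(annotation)
    if not pairs:
        logger.warning("plant_rifts: no eligible antisense L1/gene pairs")
        return []
    # at most one RIFT per gene and per L1
    seen_genes: set[str] = set()
    seen_l1: set[str] = set()
    unique_pairs = []
    for gene, l1 in pairs:
        if gene.gene_id in seen_genes or l1.l1_id in seen_l1:
            continue
        seen_genes.add(gene.gene_id)
        seen_l1.add(l1.l1_id)
        unique_pairs.append((gene, l1))
    order = rng.permutation(len(unique_pairs))
    if config.n_rifts is not None:
        order = order[:config.n_rifts]
    w = list(config.rift_tissue_weights)[:len(config.tissues)]
    w += [1.0] * (len(config.tissues) - len(w))
    weights = np.array(w, dtype=float)
    weights = weights / weights.sum()

    rifts: list[PlantedRIFT] = []
    for k in sorted(int(i) for i in order):
        gene, l1 = unique_pairs[k]
        tissue = str(rng.choice(list(config.tissues), p=weights))
        lo, hi = config.tss_window_for(tissue)
        hi = min(hi, l1.length)
        lo = min(lo, hi)
        tss = int(rng.integers(lo, hi + 1))
        spliced = bool(rng.random() < config.spliced_fraction)
        donor_motif = donor_coord = None
        if spliced:
            probs = np.array([w for _, _, w in config.donor_choices])
            choice = int(rng.choice(len(config.donor_choices),
                                    p=probs / probs.sum()))
            donor_motif, donor_coord, _ = config.donor_choices[choice]
            if donor_coord is None:
                donor_coord = int(rng.integers(1700, 2101))
                while donor_coord in (DONOR_GATG[1], DONOR_TCAG[1]):
                    donor_coord = int(rng.integers(1700, 2101))
        rifts.append(PlantedRIFT(
            gene_id=gene.gene_id, l1_id=l1.l1_id, tss_l1_coord=tss,
            spliced=spliced, donor_motif=donor_motif,
            donor_l1_coord=donor_coord,
            affected_exons=downstream_exons(gene, l1), tissue=tissue,
            strains=frozenset(l1.present_in) & frozenset(config.strains)))
    return rifts


def gen_probe_matrix(annotation: GenomeAnnotation,
                     planted: Sequence[PlantedRIFT],
                     config: GeneratorConfig) -> ProbeMatrix:
    """Simulate normalized log2 probe intensities with planted signal.

    Background intensities are Normal(background_mean, background_sd);
    probes inside the affected exons of each planted RIFT gain
    ``signal_shift`` in the samples whose (strain, tissue) matches the
    RIFT's truth labels.
    """
    rows = []
    for gene in sorted(annotation.genes, key=lambda g: (g.chrom, g.start)):
        for ei, (es, ee) in enumerate(gene.exons):
            offsets = np.linspace(0, max(ee - es - config.probe_length, 0),
                                  config.probes_per_exon).astype(int)
            for k, off in enumerate(offsets):
                rows.append((f"{gene.gene_id}_e{ei:02d}_p{k}", gene.chrom,
                             int(es + off),
                             int(es + off + config.probe_length),
                             gene.gene_id))
    probes = pd.DataFrame(rows, columns=ProbeMatrix.PROBE_COLS)
    probes = probes.sort_values(["chrom", "start"],
                                kind="stable").reset_index(drop=True)

    sample_rows = [(f"{strain}_{tissue}", strain, tissue)
                   for strain in config.strains for tissue in config.tissues]
    samples = pd.DataFrame(sample_rows,
                           columns=["sample_id", "strain", "tissue"])
    if samples["sample_id"].duplicated().any():
        raise ValueError("sample labels are not unique")

    rng = _rng(2, config)
    intensities = rng.normal(config.background_mean, config.background_sd,
                             size=(len(probes), len(samples)))

    for rift in planted:
        gene = annotation.gene(rift.gene_id)
        exon_ivs = [gene.exons[i] for i in rift.affected_exons]
        row_mask = np.zeros(len(probes), dtype=bool)
        gene_rows = probes["gene_id"] == rift.gene_id
        for es, ee in exon_ivs:
            row_mask |= (gene_rows & (probes["start"] >= es)
                         & (probes["end"] <= ee)).to_numpy()
        col_mask = ((samples["tissue"] == rift.tissue)
                    & samples["strain"].isin(rift.strains)).to_numpy()
        intensities[np.ix_(row_mask, col_mask)] += config.signal_shift
    return ProbeMatrix(probes, samples, intensities)


def gen_transcript_clones(annotation: GenomeAnnotation,
                          planted: Sequence[PlantedRIFT],
                          config: GeneratorConfig) -> list[TranscriptClone]:
    """Simulate 5' RACE / cDNA clone alignments for the planted RIFTs.

    Per tissue, ``clones_per_tissue`` clones are drawn from the planted
    RIFTs; a spliced RIFT yields a two-block clone whose L1 block ends at
    the splice donor coordinate and continues into the first downstream
    exon, an unspliced RIFT a single antisense block reading through the L1
    5' end into flanking sequence.  ``n_decoy_clones`` prematurely
    polyadenylated sense-strand clones are added as decoys.
    """
    rng = _rng(3, config)
    clones: list[TranscriptClone] = []
    counter = 0
    for tissue, n_clones in config.clones_per_tissue:
        if not planted and n_clones:
            continue
        lo, hi = config.tss_window_for(tissue)
        for _ in range(n_clones):
            rift = planted[int(rng.integers(len(planted)))]
            l1 = annotation.l1(rift.l1_id)
            gene = annotation.gene(rift.gene_id)
            strain = sorted(rift.strains)[int(rng.integers(len(rift.strains)))]
            whi = min(hi, l1.length)
            wlo = min(lo, whi)
            tss = int(rng.integers(wlo, whi + 1))
            donor = rift.donor_l1_coord if rift.spliced else None
            if donor is not None and tss <= donor:
                tss = donor + 10
            clone_id = f"{tissue}_clone_{counter:03d}"
            counter += 1
            chrom = l1.chrom
            if l1.strand == "-":
                g5 = l1.end - tss
                strand = "+"
                if rift.spliced and donor is not None and rift.affected_exons:
                    l1_block = (chrom, g5, l1.end - donor + 1)
                    exon = gene.exons[min(rift.affected_exons)]
                    blocks = (l1_block, (chrom, exon[0], exon[1]))
                else:
                    blocks = ((chrom, g5, l1.end + config.unspliced_flank),)
            else:
                g5 = l1.start + tss - 1
                strand = "-"
                if rift.spliced and donor is not None and rift.affected_exons:
                    l1_block = (chrom, l1.start + donor - 1, g5 + 1)
                    exon = gene.exons[max(rift.affected_exons)]
                    blocks = ((chrom, exon[0], exon[1]), l1_block)
                else:
                    blocks = ((chrom, l1.start - config.unspliced_flank,
                               g5 + 1),)
            clones.append(TranscriptClone(
                clone_id=clone_id, tissue=tissue, strain=strain,
                blocks=blocks, strand=strand, five_prime_genomic=g5,
                has_polyA=False))
    # premature sense-strand poly(A)+ decoys
    full_length_l1s = [l1 for l1 in annotation.l1s if l1.length > 2000]
    for k in range(config.n_decoy_clones if full_length_l1s else 0):
        l1 = full_length_l1s[int(rng.integers(len(full_length_l1s)))]
        start = l1.start + 100
        block = (l1.chrom, start, start + 600)
        five_prime = start if l1.strand == "+" else start + 599
        tissue = config.tissues[int(rng.integers(len(config.tissues)))]
        strain = config.strains[int(rng.integers(len(config.strains)))]
        clones.append(TranscriptClone(
            clone_id=f"decoy_{k:03d}", tissue=tissue, strain=strain,
            blocks=(block,), strand=l1.strand, five_prime_genomic=five_prime,
            has_polyA=True))
    return clones


def make_l1_reference(seed: int = 0, length: int = 7_000,
                      name: str = "L1syn") -> L1Reference:
    """A synthetic full-length L1 reference element.

    Random sense-strand background with the two canonical antisense splice
    donor motifs planted so that an antisense transcript leaving the
    element at sense coordinate 1838 reads GATG|gtgag and at 1892 reads
    TCAG|gtgtg, plus a TATAA motif on the antisense strand ending at sense
    coordinate 2698.  Landmarks approximate a mouse full-length element
    (5' UTR, ORF1 containing the antisense promoter, ORF2, 3' UTR).  This
    is a synthetic stand-in for a real reference element such as L1spa: the
    coordinates of the planted features match the published ones, the
    background sequence does not.
    """
    rng = np.random.default_rng([5, seed])
    bases = np.array(list("ACGT"))
    seq = list(rng.choice(bases, size=length))

    def plant(sense_start_1b: int, motif: str) -> None:
        for i, ch in enumerate(motif):
            seq[sense_start_1b - 1 + i] = ch

    # antisense GATGgtgag with last exonic base at 1838:
    #   sense[1833..1841] = revcomp("GTGAG" + "GATG"[::-1]) handled explicitly
    plant(1833, revcomp("GTGAG"))       # CTCAC at 1833-1837 (intron side)
    plant(1838, revcomp("GATG"))        # CATC at 1838-1841 (exon side)
    # antisense TCAGgtgtg with last exonic base at 1892
    plant(1887, revcomp("GTGTG"))       # CACAC at 1887-1891
    plant(1892, revcomp("TCAG"))        # CTGA at 1892-1895
    # antisense TATAA ending at sense coordinate 2698
    plant(2694, revcomp("TATAA"))       # TTATA at 2694-2698
    landmarks = {"five_utr": (1, 1800), "orf1": (1801, 2916),
                 "orf2": (2921, 6790), "three_utr": (6791, length)}
    return L1Reference(name=name, length=length,
                       sense_sequence="".join(seq), landmarks=landmarks)
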