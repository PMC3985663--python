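"""Core domain types shared across the RIFT analysis stages.

Coordinate conventions
----------------------
All genomic intervals are 0-based, half-open ``[start, end)`` — the BED
convention.  Positions *inside* an L1 element are reported 1-based on the
sense strand of the element (the convention used for reference elements such
as L1spa), regardless of the genomic strand of the integrant.  The
:mod:`riftscan.coords` module holds the converters between the two systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

Interval = tuple[int, int]


@dataclass(frozen=True)
class GeneModel:
    """A gene with its exon structure.

    ``exons`` are non-overlapping ``(start, end)`` intervals sorted in
    genomic order.  For a minus-strand gene, transcription runs from the
    last exon (highest coordinates) toward the first.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: exon list is empty")
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"gene {self.gene_id}: empty exon ({s},{e})")
            if s < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> Interval:
        return (self.start, self.end)


@dataclass(frozen=True)
class L1Integrant:
    """A genomic L1 element annotation (RepeatMasker-style).

    ``present_in`` records which mouse strains carry the integrant; a
    polymorphic element is present in a proper subset of the strains under
    study.
    """

    l1_id: str
    chrom: str
    start: int
    end: int
    strand: str
    subfamily: str
    full_length: bool
    present_in: frozenset[str]

    def __post_init__(self) -> None:
        if self.end - self.start <= 0:
            raise ValueError(f"L1 {self.l1_id}: non-positive length")
        if not self.subfamily:
            raise ValueError(f"L1 {self.l1_id}: empty subfamily")
        if not self.present_in:
            raise ValueError(f"L1 {self.l1_id}: empty present_in")
        if self.strand not in ("+", "-"):
            raise ValueError(f"L1 {self.l1_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PlantedRIFT:
    """Ground-truth record for one simulated antisense-L1 fusion transcript.

    ``tss_l1_coord`` is the 1-based position of the antisense transcription
    start site on the sense strand of the L1 reference.  ``affected_exons``
    are indices (into the gene's exon tuple) of the exons downstream of the
    initiating L1 in the direction of transcription; their probes receive
    the planted intensity shift.
    """

    gene_id: str
    l1_id: str
    tss_l1_coord: int
    spliced: bool
    donor_motif: Optional[str]
    donor_l1_coord: Optional[int]
    affected_exons: tuple[int, ...]
    tissue: str
    strains: frozenset[str]


@dataclass(frozen=True)
class GenomeAnnotation:
    """Gene models plus L1 integrants on a shared coordinate system."""

    genes: tuple[GeneModel, ...]
    l1s: tuple[L1Integrant, ...]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def l1(self, l1_id: str) -> L1Integrant:
        for e in self.l1s:
            if e.l1_id == l1_id:
                return e
        raise KeyError(l1_id)

    @property
    def chroms(self) -> set[str]:
        return {g.chrom for g in self.genes} | {e.chrom for e in self.l1s}


class ProbeMatrix:
    """Genomically positioned exon probes x samples, log2 intensities.

    Parameters
    ----------
    probes
        DataFrame with columns ``probe_id, chrom, start, end, gene_id``,
        sorted by ``(chrom, start)``.
    samples
        DataFrame with columns ``sample_id, strain, tissue``; sample ids
        must be unique.
    intensities
        ``(n_probes, n_samples)`` array of log2 intensities.
    """

    PROBE_COLS = ["probe_id", "chrom", "start", "end", "gene_id"]

    def __init__(self, probes: pd.DataFrame, samples: pd.DataFrame,
                 intensities: np.ndarray):
        probes = probes.reset_index(drop=True)
        samples = samples.reset_index(drop=True)
        if list(probes.columns[:5]) != self.PROBE_COLS:
            raise ValueError(f"probe table must start with columns {self.PROBE_COLS}")
        if samples["sample_id"].duplicated().any():
            raise ValueError("sample ids are not unique")
        intensities = np.asarray(intensities, dtype=float)
        if intensities.shape != (len(probes), len(samples)):
            raise ValueError(
                f"intensity matrix shape {intensities.shape} does not match "
                f"{len(probes)} probes x {len(samples)} samples")
        if (probes["start"] >= probes["end"]).any():
            raise ValueError("probe intervals must satisfy start < end")
        sorted_idx = probes.sort_values(["chrom", "start"], kind="stable").index
        if not (sorted_idx == probes.index).all():
            raise ValueError("probes must be sorted by (chrom, start)")
        self.probes = probes
        self.samples = samples
        self.intensities = intensities

    def sample_index(self, sample_id: str) -> int:
        hits = self.samples.index[self.samples["sample_id"] == sample_id]
        if len(hits) == 0:
            raise KeyError(f"unknown sample {sample_id!r}")
        return int(hits[0])

    def sample_values(self, sample_id: str) -> np.ndarray:
        return self.intensities[:, self.sample_index(sample_id)]

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])


@dataclass(frozen=True)
class CallerParams:
    """Every numeric filter of the RIFT-calling rule set.

    Defaults follow the published rule set: probes are "high" above the
    per-sample mean + 1 SD (~log2 7 on calibrated arrays), a candidate needs
    >= 5 consecutive high probes within a gene, and the initiating L1 must be
    > 5 kb, of an active subfamily (T_F, A, G_F or F), antisense to the gene,
    and within 30 kb of the overlapping gene and/or 100 kb of the run probes.
    """

    sd_multiplier: float = 1.0
    min_run: int = 5
    gene_distance_kb: float = 30.0
    probe_distance_kb: float = 100.0
    min_l1_length_bp: int = 5000
    allowed_subfamilies: frozenset[str] = frozenset({"T_F", "A", "G_F", "F"})
    require_antisense: bool = True
    distance_mode: str = "or"  # "or" per the published "and/or"; "and" optional

    def __post_init__(self) -> None:
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        for name in ("gene_distance_kb", "probe_distance_kb", "min_l1_length_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.distance_mode not in ("or", "and"):
            raise ValueError("distance_mode must be 'or' or 'and'")


@dataclass(frozen=True)
class RunCall:
    """A maximal run of consecutive high probes within one gene and sample.

    ``probe_indices`` are row indices into the probe matrix, contiguous in
    the gene's genomic probe order.
    """

    gene_id: str
    sample_id: str
    probe_indices: tuple[int, ...]

    @property
    def run_length(self) -> int:
        return len(self.probe_indices)


@dataclass(frozen=True)
class RIFTCall:
    """A qualifying probe run matched to its predicted initiating L1."""

    gene_id: str
    sample_id: str
    run: RunCall
    l1_id: str
    dist_l1_gene_bp: int
    dist_l1_probe_bp: int
    filters_passed: dict[str, bool] = field(default_factory=dict)

    @property
    def identity_key(self) -> str:
        return f"{self.gene_id}:{self.l1_id}"


@dataclass(frozen=True)
class TranscriptClone:
    """An aligned cDNA clone (5' RACE product or phage library clone).

    ``blocks`` are aligned segments ``(chrom, start, end)`` in genomic
    order; ``strand`` is the alignment strand shared by all blocks.
    ``five_prime_genomic`` is the 0-based genomic position of the clone's
    5'-most aligned base (in the first block for '+' alignments, the last
    for '-').
    """

    clone_id: str
    tissue: str
    strain: str
    blocks: tuple[tuple[str, int, int], ...]
    strand: str
    five_prime_genomic: int
    has_polyA: bool = False

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"clone {self.clone_id}: no blocks")
        prev_end = -1
        for chrom, s, e in self.blocks:
            if s >= e:
                raise ValueError(f"clone {self.clone_id}: empty block")
            if s < prev_end:
                raise ValueError(f"clone {self.clone_id}: blocks overlap or unsorted")
            prev_end = e
        if self.strand not in ("+", "-"):
            raise ValueError(f"clone {self.clone_id}: bad strand")
        fp_block = self.blocks[0] if self.strand == "+" else self.blocks[-1]
        if not (fp_block[1] <= self.five_prime_genomic < fp_block[2]):
            raise ValueError(
                f"clone {self.clone_id}: 5' end not in the strand-consistent "
                f"terminal block")

    @property
    def spliced(self) -> bool:
        return len(self.blocks) >= 2

    @property
    def chrom(self) -> str:
        return self.blocks[0][0]


@dataclass(frozen=True)
class L1Reference:
    """A full-length L1 reference element (L1spa-like) anchoring coordinates.

    ``landmarks`` maps region names (``five_utr``, ``orf1``, ``orf2``,
    ``three_utr``) to 1-based inclusive ``(start, end)`` sense coordinates.
    ``sense_sequence`` is optional: coordinate-only workflows leave it None.
    """

    name: str
    length: int
    sense_sequence: Optional[str] = None
    landmarks: dict[str, Interval] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sense_sequence is not None and len(self.sense_sequence) != self.length:
            raise ValueError("sense_sequence length disagrees with declared length")
        prev = 0
        for name in ("five_utr", "orf1", "orf2", "three_utr"):
            if name in self.landmarks:
                lo, hi = self.landmarks[name]
                if not (1 <= lo <= hi <= self.length):
                    raise ValueError(f"landmark {name} outside [1, {self.length}]")
                if lo <= prev:
                    raise ValueError("landmarks out of order")
                prev = hi

    def sense_slice(self, lo: int, hi: int) -> str:
        """Sense-strand nucleotides for 1-based inclusive [lo, hi]."""
        if self.sense_sequence is None:
            raise ValueError(f"{self.name}: no sequence attached")
        if not (1 <= lo <= hi <= self.length):
            raise ValueError(f"window ({lo},{hi}) outside [1,{self.length}]")
        return self.sense_sequence[lo - 1:hi]


@dataclass(frozen=True)
class SpliceDonorCall:
    """A splice-donor junction between an antisense L1 block and the next exon.

    ``exonic4`` is the last 4 nt on the transcript (exon) side, upper case;
    ``intronic5`` the first 5 nt of the intron on the transcript strand,
    lower case.  Canonical donors start the intron with ``gt``.
    """

    clone_id: str
    exonic4: str
    intronic5: str
    l1_sense_coord: int
    valid: bool

    @property
    def donor_9mer(self) -> str:
        return self.exonic4 + self.intronic5


@dataclass(frozen=True)
class RIFTCatalog:
    """A labelled set of RIFT identity keys for cross-group comparison."""

    label: str
    keys: frozenset[str]
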