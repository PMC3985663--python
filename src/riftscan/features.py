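"""Transcript-level characterization of antisense-L1 fusion transcripts.

Classifies aligned cDNA clones, maps antisense transcription start sites
onto L1 sense coordinates, extracts splice donor junctions, scans for
antisense translation starts and summarizes donor usage.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Optional, Sequence

import pandas as pd

from .coords import genomic_to_l1
from .models import (L1Integrant, L1Reference, SpliceDonorCall,
                     TranscriptClone)
from .summaries import proportion_summary
from .synthetic import revcomp

logger = logging.getLogger(__name__)

SPLICED_AS_RIFT = "SPLICED_AS_RIFT"
UNSPLICED_AS_RIFT = "UNSPLICED_AS_RIFT"
PREMATURE_SENSE_POLYA = "PREMATURE_SENSE_POLYA"
OTHER = "OTHER"

CLASS_LABELS = (SPLICED_AS_RIFT, UNSPLICED_AS_RIFT, PREMATURE_SENSE_POLYA,
                OTHER)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _five_prime_block(clone: TranscriptClone) -> tuple[str, int, int]:
    return clone.blocks[0] if clone.strand == "+" else clone.blocks[-1]


def assign_l1(clone: TranscriptClone,
              l1s: Sequence[L1Integrant]) -> Optional[L1Integrant]:
    """The L1 whose span contains the clone's 5' end (if any).

    A clone overlapping two elements is assigned to the one containing the
    5' end; ties (nested elements) go to the smaller l1_id.
    """
    hits = [l1 for l1 in l1s
            if l1.chrom == clone.chrom
            and l1.start <= clone.five_prime_genomic < l1.end]
    if not hits:
        return None
    return min(hits, key=lambda l1: l1.l1_id)


def classify_clone(clone: TranscriptClone,
                   l1s: Sequence[L1Integrant]) -> str:
    """Assign one of the four clone classes.

    A clone whose 5' block lies in an L1 read antiparallel to the element's
    sense strand is antisense (AS).  AS clones with a block outside the L1
    are spliced AS RIFTs; a single AS block running through the element's
    5' end into flanking sequence is an unspliced AS RIFT; a sense-strand
    poly(A)+ clone contained in the element is a prematurely polyadenylated
    sense transcript; everything else is OTHER.
    """
    chrom, fp_start, fp_end = _five_prime_block(clone)
    candidates = [l1 for l1 in l1s if l1.chrom == chrom
                  and _overlap((fp_start, fp_end), (l1.start, l1.end))]
    if not candidates:
        return OTHER
    l1 = (assign_l1(clone, candidates)
          or min(candidates, key=lambda e: e.l1_id))
    antisense = clone.strand != l1.strand
    if antisense:
        if clone.spliced:
            # >=2 blocks with at least one block (partly) outside the L1
            outside = any(s < l1.start or e > l1.end
                          for _, s, e in clone.blocks)
            if outside:
                return SPLICED_AS_RIFT
        else:
            _, s, e = clone.blocks[0]
            crosses_5p = e > l1.end if l1.strand == "-" else s < l1.start
            if crosses_5p:
                return UNSPLICED_AS_RIFT
        return OTHER
    # sense orientation relative to the L1
    if (not clone.spliced) and clone.has_polyA:
        _, s, e = clone.blocks[0]
        if s >= l1.start and e <= l1.end:
            return PREMATURE_SENSE_POLYA
    return OTHER


def class_counts(clones: Iterable[TranscriptClone],
                 l1s: Sequence[L1Integrant]) -> pd.DataFrame:
    """Clone class tally with percent of total, one row per class."""
    counts = Counter(classify_clone(c, l1s) for c in clones)
    total = sum(counts.values())
    rows = [(label, counts.get(label, 0),
             proportion_summary(counts.get(label, 0), total) if total else 0)
            for label in CLASS_LABELS]
    return pd.DataFrame(rows, columns=["clone_class", "count", "percent"])


def map_tss(clones: Iterable[TranscriptClone], l1s: Sequence[L1Integrant],
            ref: Optional[L1Reference] = None,
            ) -> dict[str, Counter]:
    """Per-tissue distribution of antisense TSS in L1 sense coordinates.

    Each clone's genomic 5' end is converted to the 1-based sense
    coordinate of the containing L1 integrant; clones whose 5' end falls
    outside every annotated L1 are skipped and logged.
    """
    dist: dict[str, Counter] = {}
    for clone in clones:
        l1 = assign_l1(clone, l1s)
        if l1 is None:
            logger.info("map_tss: clone %s 5' end outside all L1s; skipped",
                        clone.clone_id)
            continue
        coord = genomic_to_l1(clone.five_prime_genomic, l1)
        if ref is not None and coord > ref.length:
            logger.warning("map_tss: clone %s maps beyond the reference",
                           clone.clone_id)
        dist.setdefault(clone.tissue, Counter())[coord] += 1
    return dist


def find_splice_donors(clone: TranscriptClone, l1s: Sequence[L1Integrant],
                       ref: L1Reference) -> Optional[SpliceDonorCall]:
    """Splice donor at the junction between the L1 block and the next block.

    The junction is anchored at the L1 sense coordinate of the last exonic
    base of the L1 block.  On the antisense transcript the exonic 4-mer is
    the reverse complement of reference sense positions [j, j+3] and the
    intronic 5-mer the reverse complement of [j-5, j-1].  A call is valid
    when the intron starts with "gt".
    """
    if not clone.spliced:
        return None
    l1 = assign_l1(clone, l1s)
    if l1 is None:
        return None
    if l1.strand == "-":
        # antisense transcript runs left->right on the genome; the L1 block
        # is the clone's first block and ends at its right edge
        _, bs, be = clone.blocks[0]
        junction_genomic = be - 1
    else:
        _, bs, be = clone.blocks[-1]
        junction_genomic = bs
    j = genomic_to_l1(junction_genomic, l1)
    if not (6 <= j <= ref.length - 3):
        logger.warning("donor junction %d of clone %s too close to the "
                       "reference edge", j, clone.clone_id)
        return None
    exonic4 = revcomp(ref.sense_slice(j, j + 3)).upper()
    intronic5 = revcomp(ref.sense_slice(j - 5, j - 1)).lower()
    return SpliceDonorCall(clone_id=clone.clone_id, exonic4=exonic4,
                           intronic5=intronic5, l1_sense_coord=j,
                           valid=intronic5.startswith("gt"))


def scan_atg(ref: L1Reference, window: tuple[int, int],
             ) -> list[tuple[int, int, int]]:
    """Antisense ATG occurrences within a sense-coordinate window.

    The window ``(lo, hi)`` (1-based inclusive sense coordinates) is
    reverse-complemented and scanned; each hit is reported as
    ``(as_offset, frame, l1_sense_coord)`` where ``as_offset`` is the
    0-based position on the antisense sequence, ``frame`` is
    ``as_offset % 3`` relative to the antisense transcript start, and
    ``l1_sense_coord`` is the sense coordinate of the A (``hi - as_offset``).
    """
    lo, hi = window
    as_seq = revcomp(ref.sense_slice(lo, hi)).upper()
    hits = []
    pos = as_seq.find("ATG")
    while pos != -1:
        hits.append((pos, pos % 3, hi - pos))
        pos = as_seq.find("ATG", pos + 1)
    return hits


def summarize_donor_usage(calls: Sequence[SpliceDonorCall]) -> pd.DataFrame:
    """Donor 9-mer usage table: count and integer percent of spliced clones."""
    if not calls:
        return pd.DataFrame(columns=["donor", "count", "percent"])
    counts = Counter(c.donor_9mer for c in calls)
    total = len(calls)
    rows = [(donor, n, proportion_summary(n, total))
            for donor, n in sorted(counts.items(),
                                   key=lambda kv: (-kv[1], kv[0]))]
    return pd.DataFrame(rows, columns=["donor", "count", "percent"])
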