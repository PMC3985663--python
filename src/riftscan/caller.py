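"""The RIFT-calling rule set.

A candidate retrotransposon-initiated fusion transcript (RIFT) is scored
from exon-array probe intensities in four steps:

1. per-sample intensity threshold = mean + ``sd_multiplier`` * SD over all
   probes of the sample (sample SD, n-1 denominator);
2. probes strictly above the threshold are "high";
3. within each gene, maximal runs of >= ``min_run`` consecutive high probes
   (consecutive = adjacent in the gene's genomic probe order) are collected;
4. each run is joined to a candidate initiating L1 integrant that must be
   full-length (> ``min_l1_length_bp``), of an active subfamily (T_F, A,
   G_F or F), antisense to the gene, and within ``gene_distance_kb`` of the
   gene span and/or ``probe_distance_kb`` of the run probes.

Calling is strain-aware: an L1 absent from a sample's strain is never a
candidate for that sample.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .models import (CallerParams, GeneModel, GenomeAnnotation, L1Integrant,
                     ProbeMatrix, RIFTCall, RunCall)

logger = logging.getLogger(__name__)

# RepeatMasker repeat name -> canonical active-subfamily label.  Prefix
# matching, case-insensitive; user-overridable in normalize_subfamily().
DEFAULT_SUBFAMILY_TABLE: tuple[tuple[str, str], ...] = (
    (r"^L1Md_T", "T_F"),
    (r"^L1Md_Gf", "G_F"),
    (r"^L1Md_A", "A"),
    (r"^L1Md_F", "F"),
    (r"^L1_Mus", "F"),
)


def normalize_subfamily(name: str,
                        table: Sequence[tuple[str, str]] = DEFAULT_SUBFAMILY_TABLE,
                        ) -> Optional[str]:
    """Map a RepeatMasker repeat name to its canonical subfamily label.

    Returns None for names outside the table (e.g. ancient Lx elements).
    Canonical labels (``T_F`` etc.) pass through unchanged.
    """
    canonical = {label for _, label in table}
    if name in canonical:
        return name
    for pattern, label in table:
        if re.match(pattern, name, flags=re.IGNORECASE):
            return label
    return None


def interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Nearest-edge (gap) distance between two half-open intervals; 0 on overlap."""
    if a_end <= b_start:
        return b_start - a_end
    if b_end <= a_start:
        return a_start - b_end
    return 0


def compute_threshold(matrix: ProbeMatrix, sample_id: str,
                      params: CallerParams = CallerParams()) -> float:
    """Per-sample high-expression threshold: mean + sd_multiplier * sample SD."""
    values = matrix.sample_values(sample_id)
    if len(values) < 2:
        raise ValueError("need >= 2 probes to estimate a threshold")
    return float(values.mean() + params.sd_multiplier * values.std(ddof=1))


def call_high_probes(matrix: ProbeMatrix, sample_id: str,
                     threshold: float) -> np.ndarray:
    """Boolean flag per probe: intensity strictly above the threshold."""
    if np.isnan(threshold) or threshold == np.inf:
        raise ValueError("threshold must be finite or -inf")
    return matrix.sample_values(sample_id) > threshold


def find_runs(matrix: ProbeMatrix, sample_id: str, high_flags: np.ndarray,
              params: CallerParams = CallerParams()) -> list[RunCall]:
    """Maximal runs of >= min_run consecutive high probes within each gene.

    Probes are taken in genomic order within each gene's probe list; probes
    without a gene assignment are ignored.  Runs are maximal: they cannot be
    extended by another high probe of the same gene.
    """
    high_flags = np.asarray(high_flags, dtype=bool)
    if len(high_flags) != matrix.n_probes:
        raise ValueError("flag vector length does not match probe count")
    runs: list[RunCall] = []
    # probe table is (chrom, start)-sorted, so a stable groupby preserves
    # genomic order within each gene
    for gene_id, group in matrix.probes.groupby("gene_id", sort=True):
        if gene_id is None or (isinstance(gene_id, float) and np.isnan(gene_id)) \
                or gene_id == "":
            continue
        idx = group.index.to_numpy()
        flags = high_flags[idx]
        start = None
        for i, f in enumerate(np.append(flags, False)):
            if f and start is None:
                start = i
            elif not f and start is not None:
                if i - start >= params.min_run:
                    runs.append(RunCall(gene_id=str(gene_id),
                                        sample_id=sample_id,
                                        probe_indices=tuple(int(j) for j in
                                                            idx[start:i])))
                start = None
    runs.sort(key=lambda r: (r.gene_id, r.probe_indices[0]))
    return runs


def l1_passes_static_filters(l1: L1Integrant, gene: GeneModel,
                             params: CallerParams) -> dict[str, bool]:
    """Per-filter evidence flags for an (L1, gene) pair, distance excluded."""
    sub = normalize_subfamily(l1.subfamily)
    return {
        "full_length": l1.full_length and l1.length > params.min_l1_length_bp,
        "subfamily": sub is not None and sub in params.allowed_subfamilies,
        "antisense": (not params.require_antisense) or (l1.strand != gene.strand),
        "same_chrom": l1.chrom == gene.chrom,
    }


def find_initiating_l1(run: RunCall, probes: pd.DataFrame,
                       annotation: GenomeAnnotation,
                       params: CallerParams = CallerParams(),
                       l1s: Optional[Sequence[L1Integrant]] = None,
                       attrition: Optional[Counter] = None,
                       ) -> Optional[tuple[L1Integrant, int, int]]:
    """Best candidate initiating L1 for a probe run, or None.

    Returns ``(l1, dist_to_gene_bp, dist_to_nearest_run_probe_bp)``.  Among
    surviving candidates the one minimizing the probe distance wins, ties
    broken by lexicographically smaller l1_id.
    """
    gene = annotation.gene(run.gene_id)
    if l1s is None:
        l1s = annotation.l1s
    probe_rows = probes.loc[list(run.probe_indices)]
    best: Optional[tuple[int, str, L1Integrant, int]] = None
    gene_limit = int(params.gene_distance_kb * 1000)
    probe_limit = int(params.probe_distance_kb * 1000)
    for l1 in l1s:
        flags = l1_passes_static_filters(l1, gene, params)
        if attrition is not None:
            for name, ok in flags.items():
                if not ok:
                    attrition[name] += 1
        if not all(flags.values()):
            continue
        dist_gene = interval_gap(l1.start, l1.end, gene.start, gene.end)
        dist_probe = min(interval_gap(l1.start, l1.end, int(r.start), int(r.end))
                         for r in probe_rows.itertuples())
        gene_ok = dist_gene <= gene_limit
        probe_ok = dist_probe <= probe_limit
        distance_ok = (gene_ok or probe_ok) if params.distance_mode == "or" \
            else (gene_ok and probe_ok)
        if not distance_ok:
            if attrition is not None:
                attrition["distance"] += 1
            continue
        key = (dist_probe, l1.l1_id)
        if best is None or key < (best[0], best[1]):
            best = (dist_probe, l1.l1_id, l1, dist_gene)
    if best is None:
        return None
    dist_probe, _, l1, dist_gene = best
    return l1, dist_gene, dist_probe


def call_rifts(matrix: ProbeMatrix, annotation: GenomeAnnotation,
               params: CallerParams = CallerParams()) -> list[RIFTCall]:
    """Run the full rule set over every sample of a probe matrix."""
    matrix_chroms = set(matrix.probes["chrom"].unique())
    if annotation.chroms and not matrix_chroms <= annotation.chroms:
        raise ValueError(
            f"probe chromosomes {sorted(matrix_chroms - annotation.chroms)} "
            f"absent from the annotation")
    calls: list[RIFTCall] = []
    attrition: Counter = Counter()
    for _, sample in matrix.samples.iterrows():
        sample_id, strain = sample["sample_id"], sample["strain"]
        threshold = compute_threshold(matrix, sample_id, params)
        flags = call_high_probes(matrix, sample_id, threshold)
        runs = find_runs(matrix, sample_id, flags, params)
        attrition[f"{sample_id}:high_probes"] = int(flags.sum())
        attrition[f"{sample_id}:runs"] = len(runs)
        candidates = [l1 for l1 in annotation.l1s if strain in l1.present_in]
        for run in runs:
            hit = find_initiating_l1(run, matrix.probes, annotation, params,
                                     l1s=candidates, attrition=attrition)
            if hit is None:
                continue
            l1, dist_gene, dist_probe = hit
            gene = annotation.gene(run.gene_id)
            flags_passed = l1_passes_static_filters(l1, gene, params)
            flags_passed["distance"] = True
            flags_passed["strain"] = True
            calls.append(RIFTCall(gene_id=run.gene_id, sample_id=sample_id,
                                  run=run, l1_id=l1.l1_id,
                                  dist_l1_gene_bp=dist_gene,
                                  dist_l1_probe_bp=dist_probe,
                                  filters_passed=flags_passed))
    logger.info("call_rifts attrition: %s", dict(attrition))
    return calls


def build_l1_tree(l1s: Iterable[L1Integrant]) -> IntervalTree:
    """Interval tree over L1 integrants keyed by genomic span (one chrom)."""
    tree = IntervalTree()
    for l1 in l1s:
        tree[l1.start:l1.end] = l1
    return tree
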