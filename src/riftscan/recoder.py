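"""Synonymous ORF recoding under A/T-content constraints.

The design goal mirrors the construction of an antisense-promoter-dead L1
donor: change as many nucleotides as possible without touching the encoded
protein, while either keeping the overall A/T fraction of the fragment
essentially unchanged (``neutral_AT`` mode — the behaviour of natural-base-
composition recodings) or driving it as low as the synonymous code allows
(``min_AT`` mode — the behaviour of GC-maximized synthetic elements).

Algorithm: for every codon the synonymous alternatives at maximal Hamming
distance from the original are enumerated (per-codon optimal by exhaustive
search over the <=6 synonyms).  ``min_AT`` picks the G/C-richest of those;
``neutral_AT`` starts from the lexicographically smallest choice and runs a
repair pass that swaps individual codons — always within the
maximal-distance set — toward the deficient base class until the global
A/T difference is within tolerance.  Ties break lexicographically, so the
result is deterministic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

MODES = ("neutral_AT", "min_AT")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]", "K": "[GT]",
    "M": "[AC]", "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]",
    "N": "[ACGT]",
}


@dataclass(frozen=True)
class CodingSequence:
    """A protein-coding nucleotide sequence (length divisible by 3)."""

    seq_id: str
    nucleotides: str
    table_id: int = 1
    allow_internal_stops: bool = False

    def __post_init__(self) -> None:
        nt = self.nucleotides.upper()
        object.__setattr__(self, "nucleotides", nt)
        if len(nt) % 3 != 0:
            raise ValueError(f"{self.seq_id}: length {len(nt)} not divisible by 3")
        if not re.fullmatch("[ACGT]*", nt):
            raise ValueError(f"{self.seq_id}: non-ACGT characters")
        if not self.allow_internal_stops:
            aa = str(Seq(nt).translate(table=self.table_id))
            if "*" in aa[:-1]:
                raise ValueError(f"{self.seq_id}: internal stop codon")

    @property
    def codons(self) -> list[str]:
        return [self.nucleotides[i:i + 3]
                for i in range(0, len(self.nucleotides), 3)]

    def translate(self) -> str:
        return str(Seq(self.nucleotides).translate(table=self.table_id))


@dataclass(frozen=True)
class RecodedSequence:
    """A recoding result with its divergence and base-composition statistics."""

    original: CodingSequence
    recoded: CodingSequence
    nt_identity: float
    codons_changed: int
    at_original: float
    at_recoded: float
    mode: str
    at_feasible: bool = True


@lru_cache(maxsize=8)
def synonym_table(table_id: int = 1) -> dict[str, tuple[str, ...]]:
    """codon -> all codons encoding the same amino acid (stops included)."""
    table = unambiguous_dna_by_id[table_id]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    by_aa["*"] = list(table.stop_codons)
    out = {}
    for aa, codons in by_aa.items():
        group = tuple(sorted(codons))
        for c in codons:
            out[c] = group
    return out


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def at_count(seq: str) -> int:
    return seq.count("A") + seq.count("T")


def at_fraction(seq: str) -> float:
    return at_count(seq) / len(seq) if seq else 0.0


def max_distance_synonyms(codon: str, table_id: int = 1) -> tuple[str, ...]:
    """Synonymous codons at maximal Hamming distance from ``codon``.

    For Met/Trp (no alternative) the set is the codon itself, distance 0.
    """
    syn = synonym_table(table_id).get(codon)
    if syn is None:
        raise ValueError(f"invalid codon {codon!r}")
    alternatives = [c for c in syn if c != codon]
    if not alternatives:
        return (codon,)
    best = max(hamming(codon, c) for c in alternatives)
    return tuple(sorted(c for c in alternatives if hamming(codon, c) == best))


def recode_orf(cds: CodingSequence, mode: str = "neutral_AT",
               at_tolerance: float = 0.01, seed: int = 0) -> RecodedSequence:
    """Recode every codon to a maximally diverged synonym.

    ``neutral_AT`` keeps |AT(recoded) - AT(original)| <= ``at_tolerance``
    whenever the maximal-distance candidate sets allow it (``at_feasible``
    reports whether they did); ``min_AT`` picks the G/C-richest
    maximal-distance synonym per codon.  Deterministic for a given input;
    ``seed`` is accepted for interface symmetry with the generators.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    candidates = [max_distance_synonyms(c, cds.table_id) for c in cds.codons]

    if mode == "min_AT":
        chosen = [min(cset, key=lambda c: (at_count(c), c))
                  for cset in candidates]
        feasible = True
    else:
        chosen = [cset[0] for cset in candidates]  # lexicographic start
        n = len(cds.nucleotides)
        target = at_count(cds.nucleotides)
        budget = at_tolerance * n
        diff = sum(at_count(c) for c in chosen) - target
        while abs(diff) > budget + 1e-9:
            best_swap: Optional[tuple[float, int, str]] = None
            for i, cset in enumerate(candidates):
                cur = chosen[i]
                for alt in cset:
                    if alt == cur:
                        continue
                    new_diff = diff + at_count(alt) - at_count(cur)
                    if abs(new_diff) < abs(diff) - 1e-9:
                        key = (abs(new_diff), i, alt)
                        if best_swap is None or key < best_swap:
                            best_swap = key
            if best_swap is None:
                break
            _, i, alt = best_swap
            diff += at_count(alt) - at_count(chosen[i])
            chosen[i] = alt
        feasible = abs(diff) <= budget + 1e-9

    recoded = CodingSequence(seq_id=f"{cds.seq_id}|recoded_{mode}",
                             nucleotides="".join(chosen),
                             table_id=cds.table_id,
                             allow_internal_stops=cds.allow_internal_stops)
    assert recoded.translate() == cds.translate()
    identity, changed, at_o, at_r = recode_stats(cds, recoded)
    return RecodedSequence(original=cds, recoded=recoded,
                           nt_identity=identity, codons_changed=changed,
                           at_original=at_o, at_recoded=at_r, mode=mode,
                           at_feasible=feasible)


def recode_stats(original: CodingSequence, recoded: CodingSequence,
                 ) -> tuple[float, int, float, float]:
    """(nt identity fraction, codons changed, A/T original, A/T recoded)."""
    a, b = original.nucleotides, recoded.nucleotides
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    identity = sum(x == y for x, y in zip(a, b)) / len(a) if a else 1.0
    changed = sum(ca != cb for ca, cb in zip(original.codons, recoded.codons))
    return identity, changed, at_fraction(a), at_fraction(b)


def iupac_regex(pattern: str) -> re.Pattern:
    try:
        return re.compile("".join(IUPAC[ch] for ch in pattern.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC symbol {exc.args[0]!r} in "
                         f"{pattern!r}") from None


def count_motif(seq: str, pattern: str, both_strands: bool = False) -> int:
    """Overlapping IUPAC motif matches in ``seq`` (optionally both strands)."""
    rx = iupac_regex(pattern)
    n = len(re.findall(f"(?={rx.pattern})", seq.upper()))
    if both_strands:
        comp = str.maketrans("ACGT", "TGCA")
        rc = seq.upper().translate(comp)[::-1]
        n += len(re.findall(f"(?={rx.pattern})", rc))
    return n


def motif_disruption(original: CodingSequence, recoded: CodingSequence,
                     catalog: Sequence[tuple[str, str]],
                     both_strands: bool = True) -> list[dict]:
    """Per-motif occurrence counts before/after recoding.

    ``disrupted`` = count_original - count_recoded; a negative value means
    the recoding created new sites and is reported as-is.
    """
    if not catalog:
        raise ValueError("motif catalog is empty")
    rows = []
    for name, pattern in catalog:
        n_orig = count_motif(original.nucleotides, pattern, both_strands)
        n_rec = count_motif(recoded.nucleotides, pattern, both_strands)
        rows.append({"motif": name, "pattern": pattern,
                     "count_original": n_orig, "count_recoded": n_rec,
                     "disrupted": n_orig - n_rec})
    return rows
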