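"""Readers and writers for the pipeline's on-disk formats.

Gene models travel as GFF3 (1-based inclusive on disk) or BED12 (0-based
half-open); L1 integrants as BED6 plus three extra columns (subfamily,
full_length, comma-separated strain presence); probes plus intensities as
a TSV with one column per sample; clones as BED12 with tissue/strain/polyA
packed into the name field; generator configuration as YAML.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd
import yaml

from .models import (GeneModel, GenomeAnnotation, L1Integrant, PlantedRIFT,
                     ProbeMatrix, RIFTCall, TranscriptClone)
from .synthetic import GeneratorConfig

PathLike = Union[str, Path]


class ParseError(ValueError):
    """A malformed line in an input file (message carries the line number)."""


# ---------------------------------------------------------------- gene models

def write_gff3(genes: Iterable[GeneModel], path: PathLike) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        lines.append("\t".join([
            g.chrom, "riftscan", "gene", str(g.start + 1), str(g.end), ".",
            g.strand, ".", f"ID={g.gene_id}"]))
        for i, (s, e) in enumerate(g.exons):
            lines.append("\t".join([
                g.chrom, "riftscan", "exon", str(s + 1), str(e), ".",
                g.strand, ".", f"ID={g.gene_id}.e{i};Parent={g.gene_id}"]))
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_gff3(path: Path) -> list[GeneModel]:
    strands: dict[str, str] = {}
    chroms: dict[str, str] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns, "
                             f"got {len(fields)}")
        chrom, _, ftype, start, end, _, strand, _, attrs = fields
        try:
            start_i, end_i = int(start) - 1, int(end)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates")
        attr_map = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        if ftype == "gene":
            gid = attr_map.get("ID")
            if gid is None:
                raise ParseError(f"{path}:{lineno}: gene without ID")
            strands[gid] = strand
            chroms[gid] = chrom
            order.append(gid)
        elif ftype == "exon":
            parent = attr_map.get("Parent")
            if parent is None:
                raise ParseError(f"{path}:{lineno}: exon without Parent")
            exons.setdefault(parent, []).append((start_i, end_i))
            strands.setdefault(parent, strand)
            chroms.setdefault(parent, chrom)
            if parent not in order:
                order.append(parent)
    return [GeneModel(gene_id=gid, chrom=chroms[gid], strand=strands[gid],
                      exons=tuple(sorted(exons.get(gid, []))))
            for gid in order]


def write_bed12_genes(genes: Iterable[GeneModel], path: PathLike) -> None:
    rows = []
    for g in genes:
        sizes = ",".join(str(e - s) for s, e in g.exons)
        starts = ",".join(str(s - g.start) for s, _ in g.exons)
        rows.append([g.chrom, g.start, g.end, g.gene_id, 0, g.strand,
                     g.start, g.end, "0", len(g.exons), sizes, starts])
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def _parse_bed12_rows(path: Path) -> list[tuple[list[str], int]]:
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ParseError(f"{path}:{lineno}: expected 12 BED columns, "
                             f"got {len(fields)}")
        rows.append((fields, lineno))
    return rows


def _blocks_from_bed12(fields: list[str], path: Path, lineno: int,
                       ) -> tuple[str, str, str, list[tuple[int, int]]]:
    try:
        chrom, start = fields[0], int(fields[1])
        name, strand = fields[3], fields[5]
        n_blocks = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
    except ValueError:
        raise ParseError(f"{path}:{lineno}: malformed BED12 fields")
    if len(sizes) != n_blocks or len(offsets) != n_blocks:
        raise ParseError(f"{path}:{lineno}: blockCount disagrees with "
                         f"blockSizes/blockStarts")
    blocks = [(start + o, start + o + sz) for o, sz in zip(offsets, sizes)]
    return chrom, name, strand, blocks


def read_gene_models(path: PathLike) -> list[GeneModel]:
    """Read gene models from GFF3 (.gff/.gff3) or BED12 (.bed)."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"gene model file not found: {p}")
    if p.suffix.lower() in (".gff", ".gff3"):
        return _parse_gff3(p)
    genes = []
    for fields, lineno in _parse_bed12_rows(p):
        chrom, name, strand, blocks = _blocks_from_bed12(fields, p, lineno)
        genes.append(GeneModel(gene_id=name, chrom=chrom, strand=strand,
                               exons=tuple(blocks)))
    return genes


# ---------------------------------------------------------------- L1 elements

def write_l1_bed(l1s: Iterable[L1Integrant], path: PathLike) -> None:
    rows = [[l1.chrom, l1.start, l1.end, l1.l1_id, 0, l1.strand,
             l1.subfamily, int(l1.full_length),
             ",".join(sorted(l1.present_in))] for l1 in l1s]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_l1_annotations(path: PathLike, full_length_min_bp: int = 5000,
                        default_strains: Sequence[str] = ("B6",),
                        ) -> list[L1Integrant]:
    """Read L1 integrants from BED6+ (extra cols: subfamily, full_length,
    present_in).  ``full_length`` is derived from the element length when
    the column is absent; unknown subfamily names pass through unchanged
    (the caller's subfamily filter will reject them).
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"L1 annotation file not found: {p}")
    out = []
    for lineno, line in enumerate(p.read_text().splitlines(), start=1):
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise ParseError(f"{p}:{lineno}: expected >= 6 BED columns")
        try:
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name, strand = fields[3], fields[5]
        except ValueError:
            raise ParseError(f"{p}:{lineno}: malformed BED coordinates")
        subfamily = fields[6] if len(fields) > 6 else "unknown"
        if len(fields) > 7 and fields[7] != "":
            full_length = bool(int(fields[7]))
        else:
            full_length = (end - start) > full_length_min_bp
        if len(fields) > 8 and fields[8]:
            present = frozenset(fields[8].split(","))
        else:
            present = frozenset(default_strains)
        out.append(L1Integrant(l1_id=name, chrom=chrom, start=start, end=end,
                               strand=strand, subfamily=subfamily,
                               full_length=full_length, present_in=present))
    return out


# --------------------------------------------------------------- probe matrix

def write_probe_matrix(matrix: ProbeMatrix, path: PathLike) -> None:
    df = matrix.probes.copy()
    for j, sid in enumerate(matrix.sample_ids):
        df[sid] = matrix.intensities[:, j]
    with open(path, "w") as fh:
        strains = ",".join(matrix.samples["strain"])
        tissues = ",".join(matrix.samples["tissue"])
        fh.write(f"#strains={strains}\n#tissues={tissues}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_probe_matrix(path: PathLike) -> ProbeMatrix:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"probe matrix file not found: {p}")
    meta: dict[str, list[str]] = {}
    text = p.read_text().splitlines(keepends=True)
    n_header = 0
    for line in text:
        if not line.startswith("#"):
            break
        key, _, val = line[1:].strip().partition("=")
        meta[key] = val.split(",")
        n_header += 1
    df = pd.read_csv(io.StringIO("".join(text[n_header:])), sep="\t")
    probe_cols = ProbeMatrix.PROBE_COLS
    sample_ids = [c for c in df.columns if c not in probe_cols]
    strains = meta.get("strains", [s.split("_")[0] for s in sample_ids])
    tissues = meta.get("tissues",
                       [s.split("_", 1)[-1] for s in sample_ids])
    samples = pd.DataFrame({"sample_id": sample_ids, "strain": strains,
                            "tissue": tissues})
    return ProbeMatrix(df[probe_cols], samples,
                       df[sample_ids].to_numpy(dtype=float))


# --------------------------------------------------------------------- clones

def write_clones_bed12(clones: Iterable[TranscriptClone],
                       path: PathLike) -> None:
    rows = []
    for c in clones:
        start = c.blocks[0][1]
        end = c.blocks[-1][2]
        sizes = ",".join(str(e - s) for _, s, e in c.blocks)
        offsets = ",".join(str(s - start) for _, s, _ in c.blocks)
        name = f"{c.clone_id}|{c.tissue}|{c.strain}|{int(c.has_polyA)}"
        rows.append([c.chrom, start, end, name, 0, c.strand, start, end, "0",
                     len(c.blocks), sizes, offsets])
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_clones(path: PathLike) -> list[TranscriptClone]:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"clone file not found: {p}")
    clones = []
    for fields, lineno in _parse_bed12_rows(p):
        chrom, name, strand, blocks = _blocks_from_bed12(fields, p, lineno)
        parts = name.split("|")
        clone_id = parts[0]
        tissue = parts[1] if len(parts) > 1 else "unknown"
        strain = parts[2] if len(parts) > 2 else "unknown"
        polya = bool(int(parts[3])) if len(parts) > 3 else False
        fp = blocks[0][0] if strand == "+" else blocks[-1][1] - 1
        clones.append(TranscriptClone(
            clone_id=clone_id, tissue=tissue, strain=strain,
            blocks=tuple((chrom, s, e) for s, e in blocks), strand=strand,
            five_prime_genomic=fp, has_polyA=polya))
    return clones


# ------------------------------------------------------------- truth / config

def write_truth(planted: Sequence[PlantedRIFT], path: PathLike) -> None:
    records = []
    for r in planted:
        d = asdict(r)
        d["strains"] = sorted(r.strains)
        d["affected_exons"] = list(r.affected_exons)
        records.append(d)
    Path(path).write_text(json.dumps(records, indent=1, sort_keys=True) + "\n")


def read_truth(path: PathLike) -> list[PlantedRIFT]:
    records = json.loads(Path(path).read_text())
    return [PlantedRIFT(
        gene_id=d["gene_id"], l1_id=d["l1_id"],
        tss_l1_coord=d["tss_l1_coord"], spliced=d["spliced"],
        donor_motif=d["donor_motif"], donor_l1_coord=d["donor_l1_coord"],
        affected_exons=tuple(d["affected_exons"]), tissue=d["tissue"],
        strains=frozenset(d["strains"])) for d in records]


def _tuplify(obj):
    if isinstance(obj, list):
        return tuple(_tuplify(x) for x in obj)
    return obj


def _listify(obj):
    if isinstance(obj, tuple):
        return [_listify(x) for x in obj]
    return obj


def write_generator_config(config: GeneratorConfig, path: PathLike) -> None:
    data = {k: _listify(v) for k, v in asdict(config).items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def read_generator_config(path: PathLike) -> GeneratorConfig:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    data = yaml.safe_load(p.read_text()) or {}
    return GeneratorConfig(**{k: _tuplify(v) for k, v in data.items()})


# ---------------------------------------------------------------------- calls

def calls_to_records(calls: Sequence[RIFTCall]) -> list[dict]:
    return [{
        "gene_id": c.gene_id, "sample_id": c.sample_id, "l1_id": c.l1_id,
        "run_probes": list(c.run.probe_indices),
        "run_length": c.run.run_length,
        "dist_l1_gene_bp": c.dist_l1_gene_bp,
        "dist_l1_probe_bp": c.dist_l1_probe_bp,
        "filters_passed": c.filters_passed,
    } for c in calls]


def write_calls_json(calls: Sequence[RIFTCall], path: PathLike) -> None:
    Path(path).write_text(
        json.dumps(calls_to_records(calls), indent=1, sort_keys=True) + "\n")


def write_calls_bed(calls: Sequence[RIFTCall], annotation: GenomeAnnotation,
                    path: PathLike) -> None:
    """Calls as BED6 over the gene span; the name field links gene, L1 and
    sample as ``gene:l1:sample``."""
    rows = []
    for c in calls:
        gene = annotation.gene(c.gene_id)
        rows.append([gene.chrom, gene.start, gene.end,
                     f"{c.gene_id}:{c.l1_id}:{c.sample_id}",
                     c.run.run_length, gene.strand])
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
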