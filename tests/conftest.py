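"""Shared fixtures: small synthetic runs and hand-built probe matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import riftscan as rs
from riftscan.models import ProbeMatrix


def tiny_matrix(values, gene_ids=None, sample_id="s1", strain="B6",
                tissue="testis", start0=1000, step=100, chrom="chr1"):
    """A one-sample probe matrix from a flat list of intensities."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if gene_ids is None:
        gene_ids = ["geneA"] * n
    probes = pd.DataFrame({
        "probe_id": [f"p{i}" for i in range(n)],
        "chrom": chrom,
        "start": [start0 + i * step for i in range(n)],
        "end": [start0 + i * step + 25 for i in range(n)],
        "gene_id": gene_ids,
    })
    samples = pd.DataFrame({"sample_id": [sample_id], "strain": [strain],
                            "tissue": [tissue]})
    return ProbeMatrix(probes, samples, values.reshape(-1, 1))


@pytest.fixture(scope="session")
def default_config():
    return rs.GeneratorConfig(seed=11)


@pytest.fixture(scope="session")
def default_run(default_config):
    """One full synthetic dataset under the default study conditions."""
    ann = rs.gen_genome(default_config)
    planted = rs.plant_rifts(ann, default_config)
    matrix = rs.gen_probe_matrix(ann, planted, default_config)
    clones = rs.gen_transcript_clones(ann, planted, default_config)
    ref = rs.make_l1_reference(seed=default_config.seed)
    return {"config": default_config, "annotation": ann, "planted": planted,
            "matrix": matrix, "clones": clones, "ref": ref}
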