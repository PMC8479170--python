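"""Shared fixtures: tiny hand-built alignments and one full-scale simulated
plastome set (session-scoped; the default configuration is the study-design
fixture every end-to-end test shares)."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from plastdiv.alignment import AlignedGenomeSet
from plastdiv.annotation import AnnotationSet, Feature
from plastdiv.pipeline import run_analysis
from plastdiv.simulate import SimConfig, simulate
from plastdiv.structure import RegionPartition


@pytest.fixture(scope="session")
def sim():
    return simulate(SimConfig(), seed=1)


@pytest.fixture(scope="session")
def bundle(sim):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_analysis(sim.aln, sim.ann, sim.part)


@pytest.fixture
def toy_aln():
    """4 x 20 alignment with two SNP columns and one 3-bp deletion."""
    rows = {
        "ref": "ACGTACGTACGTACGTACGT",
        "s2":  "ACGTACGTACGTACGTACGT",
        "s3":  "ACTTACGTAC---CGTACGT",
        "s4":  "ACTTACGAACGTACGTACGT",
    }
    return AlignedGenomeSet.from_sequences(rows, "ref")


@pytest.fixture
def toy_partition():
    # 20-bp toy: LSC 8 | IRb 4 | SSC 3 | IRa 4  is invalid (lsc>ssc ok,
    # lengths must sum) -> use 9/4/3/4
    return RegionPartition((0, 9), (9, 13), (13, 16), (16, 20), 20)


@pytest.fixture
def one_gene_annotation():
    """Single plus-strand CDS covering positions [3, 12) of an 20-bp genome."""
    return AnnotationSet(
        [
            Feature("g1", "gene", "+", [(3, 12)]),
            Feature("g1", "CDS", "+", [(3, 12)], phases=[0]),
        ],
        20,
    )


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
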