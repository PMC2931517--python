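"""Shared fixtures: tiny hand-built architectures and random generators."""

from __future__ import annotations

import random

import pytest

from fact.architecture_model import (
    FeatureArchitecture,
    FeatureCatalog,
    FeatureInstance,
)
from fact.annotation_io import Proteome


@pytest.fixture
def gst_catalog() -> FeatureCatalog:
    """Two glutathione-transferase domains sharing one clan."""
    return FeatureCatalog(
        {"pfam:PF02798": "CL0172", "pfam:PF00043": "CL0172"},
        pfam_namespaces={"pfam"},
    )


@pytest.fixture
def gst_pair():
    """A glutathione-transferase-style pair: two shared Pfam domains plus a
    shared transmembrane segment; a signal peptide only in the query."""
    query = FeatureArchitecture(
        "HS_GST",
        230,
        [
            FeatureInstance("signalp:SP", 1, 22),
            FeatureInstance("pfam:PF02798", 30, 110),
            FeatureInstance("pfam:PF00043", 120, 210),
            FeatureInstance("tmhmm:TM", 211, 230),
        ],
    )
    subject = FeatureArchitecture(
        "SC_GST",
        220,
        [
            FeatureInstance("pfam:PF02798", 10, 95),
            FeatureInstance("pfam:PF00043", 105, 200),
            FeatureInstance("tmhmm:TM", 201, 220),
        ],
    )
    return query, subject


def random_architecture(
    rng: random.Random,
    protein_id: str,
    features=("A", "B", "C", "D", "E", "pfam:PF1", "pfam:PF2"),
    max_instances: int = 6,
    min_instances: int = 0,
    length_range=(50, 400),
) -> FeatureArchitecture:
    """Small random architecture for property tests (plain stdlib RNG)."""
    length = rng.randint(*length_range)
    n = rng.randint(min_instances, max_instances)
    instances = []
    for _ in range(n):
        fid = rng.choice(features)
        start = rng.randint(1, length)
        end = rng.randint(start, min(length, start + length // 3))
        instances.append(FeatureInstance(fid, start, end))
    return FeatureArchitecture(protein_id, length, instances)


@pytest.fixture
def random_pair_factory():
    """Seeded factory of random (subject, query, reference) triples."""

    def factory(seed: int):
        rng = random.Random(seed)
        p = random_architecture(rng, "P")
        q = random_architecture(rng, "Q")
        extras = [
            random_architecture(rng, f"R{i}", min_instances=1) for i in range(3)
        ]
        ref = Proteome([p, q] + extras)
        return p, q, ref

    return factory
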