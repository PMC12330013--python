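from __future__ import annotations

import numpy as np
import pytest

from sqmine.catalog import MiningParams, default_catalog
from sqmine.colocation import GeneCluster
from sqmine.genome_io import FamilyAssignment, GeneFeature


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture
def params():
    return MiningParams()


def make_features(labels, genome_id="g", contig_id="c", gene_len=900, gap=120,
                  start=1):
    """Features laid head-to-tail; labels only fix the gene count here."""
    feats = []
    pos = start
    for rank, _ in enumerate(labels):
        s, e = pos, pos + gene_len - 1
        pos = e + gap + 1
        feats.append(GeneFeature(genome_id, contig_id, rank, s, e, "+",
                                 f"{genome_id}_{contig_id}_gene{rank}"))
    return feats


def make_cluster(labels, bitscores=None, genome_id="g", contig_id="c",
                 cluster_id="cl", gene_len=900, gap=120):
    """Build a GeneCluster from family labels; None marks an unassigned gene.

    Genes are evenly spaced well inside the 3500-nt co-location limit, so
    the label sequence alone determines synteny behaviour.
    """
    if bitscores is None:
        bitscores = [150.0] * len(labels)
    feats = make_features(labels, genome_id, contig_id, gene_len, gap)
    members, intervening = [], []
    pending = 0
    for feat, lab, score in zip(feats, labels, bitscores):
        if lab is None:
            pending += 1
            continue
        if members:
            intervening.append(pending)
        pending = 0
        members.append((feat, FamilyAssignment(feat.gene_id, lab, score)))
    if not members:
        raise ValueError("cluster needs at least one assigned gene")
    return GeneCluster(cluster_id, genome_id, contig_id, tuple(members),
                       tuple(intervening))


def random_cluster(rng: np.random.Generator, families, decoys,
                   min_len=2, max_len=12):
    """Random label sequence over pattern families, decoy families and
    unassigned genes; at least one assigned gene guaranteed."""
    n = int(rng.integers(min_len, max_len + 1))
    pool = list(families) + list(decoys) + [None, None]
    labels = [pool[int(rng.integers(0, len(pool)))] for _ in range(n)]
    if all(l is None for l in labels):
        labels[int(rng.integers(0, n))] = families[0]
    scores = [float(rng.uniform(100.0, 250.0)) for _ in labels]
    return make_cluster(labels, scores)
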