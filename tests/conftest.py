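"""Shared fixtures: a small synthetic study and hand-built toy inputs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from epsbloom.model import MagRecord, MarkerGeneSet, OrfRecord
from epsbloom.simulate import (
    Community,
    SimulationConfig,
    generate_community,
    generate_counts,
    mag_id,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A compact planted-effect study: 12 MAGs, 30 samples, 2 active MAGs,
    one elevated and one unchanged alginate cluster."""
    return SimulationConfig(
        seed=11,
        n_mags=12,
        contigs_per_mag=2,
        mean_contig_kb=30.0,
        active_mags=(mag_id(0), mag_id(1)),
        eps_planted={mag_id(3): "alginate"},
        eps_null_planted={mag_id(4): "alginate"},
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    community = generate_community(small_config)
    counts, samples = generate_counts(community, small_config)
    return community, counts, samples


def make_orf(orf_id, mag="MAGA", contig="c1", start=1, length_bp=1000,
             annotations=(), strand="+"):
    return OrfRecord(
        orf_id=orf_id,
        mag_id=mag,
        contig_id=contig,
        start=start,
        end=start + length_bp - 1,
        strand=strand,
        annotations=frozenset(annotations),
    )


@pytest.fixture
def marker_toy():
    """One MAG with 10 marker ORFs (1 kb each) and one 1 kb test ORF.

    Per-sample marker counts are 2..11 reads (median rate 6.5 /kb) and the
    test ORF has 8 reads, so its MG-normalized value is 8/6.5.
    """
    from epsbloom.model import MARKER_COGS

    orfs = [make_orf("orf_t", start=1)]
    assignments = {"MAGA": {}}
    counts = {"orf_t": [8, 8]}
    for i, cog in enumerate(MARKER_COGS):
        oid = f"orf_m{i}"
        orfs.append(make_orf(oid, start=2000 * (i + 1)))
        assignments["MAGA"][cog] = oid
        counts[oid] = [i + 2, i + 2]
    matrix = pd.DataFrame(counts, index=["s1", "s2"])
    markers = MarkerGeneSet(assignments=assignments)
    return orfs, matrix, markers


@pytest.fixture
def toy_two_mags():
    """5 ORFs across 2 MAGs, 2 samples — small enough for straight-line
    arithmetic oracles.  Each MAG carries 2 marker ORFs (of the 10 families).
    """
    from epsbloom.model import MARKER_COGS

    orfs = [
        make_orf("a1", mag="MAGA", contig="cA", start=1, length_bp=1000),
        make_orf("a2", mag="MAGA", contig="cA", start=1500, length_bp=2000),
        make_orf("a3", mag="MAGA", contig="cA", start=4000, length_bp=500),
        make_orf("b1", mag="MAGB", contig="cB", start=1, length_bp=1000),
        make_orf("b2", mag="MAGB", contig="cB", start=1200, length_bp=4000),
    ]
    mags = [
        MagRecord(mag_id="MAGA", contigs=(("cA", 6000),)),
        MagRecord(mag_id="MAGB", contigs=(("cB", 6000),)),
    ]
    counts = pd.DataFrame(
        {
            "a1": [10, 3],
            "a2": [20, 0],
            "a3": [5, 7],
            "b1": [8, 12],
            "b2": [40, 9],
        },
        index=["s1", "s2"],
    )
    markers = MarkerGeneSet(
        assignments={
            "MAGA": {MARKER_COGS[0]: "a1", MARKER_COGS[1]: "a2"},
            "MAGB": {MARKER_COGS[0]: "b1", MARKER_COGS[1]: "b2"},
        }
    )
    return orfs, mags, counts, markers
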