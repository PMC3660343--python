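"""Shared fixtures: a default config and one small noise-free simulated
dataset (genome, CP family, physical map + BES, reference hits) reused by
the anchoring/integration/synteny tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from carpmap.dataio import PipelineConfig
from carpmap.simdata import (
    SimConfig,
    TrueGenome,
    TrueLG,
    TrueMarker,
    chromosome_lengths,
    simulate_cp_family,
    simulate_physical_and_bes,
    simulate_reference_placements,
    simulate_true_genome,
)


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@dataclass
class SimBundle:
    sim: SimConfig
    genome: TrueGenome
    family: object
    pm: object
    bes: dict
    marker_seqs: dict
    anchor_truth: pd.DataFrame
    ref_hits: list
    ref_truth: pd.DataFrame
    chrom_len: dict


def _make_bundle(sim: SimConfig) -> SimBundle:
    genome = simulate_true_genome(sim)
    family = simulate_cp_family(genome, sim)
    pm, bes, marker_seqs, anchor_truth = simulate_physical_and_bes(genome, sim)
    ref_hits, ref_truth = simulate_reference_placements(genome, sim, pm, anchor_truth)
    return SimBundle(
        sim, genome, family, pm, bes, marker_seqs, anchor_truth,
        ref_hits, ref_truth, chromosome_lengths(genome, sim),
    )


@pytest.fixture(scope="session")
def clean_sim() -> SimBundle:
    """4 LGs x 10 markers, 107 offspring, zero noise, no chimeric contigs."""
    return _make_bundle(
        SimConfig(
            n_lgs=4, markers_per_lg=10, n_contigs=16, n_offspring=107,
            missing_rate=0.0, distortion_frac=0.0, chimeric_fraction=0.0,
            dup_marker_count=3, seed=11,
        )
    )


@pytest.fixture(scope="session")
def chimeric_sim() -> SimBundle:
    """Same scale but with 2/16 contigs deliberately chimeric."""
    return _make_bundle(
        SimConfig(
            n_lgs=4, markers_per_lg=10, n_contigs=16, n_offspring=107,
            missing_rate=0.0, distortion_frac=0.0, chimeric_fraction=2 / 16,
            dup_marker_count=0, seed=23,
        )
    )


def true_map_from_genome(genome: TrueGenome):
    """GeneticMap matching the generator's truth exactly (for stages that
    are tested downstream of linkage)."""
    from carpmap.linkage import GeneticMap, LinkageGroupMap

    groups = []
    for g in genome.linkage_groups:
        ms = sorted(g.markers, key=lambda m: (m.position_cM, m.marker_id))
        groups.append(
            LinkageGroupMap(
                g.lg_id, [m.marker_id for m in ms],
                [m.position_cM - ms[0].position_cM for m in ms],
            )
        )
    return GeneticMap(groups)


def anchors_from_truth(anchor_truth: pd.DataFrame):
    """MarkerAnchor list equal to the generator's embedding truth."""
    from carpmap.anchoring import MarkerAnchor
    from carpmap.dataio import clone_of_bes

    return [
        MarkerAnchor(
            r.marker_id, r.bes_id, clone_of_bes(r.bes_id),
            r.target_kind, r.target_id, True,
        )
        for r in anchor_truth.itertuples()
    ]
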