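"""Shared fixtures: small hand-built objects and one default synthetic bundle."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from clonediv.seq_io import Alignment, CloneRecord, Haplotype, HaplotypeTable
from clonediv.simulate import SimulationParams, simulate_bundle

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def mutate_at(seq: str, positions, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    for p in positions:
        arr[p] = _BASES[_BASES != arr[p]][rng.integers(0, 3)]
    return arr.tobytes().decode()


def make_clones(seq_multiplicities, individual="I1", site="XX", replicate=1) -> list[CloneRecord]:
    """Clone records from (sequence, count) pairs, all from one individual."""
    clones = []
    i = 0
    for seq, count in seq_multiplicities:
        for _ in range(count):
            i += 1
            clones.append(
                CloneRecord(
                    clone_id=f"c{i:03d}",
                    individual_id=individual,
                    site_code=site,
                    pcr_replicate=replicate,
                    sequence=seq,
                )
            )
    return clones


def make_table(seq_counts) -> HaplotypeTable:
    """HaplotypeTable straight from (sequence, count) pairs (one carrier each)."""
    order = sorted(range(len(seq_counts)), key=lambda i: (-seq_counts[i][1], seq_counts[i][0]))
    width = max(3, len(str(len(seq_counts))))
    haps = []
    for rank, i in enumerate(order, start=1):
        seq, count = seq_counts[i]
        haps.append(
            Haplotype(f"H{rank:0{width}d}", seq, count, {"I1": count}, frozenset({"XX"}))
        )
    return HaplotypeTable(tuple(haps))


def make_alignment(seqs) -> Alignment:
    return Alignment(ids=tuple(f"s{i}" for i in range(len(seqs))), seqs=tuple(seqs))


@pytest.fixture(scope="session")
def default_params() -> SimulationParams:
    return SimulationParams()


@pytest.fixture(scope="session")
def bundle(default_params):
    """One default-parameter synthetic dataset shared across tests."""
    return simulate_bundle(default_params, seed=11)
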