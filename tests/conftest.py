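from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from milseek.discover import call_candidates, find_precursor_candidates, map_reads
from milseek.fold import fold_contig
from milseek.io import RunConfig, read_fasta, read_fastq
from milseek.preprocess import group_reads, preprocess_library
from milseek.simulate import default_truth, simulate_study


@pytest.fixture()
def config() -> RunConfig:
    return RunConfig()


def run_discovery(paths, adapter, config):
    """Shared plumbing: preprocess both libraries, fold, map, call."""
    my = preprocess_library(read_fastq(paths["srna_MY"]), adapter, config)
    fb = preprocess_library(read_fastq(paths["srna_FB"]), adapter, config)
    grouped = group_reads(my, fb)
    folded = []
    for contig in read_fasta(paths["contigs"], moltype="RNA"):
        folded.extend(fold_contig(contig, config))
    placements = map_reads(grouped, folded, mismatch_max=config.mismatch_max)
    precursors = find_precursor_candidates(placements, folded)
    candidates, precursor_calls = call_candidates(precursors, folded, config)
    return {
        "grouped": grouped,
        "folded": folded,
        "placements": placements,
        "precursors": precursors,
        "candidates": candidates,
        "precursor_calls": precursor_calls,
    }


@pytest.fixture(scope="session")
def clean_study(tmp_path_factory):
    """A clean (no noise, no background) 20-locus synthetic study with the
    full discovery pipeline already run on it."""
    truth = default_truth(seed=3, n_loci=20)
    out = tmp_path_factory.mktemp("clean_study")
    paths = simulate_study(truth, out)
    cfg = RunConfig()
    result = run_discovery(paths, truth.adapter, cfg)
    return {"truth": truth, "paths": paths, "config": cfg, **result}
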