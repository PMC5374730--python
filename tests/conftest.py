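import os
import random

import pytest

from methylhint.io_formats import FlatReference, read_cx_report
from methylhint.pipeline import PipelineConfig, run
from methylhint.simulate import SimulationParams, TruthTable, write_fixture


def make_ref(**chroms: str) -> FlatReference:
    ref = FlatReference()
    for name, seq in chroms.items():
        ref.chrom_names.append(name)
        ref.sequences[name] = seq
    return ref


def random_seq(rng: random.Random, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


@pytest.fixture(scope="session")
def seed7_run(tmp_path_factory):
    """Exact-regime fixture and pipeline run: 100 groups, no noise, seed 7."""
    base = tmp_path_factory.mktemp("seed7")
    params = SimulationParams(seed=7, n_groups=100)
    paths = write_fixture(params, str(base / "fixture"))
    out = str(base / "out")
    summary = run(PipelineConfig(), paths["reference"], paths["targets"], out)
    return {
        "params": params,
        "paths": paths,
        "out": out,
        "summary": summary,
        "truth": TruthTable.read_tsv(paths["truth_cytosines"], paths["truth_groups"]),
        "counts": read_cx_report(os.path.join(out, "methylation_cx.tsv")),
    }


@pytest.fixture(scope="session")
def seed42_fixture(tmp_path_factory):
    """Fixture for the serial/parallel equivalence matrix."""
    base = tmp_path_factory.mktemp("seed42")
    params = SimulationParams(seed=42, n_groups=100)
    return params, write_fixture(params, str(base / "fixture"))


@pytest.fixture(scope="session")
def noisy_run(tmp_path_factory):
    """High-coverage noisy fixture: ~50x per-strand coverage, errors, jitter."""
    base = tmp_path_factory.mktemp("noisy")
    params = SimulationParams(
        seed=11,
        genome_length=3000,
        n_chromosomes=1,
        n_groups=6000,
        sequencing_error_rate=0.005,
        hint_jitter=200,
    )
    paths = write_fixture(params, str(base / "fixture"))
    out = str(base / "out")
    summary = run(PipelineConfig(n_workers=2), paths["reference"], paths["targets"], out)
    return {
        "params": params,
        "paths": paths,
        "out": out,
        "summary": summary,
        "truth": TruthTable.read_tsv(paths["truth_cytosines"], paths["truth_groups"]),
        "counts": read_cx_report(os.path.join(out, "methylation_cx.tsv")),
    }
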