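import json
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from glycoscreen.pipeline import PipelineConfig, run_pipeline
from glycoscreen.seqcore import Transcript, Transcriptome
from glycoscreen.synthetic_data import SimulationConfig, make_fixture

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

BASES = np.frombuffer(b"ACGT", dtype="S1")


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def random_transcriptome(
    rng: np.random.Generator,
    n_genes: int,
    length_range: tuple[int, int] = (200, 1000),
    shared_block: int = 0,
) -> Transcriptome:
    """Toy transcriptome; optionally implant one shared block in genes 0/1."""
    lo, hi = length_range
    seqs = {
        f"g{i}": random_sequence(rng, int(rng.integers(lo, hi + 1)))
        for i in range(n_genes)
    }
    if shared_block and n_genes >= 2:
        block = random_sequence(rng, shared_block)
        for g in ("g0", "g1"):
            pos = int(rng.integers(0, len(seqs[g]) - shared_block + 1))
            seqs[g] = seqs[g][:pos] + block + seqs[g][pos + shared_block :]
    return Transcriptome(Transcript(f"{g}.t", g, s) for g, s in seqs.items())


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def fixture_dataset(default_config, tmp_path_factory) -> dict[str, Path]:
    outdir = tmp_path_factory.mktemp("fixture")
    return make_fixture(default_config, outdir)


@pytest.fixture(scope="session")
def ground_truth(fixture_dataset) -> dict:
    return json.loads(fixture_dataset["ground_truth"].read_text())


def pipeline_config(paths: dict[str, Path], run_dir: Path, **overrides) -> PipelineConfig:
    return PipelineConfig(
        run_dir=run_dir,
        transcriptome=paths["transcriptome"],
        library=paths["library"],
        screen_primary=paths["screen_primary"],
        screen_repro=paths["screen_repro"],
        screen_secondary=paths["screen_secondary"],
        secondary_library=paths["secondary_library"],
        decay=paths["decay"],
        fractionation=paths["fractionation"],
        glycoforms=paths["glycoforms"],
        **overrides,
    )


@pytest.fixture(scope="session")
def pipeline_run(fixture_dataset, tmp_path_factory):
    run_dir = tmp_path_factory.mktemp("run")
    final = run_pipeline(pipeline_config(fixture_dataset, run_dir))
    return final, run_dir
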