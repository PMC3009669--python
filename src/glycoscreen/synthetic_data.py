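"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the screen's data-generating process:

- a toy transcriptome of uniform-random transcripts, optionally with exact
  shared sequence blocks implanted into gene pairs (the off-target
  structure a 19-mer scorer must detect);
- a knockdown library with one primary construct per gene (constructs are
  placed to span any implanted block so the off-target signal is visible);
- dot-blot signals whose probe/Chp ratio is log-normal around the true
  effect: a spiked glycogene multiplies its affected probes' ratios by a
  value in (0,1], and a construct sharing >= 3 distinct 19-mers with a true
  glycogene phenocopies (a configurable fraction of) that gene's effect;
  Chp amounts are randomized so only the ratio is informative;
- exponential mRNA decay series and two-fraction qPCR abundances with a
  configurable nuclear-export-block fold.

All generators are pure functions of (config, seed): identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .blotstats import GLYCAN_PROBES, SPOT_COLUMNS
from .downstream import DECAY_TIMES_DEFAULT, DecaySeries, FRACTIONATION_COLUMNS
from .errors import ConfigError, IntegrityError
from .seqcore import (
    DsRNAConstruct,
    Transcript,
    Transcriptome,
    count_offtarget_kmers,
    count_offtarget_kmers_naive,
    design_secondary_construct,
    write_construct_table,
    write_fasta,
)

_LN2 = math.log(2)

#: Default per-gene anti-HRP ratio multipliers for the three spiked
#: glycogenes, emulating the quantified loss-of-function effect sizes
#: (22.7%, 28.3%, 59.5% of control) of the strongest characterized
#: alpha1,3-fucosylation regulators.
DEFAULT_SPIKED_EFFECTS: dict[str, dict[str, float]] = {
    "g01": {"antiHRP": 0.227},
    "g02": {"antiHRP": 0.283},
    "g03": {"antiHRP": 0.595},
}

#: One implanted off-target pair: a 25-nt exact block copied into a null
#: gene (g10) and a true glycogene (g01), yielding 25-19+1 = 7 shared
#: 19-mers, above the OTPS threshold of 3.
DEFAULT_SHARED_BLOCKS: tuple[tuple[str, str, int], ...] = (("g10", "g01", 25),)


def _default_decay_rates() -> dict[str, float]:
    # first-order rates reproducing half-lives of 97.72 and 100.48 min
    return {"kd": _LN2 / 97.72, "control": _LN2 / 100.48}


def _default_export_folds() -> dict[str, float]:
    # target mRNA shows a strong nuclear-export block; the housekeeping
    # reference a mild one
    return {"fucTA": 9.6, "act5c": 1.7}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset; the defaults are the
    conditions every test and fixture runs under."""

    seed: int
    n_genes: int = 20
    transcript_length: tuple[int, int] = (1000, 1500)
    shared_blocks: tuple[tuple[str, str, int], ...] = DEFAULT_SHARED_BLOCKS
    spiked_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(p) for g, p in DEFAULT_SPIKED_EFFECTS.items()}
    )
    noise_sd: float = 0.1  # sd of additive noise on ln(probe/Chp)
    n_controls: int = 48
    n_repro_replicates: int = 3
    n_secondary_replicates: int = 2
    construct_length: int = 500
    phenocopy_fraction: float = 1.0  # of the shared gene's log effect
    otps_threshold: int = 3
    k: int = 19
    min_len: int = 300
    decay_rates: dict[str, float] = field(default_factory=_default_decay_rates)
    decay_times: tuple[float, ...] = DECAY_TIMES_DEFAULT
    decay_noise_sd: float = 0.05
    export_folds: dict[str, float] = field(default_factory=_default_export_folds)
    base_nc_ratio: float = 0.5  # control nuclear/cytoplasmic ratio
    fractionation_noise_sd: float = 0.05
    fractionation_replicates: int = 4

    def __post_init__(self) -> None:
        lo, hi = self.transcript_length
        if not (0 < lo <= hi):
            raise ConfigError(f"invalid transcript length range {self.transcript_length}")
        for gene, probes in self.spiked_effects.items():
            for probe, mult in probes.items():
                if probe not in GLYCAN_PROBES:
                    raise ConfigError(f"spiked effect on unknown probe {probe!r}")
                if not (0 < mult <= 1):
                    raise ConfigError(
                        f"effect multiplier for {gene}/{probe} must be in (0,1], got {mult}"
                    )
        for ga, gb, length in self.shared_blocks:
            if length < self.k:
                raise ConfigError(
                    f"shared block {ga}-{gb} of length {length} shorter than k={self.k}"
                )
        if any(k_ < 0 for k_ in self.decay_rates.values()):
            raise ConfigError("decay rates must be >= 0")
        if any(f <= 0 for f in self.export_folds.values()):
            raise ConfigError("export folds must be > 0")

    def gene_ids(self) -> list[str]:
        width = max(2, len(str(self.n_genes)))
        return [f"g{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def rng(self, stage: int) -> np.random.Generator:
        """Independent, reproducible stream per pipeline stage."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stage,))
        )


@dataclass
class GroundTruth:
    """What the generator knows: spiked genes, implanted off-target pairs,
    and the expected OTPS of every library construct (verified against the
    brute-force scanner at generation time)."""

    glycogene_effects: dict[str, dict[str, float]]
    shared_blocks: list[dict]  # gene_a, gene_b, length, positions
    expected_otps: dict[str, int] = field(default_factory=dict)
    phenocopied_lines: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def generate_transcriptome(config: SimulationConfig) -> tuple[Transcriptome, GroundTruth]:
    """Uniform-random transcripts, one per gene, with shared blocks implanted."""
    rng = config.rng(stage=0)
    lo, hi = config.transcript_length
    gene_ids = config.gene_ids()
    known = set(gene_ids)
    for gene in config.spiked_effects:
        if gene not in known:
            raise ConfigError(f"spiked gene {gene!r} not among generated genes")
    sequences = {
        gene: _random_sequence(int(rng.integers(lo, hi + 1)), rng) for gene in gene_ids
    }
    blocks = []
    for gene_a, gene_b, length in config.shared_blocks:
        for g in (gene_a, gene_b):
            if g not in known:
                raise ConfigError(f"shared-block gene {g!r} not among generated genes")
            if length > len(sequences[g]):
                raise ConfigError(
                    f"shared block of length {length} longer than transcript of {g}"
                )
        block = _random_sequence(length, rng)
        positions = {}
        for g in (gene_a, gene_b):
            seq = sequences[g]
            # keep at least one flanking base on each side so the shared
            # identity run can be pinned to exactly `length`
            pos = int(rng.integers(1, len(seq) - length))
            sequences[g] = seq[:pos] + block + seq[pos + length :]
            positions[g] = pos
        # guard the flanks: a chance flank match would extend the identical
        # run and inflate the shared 19-mer count beyond length - k + 1
        pa, pb = positions[gene_a], positions[gene_b]
        sb = list(sequences[gene_b])
        for off_a, off_b in ((pa - 1, pb - 1), (pa + length, pb + length)):
            if sequences[gene_a][off_a] == sb[off_b]:
                sb[off_b] = {"A": "C", "C": "G", "G": "T", "T": "A"}[sb[off_b]]
        sequences[gene_b] = "".join(sb)
        blocks.append(
            {"gene_a": gene_a, "gene_b": gene_b, "length": length, "positions": positions}
        )
    txome = Transcriptome(
        Transcript(f"{g}.t1", g, sequences[g]) for g in gene_ids
    )
    truth = GroundTruth(
        glycogene_effects={g: dict(p) for g, p in config.spiked_effects.items()},
        shared_blocks=blocks,
    )
    return txome, truth


def make_library(
    txome: Transcriptome, truth: GroundTruth, config: SimulationConfig
) -> list[DsRNAConstruct]:
    """One primary construct per gene, spanning any implanted block.

    Fills ``truth.expected_otps`` from the brute-force scanner and verifies
    the indexed scorer agrees.
    """
    rng = config.rng(stage=1)
    cl = config.construct_length
    block_span: dict[str, tuple[int, int]] = {}
    for blk in truth.shared_blocks:
        for g, pos in blk["positions"].items():
            block_span[g] = (pos, pos + blk["length"])
    constructs = []
    for gene in sorted(txome.gene_index):
        (transcript,) = txome.transcripts_of(gene)
        n = len(transcript)
        if cl > n:
            raise ConfigError(f"construct length {cl} exceeds transcript of {gene}")
        if gene in block_span:
            b0, b1 = block_span[gene]
            lo = max(0, b1 - cl)
            hi = min(b0, n - cl)
            if lo > hi:
                raise ConfigError(
                    f"cannot place a {cl}-nt construct covering the block on {gene}"
                )
            start = int(rng.integers(lo, hi + 1))
        else:
            start = int(rng.integers(0, n - cl + 1))
        constructs.append(
            DsRNAConstruct(
                construct_id=f"{gene}_primary",
                target_gene=gene,
                source_transcript_id=transcript.transcript_id,
                start=start,
                end=start + cl,
                sequence=transcript.sequence[start : start + cl],
            )
        )
    for c in constructs:
        naive = count_offtarget_kmers_naive(c, txome, config.k)
        indexed = count_offtarget_kmers(c, txome, config.k)
        if naive.per_gene_counts != indexed.per_gene_counts:
            raise IntegrityError(
                f"off-target scorer disagreement on {c.construct_id}: "
                f"{indexed.per_gene_counts} vs naive {naive.per_gene_counts}"
            )
        truth.expected_otps[c.construct_id] = naive.otps
    return constructs


# ---------------------------------------------------------------------------
# Blot simulation


def simulate_blot_round(
    effects_ln: Mapping[str, Mapping[str, float]],
    gene_by_line: Mapping[str, str],
    n_controls: int,
    n_replicates: int,
    noise_sd: float,
    rng: np.random.Generator,
    blot_prefix: str = "b",
) -> pd.DataFrame:
    """Emit (probe_signal, chp_signal) spot pairs for one assay round.

    True ln(probe/Chp) is the per-line, per-probe effect (0 for controls and
    unaffected probes); observed L adds Normal(0, noise_sd).  Chp amounts
    are randomized log-normally so only the ratio carries information.
    """
    rows = []
    lines = [(line, gene_by_line[line]) for line in effects_ln]
    lines += [(f"ctrl_{i:03d}", "control") for i in range(1, n_controls + 1)]
    for replicate in range(1, n_replicates + 1):
        blot_id = f"{blot_prefix}{replicate}"
        for line_id, gene_id in lines:
            line_effects = effects_ln.get(line_id, {})
            for probe in GLYCAN_PROBES:
                chp = float(np.exp(rng.normal(np.log(100.0), 0.3)))
                L = line_effects.get(probe, 0.0) + float(rng.normal(0.0, noise_sd))
                rows.append(
                    {
                        "line_id": line_id,
                        "gene_id": gene_id,
                        "probe": probe,
                        "probe_signal": chp * math.exp(L),
                        "chp_signal": chp,
                        "replicate": replicate,
                        "blot_id": blot_id,
                    }
                )
    return pd.DataFrame(rows, columns=SPOT_COLUMNS)


def _construct_effects_ln(
    constructs: Sequence[DsRNAConstruct],
    txome: Transcriptome,
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[dict[str, dict[str, float]], dict[str, str], dict[str, list[str]]]:
    """True per-line ln effects: own knockdown effect plus off-target
    phenocopy inherited from glycogenes sharing >= threshold 19-mers.

    Phenocopy is scored against the glycogenes' transcripts only; shared
    k-mers with non-glycogenes carry no phenotype, so the restriction does
    not change the result.
    """
    glyco_txome = Transcriptome(
        t
        for gene in sorted(truth.glycogene_effects)
        for t in txome.transcripts_of(gene)
    )
    effects: dict[str, dict[str, float]] = {}
    gene_by_line: dict[str, str] = {}
    phenocopied: dict[str, list[str]] = {}
    for c in constructs:
        gene_by_line[c.construct_id] = c.target_gene
        ln_eff: dict[str, float] = {}
        own = truth.glycogene_effects.get(c.target_gene, {})
        for probe, mult in own.items():
            ln_eff[probe] = ln_eff.get(probe, 0.0) + math.log(mult)
        if len(glyco_txome) and len(c) >= config.k:
            report = count_offtarget_kmers(c, glyco_txome, config.k)
            for gene, count in report.per_gene_counts.items():
                if count >= config.otps_threshold:
                    phenocopied.setdefault(c.construct_id, []).append(gene)
                    for probe, mult in truth.glycogene_effects[gene].items():
                        ln_eff[probe] = ln_eff.get(probe, 0.0) + (
                            config.phenocopy_fraction * math.log(mult)
                        )
        effects[c.construct_id] = ln_eff
    return effects, gene_by_line, phenocopied


@dataclass
class ScreenData:
    """Simulated spot tables for the three assay rounds."""

    primary: pd.DataFrame
    reproducibility: pd.DataFrame
    secondary: pd.DataFrame
    secondary_constructs: list[DsRNAConstruct]


def simulate_screen(
    txome: Transcriptome,
    library: Sequence[DsRNAConstruct],
    truth: GroundTruth,
    config: SimulationConfig,
) -> ScreenData:
    """Single-round primary, n=3 repeat, and n=2 secondary blot tables.

    Secondary constructs are designed with the package's own designer
    (non-overlapping, minimal OTPS) and inherit phenocopy from whatever
    19-mers they actually share with glycogenes.
    """
    primary_eff, gene_by_line, phenocopied = _construct_effects_ln(
        library, txome, truth, config
    )
    truth.phenocopied_lines = phenocopied
    primary = simulate_blot_round(
        primary_eff, gene_by_line, config.n_controls, 1, config.noise_sd,
        config.rng(stage=2), blot_prefix="primary_b",
    )
    repro = simulate_blot_round(
        primary_eff, gene_by_line, config.n_controls, config.n_repro_replicates,
        config.noise_sd, config.rng(stage=3), blot_prefix="repro_b",
    )
    secondary_constructs = []
    for c in library:
        cdna = txome.get(c.source_transcript_id)
        sec = design_secondary_construct(
            cdna, c, txome, min_len=config.min_len, k=config.k,
            construct_id=f"{c.target_gene}_secondary",
        )
        if sec is not None:
            secondary_constructs.append(sec)
    secondary_eff, sec_gene_by_line, _ = _construct_effects_ln(
        secondary_constructs, txome, truth, config
    )
    secondary = simulate_blot_round(
        secondary_eff, sec_gene_by_line, config.n_controls,
        config.n_secondary_replicates, config.noise_sd,
        config.rng(stage=4), blot_prefix="secondary_b",
    )
    return ScreenData(primary, repro, secondary, secondary_constructs)


# ---------------------------------------------------------------------------
# Downstream simulators


def simulate_decay(config: SimulationConfig) -> dict[str, DecaySeries]:
    """Exponential decay series per condition, renormalized to t=0."""
    rng = config.rng(stage=5)
    series = {}
    for condition in sorted(config.decay_rates):
        k = config.decay_rates[condition]
        if k < 0:
            raise ConfigError(f"negative decay rate for {condition!r}")
        t = np.asarray(config.decay_times, float)
        noise = rng.normal(0.0, config.decay_noise_sd, size=len(t)) if config.decay_noise_sd > 0 else np.zeros(len(t))
        v = np.exp(-k * t) * np.exp(noise)
        v = v / v[0]
        series[condition] = DecaySeries(tuple(t), tuple(v))
    return series


def simulate_fractionation(config: SimulationConfig) -> pd.DataFrame:
    """Nuclear/cytoplasmic qPCR quantities with a per-gene export-block fold."""
    rng = config.rng(stage=6)
    rows = []
    for gene in sorted(config.export_folds):
        fold = config.export_folds[gene]
        for condition in ("control", "kd"):
            nc_ratio = config.base_nc_ratio * (fold if condition == "kd" else 1.0)
            for fraction, base in (("nuclear", nc_ratio), ("cytoplasmic", 1.0)):
                for replicate in range(1, config.fractionation_replicates + 1):
                    noise = (
                        float(np.exp(rng.normal(0.0, config.fractionation_noise_sd)))
                        if config.fractionation_noise_sd > 0
                        else 1.0
                    )
                    rows.append(
                        {
                            "gene_id": gene,
                            "fraction": fraction,
                            "condition": condition,
                            "replicate": replicate,
                            "rel_quantity": base * noise,
                        }
                    )
    return pd.DataFrame(rows, columns=FRACTIONATION_COLUMNS)


# ---------------------------------------------------------------------------
# Fixture writer

#: Synthetic per-site glycoform percentage table emulating the qualitative
#: mass-spectrometry pattern at the difucosylated site: the knockdown loses
#: the difucosylated forms (one to not-detected) while paucimannose forms
#: take up the difference.  Percentages are synthetic, not measured values.
SYNTHETIC_GLYCOFORM_ROWS = [
    ("N1012", "M3F2Gn2", "control", "9"),
    ("N1012", "M3F2Gn3", "control", "5"),
    ("N1012", "M3FGn2", "control", "40"),
    ("N1012", "M3Gn2", "control", "46"),
    ("N1012", "M3F2Gn2", "kd", "ND"),
    ("N1012", "M3F2Gn3", "kd", "2"),
    ("N1012", "M3FGn2", "kd", "48"),
    ("N1012", "M3Gn2", "kd", "50"),
]


def make_fixture(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a complete demo dataset plus ground-truth JSON; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    txome, truth = generate_transcriptome(config)
    library = make_library(txome, truth, config)
    screen = simulate_screen(txome, library, truth, config)
    decay = simulate_decay(config)
    frac = simulate_fractionation(config)

    paths = {
        "transcriptome": outdir / "transcriptome.fasta",
        "library": outdir / "library.tsv",
        "secondary_library": outdir / "secondary_library.tsv",
        "screen_primary": outdir / "screen_primary.tsv",
        "screen_repro": outdir / "screen_repro.tsv",
        "screen_secondary": outdir / "screen_secondary.tsv",
        "decay": outdir / "decay.tsv",
        "fractionation": outdir / "fractionation.tsv",
        "glycoforms": outdir / "glycoforms_synthetic.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_fasta(txome, paths["transcriptome"])
    write_construct_table(library, paths["library"])
    write_construct_table(screen.secondary_constructs, paths["secondary_library"])
    screen.primary.to_csv(paths["screen_primary"], sep="\t", index=False)
    screen.reproducibility.to_csv(paths["screen_repro"], sep="\t", index=False)
    screen.secondary.to_csv(paths["screen_secondary"], sep="\t", index=False)
    decay_rows = [
        {"condition": cond, "time_min": t, "value": v}
        for cond, s in decay.items()
        for t, v in zip(s.times, s.values)
    ]
    pd.DataFrame(decay_rows).to_csv(paths["decay"], sep="\t", index=False)
    frac.to_csv(paths["fractionation"], sep="\t", index=False)
    pd.DataFrame(
        SYNTHETIC_GLYCOFORM_ROWS, columns=["site", "composition", "condition", "percent"]
    ).to_csv(paths["glycoforms"], sep="\t", index=False)
    truth.to_json(paths["ground_truth"])
    return paths
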