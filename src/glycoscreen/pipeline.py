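"""End-to-end screen orchestration over TSV/FASTA inputs.

Stages run in order: normalize -> z-scores -> primary calls ->
reproducibility -> off-target scoring -> secondary validation -> rank
assignment -> alpha1,3-specificity -> downstream (decay / export /
glycoforms, when data are present).  Every stage writes an immutable TSV
into the run directory, every rank decision is appended to a structured
JSONL log with its rule and values, and re-running with identical config
and inputs reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import blotstats, screenflow, seqcore
from .blotstats import CONTROL_GENE, GLYCAN_PROBES
from .downstream import (
    DecaySeries,
    alpha13_summary,
    compare_decay,
    export_enrichment,
    fit_decay,
    read_glycoform_table,
)
from .errors import InputError
from .screenflow import ScreenCall

FINAL_TABLE = "final_table.tsv"


@dataclass
class PipelineConfig:
    """Paths, thresholds, and the seed for one pipeline run."""

    run_dir: Path
    transcriptome: Path
    library: Path
    screen_primary: Path
    screen_repro: Path
    screen_secondary: Optional[Path] = None
    secondary_library: Optional[Path] = None
    decay: Optional[Path] = None
    fractionation: Optional[Path] = None
    glycoforms: Optional[Path] = None
    z_threshold: float = screenflow.DEFAULT_Z_THRESHOLD
    p_reproducible: float = screenflow.DEFAULT_P_REPRODUCIBLE
    p_secondary: float = screenflow.DEFAULT_P_SECONDARY
    otps_threshold: int = screenflow.DEFAULT_OTPS_THRESHOLD
    k: int = seqcore.DEFAULT_K
    min_len: int = 300
    chp_floor: float = 0.0
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=dict)  # toggles, default all on

    def __post_init__(self) -> None:
        for name in (
            "run_dir", "transcriptome", "library", "screen_primary", "screen_repro",
            "screen_secondary", "secondary_library", "decay", "fractionation",
            "glycoforms",
        ):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))
        for threshold in (self.z_threshold, self.p_reproducible, self.p_secondary,
                          self.otps_threshold):
            if threshold <= 0:
                raise InputError("thresholds must be positive")

    def enabled(self, stage: str) -> bool:
        return self.stages.get(stage, True)

    def config_hash(self) -> str:
        payload = {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(self).items()
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        payload = {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(self).items()
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _read_spots(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise InputError(f"missing screen table: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str, "gene_id": str, "probe": str})
    required = {"line_id", "gene_id", "probe", "probe_signal", "chp_signal"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    return df


class PipelineRun:
    """Executes the staged screen analysis inside a run directory."""

    def __init__(self, config: PipelineConfig, resume: bool = False) -> None:
        self.config = config
        self.resume = resume
        self.run_dir = Path(config.run_dir)
        self.run_dir.mkdir(parents=True, exist_ok=True)
        self._log_path = self.run_dir / "decisions.log"
        self._log_entries: list[dict] = []

    # -- helpers -----------------------------------------------------------

    def _out(self, name: str) -> Path:
        return self.run_dir / name

    def _write(self, df: pd.DataFrame, name: str) -> pd.DataFrame:
        df.to_csv(self._out(name), sep="\t", index=False)
        return df

    def _cached(self, name: str) -> Optional[pd.DataFrame]:
        path = self._out(name)
        if self.resume and path.exists():
            return pd.read_csv(path, sep="\t")
        return None

    def _log(self, stage: str, **values) -> None:
        self._log_entries.append(
            {"stage": stage, "config_hash": self.config.config_hash(), **values}
        )

    # -- stages ------------------------------------------------------------

    def run(self) -> pd.DataFrame:
        cfg = self.config
        txome = seqcore.read_fasta(cfg.transcriptome)
        library = seqcore.read_construct_table(cfg.library, txome)
        by_gene = {c.target_gene: c for c in library}

        primary_norm = self._normalize("primary", cfg.screen_primary)
        repro_norm = self._normalize("repro", cfg.screen_repro)
        secondary_norm = (
            self._normalize("secondary", cfg.screen_secondary)
            if cfg.screen_secondary and Path(cfg.screen_secondary).exists()
            else None
        )

        stats = blotstats.aggregate_control_stats(
            primary_norm[primary_norm["gene_id"] == CONTROL_GENE]
        )
        zdf = self._write(
            blotstats.z_table(primary_norm, stats), "zscores.tsv"
        )

        calls = self._primary_calls(zdf)
        self._reproducibility(calls, repro_norm)
        reports = self._offtarget(calls, library, txome)
        self._secondary(calls, by_gene, txome, secondary_norm)
        self._rescreen(calls, reports)
        final = self._rank(calls)
        final = self._hrp(calls, final)
        self._write(final, FINAL_TABLE)
        self._downstream()
        self._flush_log()
        summary = {
            "config_hash": cfg.config_hash(),
            "n_genes": int(len(calls)),
            "counts": final["rank"].value_counts().to_dict(),
        }
        (self.run_dir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
        return final

    def _normalize(self, label: str, path: Path) -> pd.DataFrame:
        name = f"normalized_{label}.tsv"
        cached = self._cached(name)
        if cached is not None:
            return cached
        spots = _read_spots(Path(path))
        kept, excluded = blotstats.normalize_table(spots, chp_floor=self.config.chp_floor)
        self._write(excluded, f"excluded_{label}.tsv")
        return self._write(kept, name)

    @staticmethod
    def _z_by_gene(zdf: pd.DataFrame) -> dict[str, dict[str, float]]:
        kd = zdf[zdf["gene_id"] != CONTROL_GENE]
        out: dict[str, dict[str, float]] = {}
        for (gene, probe), grp in kd.groupby(["gene_id", "probe"]):
            out.setdefault(str(gene), {})[str(probe)] = float(grp["z"].iloc[0])
        return out

    def _primary_calls(self, zdf: pd.DataFrame) -> dict[str, ScreenCall]:
        z_by_gene = self._z_by_gene(zdf)
        calls: dict[str, ScreenCall] = {}
        rows = []
        for gene in sorted(z_by_gene):
            z = z_by_gene[gene]
            call = ScreenCall(gene_id=gene, z_by_probe=z)
            try:
                call.primary_candidate = screenflow.call_primary(z, self.config.z_threshold)
                incomplete = False
            except KeyError:
                call.primary_candidate = False
                incomplete = True
            calls[gene] = call
            rows.append(
                {"gene_id": gene, **{f"z_{p}": z.get(p, np.nan) for p in GLYCAN_PROBES},
                 "primary_candidate": call.primary_candidate, "incomplete": incomplete}
            )
            self._log(
                "primary", gene=gene, rule=f"|z| > {self.config.z_threshold} on any glycan probe",
                candidate=call.primary_candidate, incomplete=incomplete,
            )
        self._write(pd.DataFrame(rows), "primary_calls.tsv")
        return calls

    @staticmethod
    def _values_by_probe(norm: pd.DataFrame, gene: Optional[str]) -> dict[str, list[float]]:
        sel = (
            norm["gene_id"] == CONTROL_GENE if gene is None else norm["gene_id"] == gene
        )
        sub = norm[sel]
        return {p: sub[sub["probe"] == p]["L"].tolist() for p in GLYCAN_PROBES}

    def _reproducibility(self, calls: dict[str, ScreenCall], repro_norm: pd.DataFrame) -> None:
        controls = self._values_by_probe(repro_norm, None)
        rows = []
        for gene, call in calls.items():
            if not call.primary_candidate:
                continue
            probes = screenflow.aberrant_probes(call.z_by_probe, self.config.z_threshold)
            kd = self._values_by_probe(repro_norm, gene)
            testable = [p for p in probes if len(kd.get(p, [])) >= 2]
            if not testable:
                call.reproducible = False
                self._log("reproducibility", gene=gene, rule="no testable aberrant probe",
                          reproducible=False)
                continue
            reproducible, p_by_probe = screenflow.call_reproducible(
                kd, controls, testable, self.config.p_reproducible
            )
            call.reproducible = reproducible
            best = min(p_by_probe.values())
            rows.append({"gene_id": gene, "best_p": best, "reproducible": reproducible})
            self._log(
                "reproducibility", gene=gene,
                rule=f"two-sided Student t, p < {self.config.p_reproducible} on an aberrant probe (n=3)",
                p_by_probe=p_by_probe, reproducible=reproducible,
            )
        self._write(pd.DataFrame(rows, columns=["gene_id", "best_p", "reproducible"]),
                    "reproducibility.tsv")

    def _offtarget(
        self, calls: dict[str, ScreenCall], library, txome
    ) -> dict[str, seqcore.OffTargetReport]:
        reports = {}
        rows = []
        for construct in library:
            report = seqcore.count_offtarget_kmers(construct, txome, self.config.k)
            reports[construct.target_gene] = report
            if construct.target_gene in calls:
                calls[construct.target_gene].otps = report.otps
            rows.append(
                {"construct_id": construct.construct_id, "gene_id": construct.target_gene,
                 "otps": report.otps,
                 "suspected_genes": ",".join(report.suspected_genes())}
            )
        self._write(pd.DataFrame(rows), "offtarget.tsv")
        return reports

    def _secondary(self, calls, by_gene, txome, secondary_norm) -> None:
        cfg = self.config
        sec_by_gene: dict[str, seqcore.DsRNAConstruct] = {}
        if cfg.secondary_library and Path(cfg.secondary_library).exists():
            for c in seqcore.read_construct_table(cfg.secondary_library, txome):
                sec_by_gene[c.target_gene] = c
        controls = (
            self._values_by_probe(secondary_norm, None) if secondary_norm is not None else None
        )
        rows = []
        for gene, call in calls.items():
            if not (call.primary_candidate and call.reproducible):
                continue
            primary = by_gene.get(gene)
            secondary = sec_by_gene.get(gene)
            if secondary is None and primary is not None:
                cdna = txome.get(primary.source_transcript_id)
                secondary = seqcore.design_secondary_construct(
                    cdna, primary, txome, min_len=cfg.min_len, k=cfg.k
                )
            if secondary is None:
                self._log("secondary", gene=gene,
                          rule="non-overlapping secondary window of >= min_len required",
                          outcome="infeasible (cDNA too short)")
                continue
            if secondary_norm is None:
                self._log("secondary", gene=gene, outcome="no secondary assay data")
                continue
            kd = self._values_by_probe(secondary_norm, gene)
            probes = [
                p for p in screenflow.aberrant_probes(call.z_by_probe, cfg.z_threshold)
                if len(kd.get(p, [])) >= 2
            ]
            if not probes:
                self._log("secondary", gene=gene, outcome="gene untestable in secondary round")
                continue
            secondary_p, rank1 = screenflow.validate_secondary(
                primary, secondary, kd, controls, probes, cfg.p_secondary
            )
            call.secondary_p = secondary_p
            rows.append({"gene_id": gene, "secondary_construct": secondary.construct_id,
                         "secondary_p": secondary_p, "passes": rank1})
            self._log(
                "secondary", gene=gene,
                rule=f"independent non-overlapping dsRNA, two-sided Student t, "
                     f"p < {cfg.p_secondary} (n=2)",
                secondary_p=secondary_p, passes=rank1,
            )
        self._write(
            pd.DataFrame(rows, columns=["gene_id", "secondary_construct", "secondary_p", "passes"]),
            "secondary.tsv",
        )

    def _rescreen(self, calls, reports) -> None:
        """Off-target rescreen: a suspected off-target gene 'shows a defect'
        iff its own knockdown line is a primary candidate in this screen."""
        for gene, call in calls.items():
            if not (call.primary_candidate and call.reproducible):
                continue
            report = reports.get(gene)
            if report is None:
                continue
            suspects = report.suspected_genes()
            outcome: dict[str, bool] = {}
            testable = True
            for suspect in suspects:
                if suspect in calls:
                    outcome[suspect] = calls[suspect].primary_candidate
                else:
                    testable = False
            call.offtarget_rescreen = outcome if testable else None
            self._log(
                "offtarget_rescreen", gene=gene, suspects=suspects,
                rule="suspect shows a defect iff its own knockdown is a primary candidate",
                outcome=outcome if testable else "untestable suspect present",
            )

    def _rank(self, calls: dict[str, ScreenCall]) -> pd.DataFrame:
        rows = []
        for gene in sorted(calls):
            call = calls[gene]
            if not call.primary_candidate:
                call.rank = "not_hit"
                call.rationale = (
                    "not a primary candidate"
                    if call.reproducible is None
                    else "not reproducible"
                )
                if call.reproducible is None and any(
                    p not in call.z_by_probe for p in GLYCAN_PROBES
                ):
                    call.rationale = "incomplete probe panel; not called"
            else:
                calls[gene] = call = screenflow.assign_rank(
                    call, self.config.p_secondary, self.config.otps_threshold
                )
            self._log("rank", gene=gene, rank=call.rank, rationale=call.rationale,
                      secondary_p=call.secondary_p, otps=call.otps,
                      rescreen=call.offtarget_rescreen)
            rows.append(
                {
                    "gene_id": gene,
                    **{f"z_{p}": call.z_by_probe.get(p, np.nan) for p in GLYCAN_PROBES},
                    "primary_candidate": call.primary_candidate,
                    "reproducible": call.reproducible,
                    "secondary_p": call.secondary_p,
                    "otps": call.otps,
                    "rank": call.rank,
                    "rationale": call.rationale,
                }
            )
        columns = (
            ["gene_id"]
            + [f"z_{p}" for p in GLYCAN_PROBES]
            + ["primary_candidate", "reproducible", "secondary_p", "otps", "rank",
               "rationale"]
        )
        return pd.DataFrame(rows, columns=columns)

    def _hrp(self, calls: dict[str, ScreenCall], final: pd.DataFrame) -> pd.DataFrame:
        specific = []
        for gene in sorted(calls):
            call = calls[gene]
            if call.rank not in ("rank1", "rank2"):
                specific.append(False)
                continue
            try:
                hrp = screenflow.classify_hrp_specific(
                    gene, call.z_by_probe, self.config.z_threshold
                )
                specific.append(hrp.alpha13_specific)
            except KeyError:
                specific.append(False)
        final = final.copy()
        final["alpha13_specific"] = pd.Series(specific, dtype=bool, index=final.index)
        mask = final["alpha13_specific"].to_numpy(dtype=bool)
        self._write(final.loc[mask, ["gene_id", "rank"]], "hrp_specific.tsv")
        return final

    def _downstream(self) -> None:
        cfg = self.config
        if cfg.decay and Path(cfg.decay).exists() and self.config.enabled("decay"):
            df = pd.read_csv(cfg.decay, sep="\t")
            fits = {}
            series = {}
            rows = []
            for condition, grp in df.groupby("condition"):
                grp = grp.sort_values("time_min")
                s = DecaySeries(tuple(grp["time_min"]), tuple(grp["value"]))
                fit = fit_decay(s)
                fits[condition], series[condition] = fit, s
                rows.append({"condition": condition, "k_per_min": fit.k,
                             "t_half_min": fit.t_half})
            out = pd.DataFrame(rows)
            if {"kd", "control"} <= set(fits):
                cmp_ = compare_decay(
                    fits["kd"], fits["control"], series["kd"], series["control"],
                    rng=np.random.default_rng(cfg.seed),
                )
                out["k_ratio_kd_over_control"] = cmp_.k_ratio
            self._write(out, "decay_fits.tsv")
        if cfg.fractionation and Path(cfg.fractionation).exists() and cfg.enabled("export"):
            df = pd.read_csv(cfg.fractionation, sep="\t")
            rows = []
            for gene in sorted(df["gene_id"].unique()):
                e = export_enrichment(df, gene)
                rows.append({"gene_id": gene, "r_kd": e.r_kd, "r_ctrl": e.r_ctrl,
                             "fold": e.fold})
            self._write(pd.DataFrame(rows), "export_enrichment.tsv")
        if cfg.glycoforms and Path(cfg.glycoforms).exists() and cfg.enabled("glycoforms"):
            table = read_glycoform_table(cfg.glycoforms)
            summary = alpha13_summary(table, conditions=["control", "kd"])
            self._write(summary.per_form, "glycoform_per_form.tsv")
            (self.run_dir / "glycoform_summary.json").write_text(
                json.dumps(
                    {"site": summary.site,
                     "alpha13_percent": summary.percent_by_condition},
                    indent=2, sort_keys=True,
                ) + "\n"
            )

    def _flush_log(self) -> None:
        with open(self._log_path, "w") as fh:
            for entry in self._log_entries:
                fh.write(json.dumps(entry, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig, resume: bool = False) -> pd.DataFrame:
    """Run all stages; returns the final per-gene call table."""
    return PipelineRun(config, resume=resume).run()


def report(run_dir: str | Path) -> dict:
    """Summarize a completed run: counts per rank plus the alpha1,3 list.

    Writes report.json and report.md into the run directory; counts are
    computed from the final table only.
    """
    run_dir = Path(run_dir)
    final_path = run_dir / FINAL_TABLE
    if not final_path.exists():
        raise InputError(f"incomplete run: missing {FINAL_TABLE} in {run_dir}")
    final = pd.read_csv(final_path, sep="\t")
    counts = {rank: int((final["rank"] == rank).sum()) for rank in screenflow.RANKS}
    hits = final[final["rank"].isin(["rank1", "rank2"])]
    alpha13 = (
        final[final.get("alpha13_specific", False) == True]["gene_id"].tolist()  # noqa: E712
        if "alpha13_specific" in final.columns
        else []
    )
    summary = {
        "n_genes": int(len(final)),
        "n_primary_candidates": int(final["primary_candidate"].sum()),
        "n_glycosylation_genes": int(len(hits)),
        "counts_per_rank": counts,
        "alpha13_specific_genes": alpha13,
    }
    (run_dir / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    lines = [
        "# Screen run report",
        "",
        f"- genes analyzed: {summary['n_genes']}",
        f"- primary candidates (|z| > threshold): {summary['n_primary_candidates']}",
        f"- glycosylation-related genes (rank1 + rank2): {summary['n_glycosylation_genes']}",
        "",
        "| rank | genes |",
        "|------|-------|",
    ]
    lines += [f"| {rank} | {counts[rank]} |" for rank in screenflow.RANKS]
    lines += ["", f"alpha1,3-fucosylation-specific: {', '.join(alpha13) or 'none'}", ""]
    (run_dir / "report.md").write_text("\n".join(lines))
    return summary
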