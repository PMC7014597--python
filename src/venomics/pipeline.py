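"""Run configuration and the stage orchestrator.

``RunConfig`` is a flat key-value document (YAML) holding every tunable
threshold with the published defaults, the random seed, and input file
paths.  Unknown keys are rejected so a typo in a threshold name cannot
silently fall back to a default.

``run_pipeline`` executes the requested stages in order and writes one TSV
per stage plus a run log recording the seed and thresholds.  Outputs are a
pure function of (config, seed): two identical runs produce byte-identical
files.  The ``simulate`` stage writes synthetic inputs (with truth tables
alongside) that downstream stages pick up automatically when no explicit
input path is configured.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composition, de, fixtures, io, molevol, network, orthology, qc, simulate
from .exceptions import ConfigurationError

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = (
    "simulate",
    "outliers",
    "presence",
    "chimera",
    "kmerfilter",
    "cluster",
    "orthology",
    "de",
    "modules",
    "dnds",
    "report",
)


@dataclass
class RunConfig:
    # thresholds (defaults are the published analysis values)
    null_level: float = 0.99        # nontoxin null band mass
    delta_fraction: float = 0.5     # zero-replacement fraction of sample minimum
    min_depth: int = 5              # presence: minimum per-base depth
    max_low_fraction: float = 0.10  # presence: tolerated low-coverage fraction
    asym_fraction: float = 0.50     # chimera: overhang asymmetry vs mean read length
    min_reads_at_site: int = 3
    kmer_k: int = 21
    kmer_fold: float = 500.0
    cluster_identity: float = 0.98
    beta: float = 10.0
    min_module_size: int = 1
    filter_quantile: float = 0.5
    min_ds: float = 0.001
    max_ds: float = 0.10
    alpha: float = 0.05

    seed: int = 0
    outdir: str = "venomics_out"

    # input paths (all optional; stages fall back to simulate-stage outputs)
    expression: str | None = None
    annotation: str | None = None
    alignments: str | None = None
    transcript_length: int | None = None
    sequences: str | None = None       # FASTA for clustering
    reads: dict | None = None          # sample -> FASTA of reads (k-mer filter)
    orthogroups: str | None = None
    counts: str | None = None
    groups: str | None = None          # sample -> level TSV for DE
    samples: str | None = None         # sample metadata TSV for modules
    pair_fasta: str | None = None      # codon-aligned ortholog pairs
    pair_classes: str | None = None    # pair_id -> toxin/nontoxin TSV

    def __post_init__(self) -> None:
        positive = {
            "min_depth": self.min_depth,
            "kmer_k": self.kmer_k,
            "kmer_fold": self.kmer_fold,
            "beta": self.beta,
            "min_module_size": self.min_module_size,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive, got {value}")
        unit = {
            "null_level": self.null_level,
            "max_low_fraction": self.max_low_fraction,
            "asym_fraction": self.asym_fraction,
            "cluster_identity": self.cluster_identity,
            "filter_quantile": self.filter_quantile,
            "alpha": self.alpha,
            "delta_fraction": self.delta_fraction,
        }
        for name, value in unit.items():
            if not 0 < value <= 1:
                raise ConfigurationError(f"{name} must be in (0, 1], got {value}")
        if not 0 <= self.min_ds <= self.max_ds:
            raise ConfigurationError("require 0 <= min_ds <= max_ds")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a flat mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {unknown}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _require(value, name: str, stage: str):
    if value is None:
        raise ConfigurationError(f"stage {stage!r} requires input {name!r}")
    return value


class _Run:
    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.produced: dict[str, Path] = {}

    def path_for(self, key: str, stage: str) -> Path:
        configured = getattr(self.config, key, None)
        if configured is not None:
            return Path(configured)
        if key in self.produced:
            return self.produced[key]
        raise ConfigurationError(
            f"stage {stage!r} requires input {key!r} (configure it or run 'simulate' first)"
        )

    # ---------------- stages ----------------

    def stage_simulate(self) -> None:
        cfg = self.config
        expr, annot, truth = simulate.simulate_expression(seed=cfg.seed)
        io.write_expression_table(expr, self.outdir / "sim_expression.tsv")
        io.write_annotation(annot, self.outdir / "sim_annotation.tsv")
        pd.DataFrame(
            sorted(truth.outliers.items()), columns=["transcript_id", "direction"]
        ).to_csv(self.outdir / "sim_truth_outliers.tsv", sep="\t", index=False)
        self.produced["expression"] = self.outdir / "sim_expression.tsv"
        self.produced["annotation"] = self.outdir / "sim_annotation.tsv"

        aln, cov_truth = simulate.simulate_coverage(
            transcript_length=2000, junction_at=1000, seed=cfg.seed
        )
        io.write_alignment_table(aln, self.outdir / "sim_alignments.tsv")
        self.produced["alignments"] = self.outdir / "sim_alignments.tsv"
        self._sim_transcript_length = 2000

        og, _ = simulate.simulate_orthogroups(10, 2, 1, 1, 2, seed=cfg.seed)
        io.write_orthogroups(og, self.outdir / "sim_orthogroups.tsv")
        self.produced["orthogroups"] = self.outdir / "sim_orthogroups.tsv"

        s1, s2, _ = simulate.simulate_codon_pair(100, 2, 4, seed=cfg.seed)
        io.write_fasta({"pair1_A": s1, "pair1_B": s2}, self.outdir / "sim_pairs.fasta")
        self.produced["pair_fasta"] = self.outdir / "sim_pairs.fasta"

        cexpr, samples, _ = simulate.simulate_coexpression(seed=cfg.seed)
        io.write_expression_table(cexpr, self.outdir / "sim_coexpression.tsv")
        samples.to_csv(self.outdir / "sim_samples.tsv", sep="\t", index=False)
        self.produced["coexpression"] = self.outdir / "sim_coexpression.tsv"
        self.produced["samples"] = self.outdir / "sim_samples.tsv"

    def stage_outliers(self) -> None:
        cfg = self.config
        expr = io.read_expression_table(self.path_for("expression", "outliers"))
        annot = io.read_annotation(self.path_for("annotation", "outliers"))
        calls, fit, band = composition.divergence_analysis(
            expr, annot, level=cfg.null_level, delta_fraction=cfg.delta_fraction
        )
        calls.to_csv(self.outdir / "outliers.tsv", sep="\t")
        pd.DataFrame(
            [
                {
                    "lower": band.lower,
                    "upper": band.upper,
                    "level": band.level,
                    "n_background": band.n_background,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                }
            ]
        ).to_csv(self.outdir / "null_band.tsv", sep="\t", index=False)
        composition.family_composition(expr, annot).to_csv(
            self.outdir / "family_composition.tsv", sep="\t"
        )

    def _alignments(self, stage: str) -> tuple[pd.DataFrame, int]:
        path = self.path_for("alignments", stage)
        aln = (io.read_sam_alignments(path) if str(path).endswith(".sam")
               else io.read_alignment_table(path))
        length = self.config.transcript_length or getattr(
            self, "_sim_transcript_length", None
        )
        if length is None:
            length = int(aln["end"].max())
        return aln, length

    def stage_presence(self) -> None:
        cfg = self.config
        aln, length = self._alignments("presence")
        rows = []
        for tid, sub in aln.groupby("transcript_id"):
            profile = qc.depth_profile(sub, length, transcript_id=tid)
            call = qc.call_presence(
                profile, min_depth=cfg.min_depth, max_low_fraction=cfg.max_low_fraction
            )
            rows.append(dataclasses.asdict(call))
        pd.DataFrame(rows).to_csv(self.outdir / "presence.tsv", sep="\t", index=False)

    def stage_chimera(self) -> None:
        cfg = self.config
        aln, length = self._alignments("chimera")
        rows = []
        for tid, sub in aln.groupby("transcript_id"):
            flag = qc.screen_chimeras(
                sub,
                length,
                asym_fraction=cfg.asym_fraction,
                min_reads_at_site=cfg.min_reads_at_site,
                transcript_id=tid,
            )
            for site, left, right in zip(
                flag.sites, flag.left_overhang, flag.right_overhang
            ):
                rows.append(
                    {
                        "transcript_id": tid,
                        "site": int(site),
                        "mean_left_overhang": left,
                        "mean_right_overhang": right,
                        "mean_read_length": flag.mean_read_length,
                    }
                )
        pd.DataFrame(
            rows,
            columns=[
                "transcript_id",
                "site",
                "mean_left_overhang",
                "mean_right_overhang",
                "mean_read_length",
            ],
        ).to_csv(self.outdir / "chimera_sites.tsv", sep="\t", index=False)

    def stage_kmerfilter(self) -> None:
        cfg = self.config
        reads_cfg = _require(cfg.reads, "reads", "kmerfilter")
        reads = {sample: io.read_fasta(path) for sample, path in reads_cfg.items()}
        filtered, removed = qc.kmer_crosstalk_filter(reads, k=cfg.kmer_k, fold=cfg.kmer_fold)
        removed.to_csv(self.outdir / "kmer_removed_reads.tsv", sep="\t", index=False)
        for sample, kept in filtered.items():
            io.write_fasta(kept, self.outdir / f"kmer_filtered_{sample}.fasta")

    def stage_cluster(self) -> None:
        cfg = self.config
        seqs = io.read_fasta(_require(cfg.sequences, "sequences", "cluster"))
        clusters = qc.cluster_transcripts(seqs, identity=cfg.cluster_identity)
        pd.DataFrame(
            [
                {
                    "cluster_id": c.cluster_id,
                    "representative": c.representative,
                    "members": ",".join(c.members),
                }
                for c in clusters
            ]
        ).to_csv(self.outdir / "clusters.tsv", sep="\t", index=False)

    def stage_orthology(self) -> None:
        table = io.read_orthogroups(self.path_for("orthogroups", "orthology"))
        classes, events = orthology.classify_orthogroups(table)
        classes.to_csv(self.outdir / "orthology_classes.tsv", sep="\t")
        pd.DataFrame([dataclasses.asdict(e) for e in events]).to_csv(
            self.outdir / "turnover_events.tsv", sep="\t", index=False
        )

    def stage_de(self) -> None:
        cfg = self.config
        counts = io.read_expression_table(_require(cfg.counts, "counts", "de"))
        groups = pd.read_csv(
            _require(cfg.groups, "groups", "de"), sep="\t", index_col=0
        ).iloc[:, 0]
        result = de.nb_wald_test(counts, groups)
        result.to_csv(self.outdir / "de_results.tsv", sep="\t")

    def stage_modules(self) -> None:
        cfg = self.config
        expr = io.read_expression_table(self.path_for("coexpression", "modules")
                                        if cfg.expression is None
                                        else cfg.expression)
        samples = pd.read_csv(self.path_for("samples", "modules"), sep="\t")
        net_cfg = network.NetworkConfig(
            beta=cfg.beta,
            min_module_size=cfg.min_module_size,
            filter_quantile=cfg.filter_quantile,
        )
        transformed = network.transform_and_filter(expr, net_cfg)
        tom = network.topological_overlap(network.adjacency(transformed, net_cfg))
        assignment = network.detect_modules(tom, net_cfg)
        assignment.rename_axis("transcript_id").to_csv(
            self.outdir / "module_assignment.tsv", sep="\t"
        )
        network.module_profiles(assignment, transformed, samples).to_csv(
            self.outdir / "module_profiles.tsv", sep="\t"
        )

    def stage_dnds(self) -> None:
        cfg = self.config
        seqs = io.read_fasta(self.path_for("pair_fasta", "dnds"))
        pairs: dict[str, dict[str, str]] = {}
        for name, seq in seqs.items():
            pair_id, _, member = name.rpartition("_")
            pairs.setdefault(pair_id or name, {})[member] = seq
        stats_list = []
        for pair_id, members in sorted(pairs.items()):
            if len(members) != 2:
                raise ConfigurationError(
                    f"pair {pair_id!r} has {len(members)} sequences, expected 2"
                )
            s1, s2 = (members[k] for k in sorted(members))
            stats_list.append(molevol.pairwise_dnds(s1, s2, pair_id=pair_id))
        _, report = molevol.apply_ds_filters(stats_list, cfg.min_ds, cfg.max_ds)
        pd.DataFrame([dataclasses.asdict(s) for s in stats_list]).to_csv(
            self.outdir / "dnds_stats.tsv", sep="\t", index=False
        )
        report.to_csv(self.outdir / "dnds_filters.tsv", sep="\t", index=False)

    def stage_report(self) -> None:
        summary: dict[str, float | int] = {}
        for species in fixtures.SAMPLES:
            for key, value in fixtures.summarize_toxin_table(species).items():
                summary[f"{species}_{key}"] = value
        for comparison, tag in (("A", "typeA"), ("A+B", "typeAB")):
            table = fixtures.load_de_table(comparison)
            summary[f"de_{tag}_significant"] = de.count_significant(
                table, alpha=self.config.alpha
            )
        expr, annot = fixtures.toxin_expression("nigroviridis")
        comp = composition.family_composition(expr, annot)
        summary["pla2_share_CLP1864_percent"] = float(comp.loc["PLA2", "CLP1864"])
        with open(self.outdir / "report.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> Path:
    """Execute the requested stages in canonical order; returns the outdir."""
    requested = list(stages or STAGES)
    unknown = sorted(set(requested) - set(STAGES))
    if unknown:
        raise ConfigurationError(f"unknown stages {unknown}")
    run = _Run(config)
    ordered = [s for s in STAGES if s in requested]
    for stage in ordered:
        getattr(run, f"stage_{stage}")()
    log = {"seed": config.seed, "stages": ordered, "thresholds": config.to_dict()}
    with open(run.outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=str)
    return run.outdir
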