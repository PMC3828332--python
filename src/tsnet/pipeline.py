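"""End-to-end orchestration: inputs -> DEI groups -> strengths -> fits ->
networks -> enrichment, with persisted intermediates and a run report.

Every stage reads its inputs from files (either the original inputs or the
previous stage's outputs under ``out_dir``), so any stage can be re-run from
persisted intermediates. All randomness lives in the fixture generator; the
inference itself is deterministic, so two runs from the same inputs produce
identical outputs (the report's wall-clock field aside).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import enrichment as enr
from . import networks as nets
from . import preprocess as prep
from . import sf_binding as sfb
from . import tf_binding as tfb
from .genomics import (
    ConservationTrack,
    expression_samples,
    read_expression,
    read_genome,
    read_isoform_models,
    sample_condition,
)
from .lars import FitOptions, FitResult, fit_group

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    # input paths
    genome: str = ""
    gtf: str = ""
    expression: str = ""
    pwms: str = ""
    sf_motifs: str = ""
    conservation: str = ""
    gene_sets: str = ""
    out_dir: str = "tsnet_out"
    # thresholds (defaults are the method's stated constants)
    fpkm_min: float = 5.0
    motif_abs_score_min: float = 5.0
    motif_len_max: int = 15
    conservation_min: float = 2.0
    promoter_len: int = 2000
    splice_flank: int = 200
    threshold_fraction: float = 0.8
    group_size: tuple[int, int] = (10, 30)
    correlation_cut: float = 0.5
    r2_min: float = 0.5
    go_size: tuple[int, int] = (10, 100)
    q_alpha: float = 0.05
    criterion: str = "ebic"
    response: str = "condition_mean"
    universe: str = "intersection"      # collection | experiment | intersection
    seed: int = 7

    def validate(self):
        for name in ("fpkm_min", "motif_abs_score_min", "conservation_min",
                     "promoter_len", "splice_flank", "q_alpha", "threshold_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config {name} must be positive")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Flat key = value text; pairs like group_size use 'lo,hi'."""
        cfg = cls()
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if not hasattr(cfg, key):
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, tuple):
                parts = [p.strip() for p in value.split(",")]
                setattr(cfg, key, tuple(int(p) for p in parts))
            elif isinstance(current, bool):
                setattr(cfg, key, value.lower() in ("1", "true", "yes"))
            elif isinstance(current, int):
                setattr(cfg, key, int(value))
            elif isinstance(current, float):
                setattr(cfg, key, float(value))
            else:
                setattr(cfg, key, value)
        return cfg


@dataclass
class RunReport:
    n_isoforms_in: int = 0
    n_deis: int = 0
    n_groups: int = 0
    n_fits: int = 0
    n_kept_networks: int = 0
    per_group_adjusted_r2: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    wall_clock: float = 0.0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def _out(config: RunConfig) -> Path:
    p = Path(config.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _write_fasta(path: Path, records: dict[str, str]):
    with open(path, "w") as fh:
        for name in sorted(records):
            fh.write(f">{name}\n")
            seq = records[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


# ---------------------------------------------------------------- stages


def stage_preprocess(config: RunConfig) -> list[prep.CoexpressionGroup]:
    out = _out(config)
    df = read_expression(config.expression)
    records = prep.records_from_frame(df)
    deis = prep.filter_deis(records, fpkm_min=config.fpkm_min)
    groups, report = prep.cluster_coexpressed(
        prep.expression_frame(deis),
        size_range=tuple(config.group_size),
        correlation_cut=config.correlation_cut,
    )
    pd.DataFrame(
        [(g.group_id, m) for g in groups for m in g.members],
        columns=["group_id", "isoform_id"],
    ).to_csv(out / "groups.tsv", sep="\t", index=False)
    report["n_deis"] = len(deis)
    report["n_records"] = len(records)
    (out / "clustering_report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True)
    )
    return groups


def stage_score_tf(config: RunConfig) -> pd.DataFrame:
    out = _out(config)
    genome = read_genome(config.genome)
    models = read_isoform_models(config.gtf)
    pwms = tfb.read_jaspar_pwms(config.pwms)
    prd, _ = tfb.extract_promoters(models, genome, promoter_len=config.promoter_len)
    _write_fasta(out / "prd.fa", prd)
    sites = tfb.scan_promoters(prd, pwms, threshold_fraction=config.threshold_fraction)
    pd.DataFrame(
        [(s.factor, s.isoform, s.start, s.end, s.strand, s.score) for s in sites],
        columns=["factor", "isoform", "start", "end", "strand", "score"],
    ).to_csv(out / "tf_sites.tsv", sep="\t", index=False, float_format="%.6f")
    mat = tfb.tf_strength_matrix(
        sites, [m.isoform_id for m in models], [p.name for p in pwms]
    )
    mat.to_csv(out / "tf_strength.tsv", sep="\t", float_format="%.6f")
    return mat


def stage_score_sf(config: RunConfig) -> pd.DataFrame:
    out = _out(config)
    genome = read_genome(config.genome)
    models = read_isoform_models(config.gtf)
    motifs = sfb.filter_sf_motifs(
        sfb.load_sf_motifs(config.sf_motifs),
        min_abs_score=config.motif_abs_score_min,
        max_len=config.motif_len_max,
    )
    track = ConservationTrack.from_bedgraph(
        config.conservation, {c: len(s) for c, s in genome.items()}
    )
    windows = sfb.extract_splice_windows(
        models, flank=config.splice_flank,
        contig_lengths={c: len(s) for c, s in genome.items()},
    )
    eid = {
        f"{w.isoform}|{w.chrom}:{w.start}-{w.end}": genome[w.chrom][w.start:w.end]
        for w in windows
    }
    _write_fasta(out / "eid.fa", eid)
    strands = {m.isoform_id: m.strand for m in models}
    hits = sfb.score_sf_hits(
        windows, motifs, genome, track,
        min_conservation=config.conservation_min, isoform_strands=strands,
    )
    pd.DataFrame(
        [(h.factor, h.isoform, h.chrom, h.start, h.end, h.conservation) for h in hits],
        columns=["factor", "isoform", "chrom", "start", "end", "conservation"],
    ).to_csv(out / "sf_hits.tsv", sep="\t", index=False, float_format="%.6f")
    mat = sfb.sf_strength_matrix(
        hits, [m.isoform_id for m in models],
        sorted({m.factor for m in motifs}),
    )
    mat = sfb.merge_paralog_factors(mat, sfb.applicable_merges(mat))
    mat.to_csv(out / "sf_strength.tsv", sep="\t", float_format="%.6f")
    return mat


def _load_groups(config: RunConfig) -> list[prep.CoexpressionGroup]:
    out = _out(config)
    df = read_expression(config.expression)
    samples = expression_samples(df)
    members = pd.read_csv(out / "groups.tsv", sep="\t", dtype={"isoform_id": str})
    groups = []
    for gid, sub in members.groupby("group_id", sort=True):
        ids = list(sub["isoform_id"])
        groups.append(prep.CoexpressionGroup(int(gid), ids, df.loc[ids, samples]))
    return groups


def stage_fit(config: RunConfig) -> list[FitResult]:
    out = _out(config)
    groups = _load_groups(config)
    tf_mat = pd.read_csv(out / "tf_strength.tsv", sep="\t", index_col=0)
    sf_mat = pd.read_csv(out / "sf_strength.tsv", sep="\t", index_col=0)
    df = read_expression(config.expression)
    sample_conds = {s: sample_condition(s) for s in expression_samples(df)}
    up_conds = dict(zip(df["isoform_id"], df["up_condition"]))
    opts = FitOptions(response=config.response, criterion=config.criterion,
                      r2_min=config.r2_min)
    fits = []
    fit_dir = out / "fits"
    fit_dir.mkdir(exist_ok=True)
    for g in groups:
        fit = fit_group(g, tf_mat, sf_mat, sample_conds, up_conds, opts)
        fits.append(fit)
        payload = {
            "group_id": fit.group_id,
            "selected": [
                {"factor": f, "type": fit.factor_types[f],
                 "coefficient": fit.coefficients[f]}
                for f in fit.selected
            ],
            "intercept": fit.intercept,
            "adjusted_r2": fit.adjusted_r2,
            "kept": fit.kept,
            "step": fit.step,
            "criterion": fit.criterion,
            "criterion_trace": fit.criterion_trace,
        }
        (fit_dir / f"fit_{g.group_id}.json").write_text(
            json.dumps(payload, indent=1, sort_keys=True)
        )
    return fits


def stage_networks(config: RunConfig, fits: list[FitResult] | None = None
                   ) -> list[nets.RegulatoryNetwork]:
    out = _out(config)
    groups = _load_groups(config)
    if fits is None:
        fits = stage_fit(config)
    tf_mat = pd.read_csv(out / "tf_strength.tsv", sep="\t", index_col=0)
    sf_mat = pd.read_csv(out / "sf_strength.tsv", sep="\t", index_col=0)
    df = read_expression(config.expression)
    gene_names = dict(zip(df["isoform_id"], df["gene_id"]))
    networks = [
        nets.assemble_network(fit, g, tf_mat, sf_mat, gene_names)
        for fit, g in zip(fits, groups)
        if fit.kept
    ]
    nets.write_networks(networks, out / "networks.tsv", out / "graphml")
    return networks


def stage_enrich(config: RunConfig) -> pd.DataFrame:
    out = _out(config)
    networks = nets.read_networks(out / "networks.tsv")
    df = read_expression(config.expression)
    experiment_genes = set(df["gene_id"])
    coll = enr.read_gmt(config.gene_sets, name="gene_sets")
    if config.universe == "experiment":
        coll.universe = set(experiment_genes)
    elif config.universe == "intersection":
        coll.universe = coll.universe & experiment_genes
    coll = enr.filter_gene_sets(coll, *config.go_size)
    table = enr.enrich_networks(networks, [coll], alpha=config.q_alpha)
    table.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    return table


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in order and write report.json."""
    config.validate()
    t0 = time.perf_counter()
    out = _out(config)
    df = read_expression(config.expression)
    groups = stage_preprocess(config)
    stage_score_tf(config)
    stage_score_sf(config)
    fits = stage_fit(config)
    networks = stage_networks(config, fits)
    if config.gene_sets:
        stage_enrich(config)
    report = RunReport(
        n_isoforms_in=len(df),
        n_deis=json.loads((out / "clustering_report.json").read_text())["n_deis"],
        n_groups=len(groups),
        n_fits=len(fits),
        n_kept_networks=len(networks),
        per_group_adjusted_r2={
            str(f.group_id): round(f.adjusted_r2, 6) for f in fits
        },
        versions={
            "tsnet": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        config={k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(config).items()},
        wall_clock=round(time.perf_counter() - t0, 3),
    )
    (out / "report.json").write_text(report.to_json())
    return report
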