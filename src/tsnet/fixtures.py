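"""Seeded synthetic input bundles with planted regulatory structure.

The generator emits every input the pipeline consumes — genome FASTA,
isoform GTF, JASPAR PWMs, a splicing-factor motif table, a base-wise
conservation bedGraph, a per-sample expression table and a gene-set GMT —
together with the ground truth used to plant it. The generative model reads
the inference forward: each co-expression group's per-isoform expression
summary is a linear function of the interaction strengths its planted
binding sites produce, plus additive Gaussian noise;
per-sample values share a group-specific profile whose mean over the
up-regulated condition's samples is exactly 1, so the condition-mean
response recovers the linear value.

Planted TF sites are exact consensus matches of their PWM; planted SF motif
occurrences sit inside splice-site-flanking windows under elevated
conservation, so they survive the |score| >= 5 / length <= 15 /
conservation >= 2 filters by construction.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import sf_binding, tf_binding
from .genomics import ConservationTrack, IsoformModel

log = logging.getLogger(__name__)

# one synthetic chromosome; isoforms tiled in non-overlapping slots so the
# 2000-bp promoters and splice windows of neighbours never collide
CHROM = "chrS"
SLOT = 9000
TSS_OFFSET = 2500                     # leaves the full promoter inside the slot
EXON_LAYOUT = ((0, 300), (1000, 1300), (2000, 2300))   # relative to TSS
PWM_LENGTH = 8
SF_MOTIF_LENGTH = 7
CONDITIONS = ("disease", "control")
N_REPS = 4
_Y_MIN = 10.0                         # keeps every up-condition FPKM above 5


@dataclass
class FixtureConfig:
    seed: int = 7
    n_isoforms: int = 80
    n_groups: int = 3
    group_size_range: tuple[int, int] = (20, 25)
    n_tfs: int = 12
    n_sfs: int = 8
    true_support_per_group: int = 5
    coefficient_magnitude_range: tuple[float, float] = (0.5, 1.5)
    noise_sd: float = 0.05
    genome_gc: float = 0.41
    conservation_background_mean: float = 0.5
    conservation_site_mean: float = 3.0
    group_sizes: tuple[int, ...] | None = None   # explicit sizes override the range

    def validate(self):
        lo, hi = self.group_size_range
        if not (10 <= lo <= hi <= 30):
            raise ValueError("group_size_range must lie within [10, 30]")
        if self.group_sizes is not None:
            if len(self.group_sizes) != self.n_groups:
                raise ValueError("group_sizes must have one entry per group")
            if any(not (lo <= s <= hi) for s in self.group_sizes):
                raise ValueError("group_sizes entries must lie within group_size_range")
            if sum(self.group_sizes) > self.n_isoforms:
                raise ValueError("group_sizes sum exceeds n_isoforms")
        if not (self.conservation_site_mean >= 2 > self.conservation_background_mean):
            raise ValueError(
                "need conservation_site_mean >= 2 > conservation_background_mean"
            )
        if self.true_support_per_group > self.n_tfs + self.n_sfs:
            raise ValueError("true_support_per_group exceeds n_tfs + n_sfs")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 < self.genome_gc < 1):
            raise ValueError("genome_gc must be in (0, 1)")
        if self.group_sizes is None and self.n_groups * hi > self.n_isoforms:
            raise ValueError(
                "n_isoforms too small for n_groups at the top of group_size_range"
            )


@dataclass
class GroundTruth:
    """Planted factors/coefficients per group and site coordinates per isoform."""

    groups: list[dict] = field(default_factory=list)
    planted_sites: dict[str, dict[str, list[list[int]]]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"groups": self.groups, "planted_sites": self.planted_sites},
            indent=1, sort_keys=True,
        )


@dataclass
class FixtureBundle:
    config: FixtureConfig
    paths: dict[str, Path]
    truth: GroundTruth
    models: list[IsoformModel]
    expression: pd.DataFrame            # full-precision, metadata + samples
    tf_strengths: pd.DataFrame
    sf_strengths: pd.DataFrame


def plant_motif(sequence: str, motif: str, position: int) -> str:
    """Replace sequence[position : position + len(motif)] with motif."""
    if position < 0 or position + len(motif) > len(sequence):
        raise ValueError(
            f"motif of length {len(motif)} at {position} exceeds sequence "
            f"length {len(sequence)}"
        )
    return sequence[:position] + motif + sequence[position + len(motif):]


def simulate_group_expression(
    strengths: pd.DataFrame,
    truth: dict,
    noise_sd: float,
    seed: int,
) -> np.ndarray:
    """Generative linear model for one group: intercept + strengths[:,
    support] @ coefficients + Gaussian(0, noise_sd) noise.

    ``truth`` carries 'factors', 'coefficients' and 'intercept'.
    """
    factors = list(truth["factors"])
    unknown = [f for f in factors if f not in strengths.columns]
    if unknown:
        raise KeyError(f"truth factors not in strength matrix: {unknown}")
    coef = np.asarray(truth["coefficients"], dtype=float)
    rng = np.random.default_rng(seed)
    base = truth.get("intercept", 0.0) + strengths[factors].to_numpy(float) @ coef
    return base + rng.normal(0.0, noise_sd, size=len(strengths))


def _random_seq(rng, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _exon_model(i: int, iso_id: str, gene_id: str) -> IsoformModel:
    tss = i * SLOT + TSS_OFFSET
    exons = tuple((tss + a, tss + b) for a, b in EXON_LAYOUT)
    return IsoformModel(iso_id, gene_id, CHROM, "+", exons)


def _write_gtf(path: Path, models: list[IsoformModel]):
    with open(path, "w") as fh:
        for m in models:
            for s, e in m.exons:
                attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.isoform_id}";'
                fh.write(
                    f"{m.chrom}\ttsnet\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def _write_jaspar(path: Path, names: list[str], consensi: list[str]):
    with open(path, "w") as fh:
        for name, cons in zip(names, consensi):
            fh.write(f">{name} {name}\n")
            for base in "ACGT":
                counts = ["850" if c == base else "50" for c in cons]
                fh.write(f"{base}  [ {' '.join(counts)} ]\n")


def _write_bedgraph(path: Path, scores: np.ndarray):
    n = scores.size
    df = pd.DataFrame(
        {
            "chrom": CHROM,
            "start": np.arange(n, dtype=np.int64),
            "end": np.arange(1, n + 1, dtype=np.int64),
            "score": scores,
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.3f")


def generate_gene_sets(
    group_genes: dict[int, list[str]],
    universe: list[str],
    seed: int,
    planted_fraction: float = 0.8,
    n_random_sets: int = 10,
    set_size: int = 30,
) -> dict[str, list[str]]:
    """Synthetic gene-set collection: one planted set per group (drawing
    ``planted_fraction`` of its members from the group's genes) plus random
    filler sets over the same universe."""
    rng = np.random.default_rng(seed)
    universe = sorted(universe)
    sets: dict[str, list[str]] = {}
    for gid in sorted(group_genes):
        genes = sorted(group_genes[gid])
        n_from_group = min(len(genes), int(round(planted_fraction * set_size)))
        chosen = list(rng.choice(genes, size=n_from_group, replace=False))
        others = sorted(set(universe) - set(chosen))
        n_fill = min(max(set_size - n_from_group, 0), len(others))
        chosen += list(rng.choice(others, size=n_fill, replace=False))
        sets[f"PLANTED_SET_G{gid}"] = sorted(chosen)
    for k in range(n_random_sets):
        size = int(rng.integers(12, 40))
        sets[f"RANDOM_SET_{k + 1:02d}"] = sorted(
            rng.choice(universe, size=min(size, len(universe)), replace=False)
        )
    return sets


def write_gmt(path: Path, sets: dict[str, list[str]]):
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, "synthetic"] + list(sets[name])) + "\n")


def generate_fixture(config: FixtureConfig, out_dir) -> FixtureBundle:
    """Generate and write the full input bundle; deterministic in (config, seed)."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    n_iso = config.n_isoforms
    iso_ids = [f"iso{i + 1:04d}" for i in range(n_iso)]
    gene_ids = [f"g{i + 1:04d}" for i in range(n_iso)]
    models = [_exon_model(i, iso_ids[i], gene_ids[i]) for i in range(n_iso)]
    genome_len = n_iso * SLOT + 2000
    genome_seq = _random_seq(rng, genome_len, config.genome_gc)

    # --- factors ----------------------------------------------------------
    tf_names = [f"TF{j + 1:02d}" for j in range(config.n_tfs)]
    tf_consensi = [_random_seq(rng, PWM_LENGTH, 0.5) for _ in tf_names]
    sf_names = [f"SF{k + 1:02d}" for k in range(config.n_sfs)]
    sf_seqs = [_random_seq(rng, SF_MOTIF_LENGTH, 0.5) for _ in sf_names]
    sf_scores = [
        float(np.round(rng.uniform(5.0, 10.0) * (1 if rng.random() < 0.5 else -1), 2))
        for _ in sf_names
    ]

    # --- group membership and planted support -----------------------------
    lo, hi = config.group_size_range
    if config.group_sizes is not None:
        sizes = [int(s) for s in config.group_sizes]
    else:
        sizes = [int(rng.integers(lo, hi + 1)) for _ in range(config.n_groups)]
    order = rng.permutation(n_iso)
    groups: dict[int, list[int]] = {}
    cursor = 0
    for gid, size in enumerate(sizes, start=1):
        groups[gid] = sorted(int(i) for i in order[cursor:cursor + size])
        cursor += size
    background = sorted(int(i) for i in order[cursor:])

    all_factors = tf_names + sf_names
    support: dict[int, list[str]] = {
        gid: sorted(rng.choice(all_factors, size=config.true_support_per_group,
                               replace=False))
        for gid in groups
    }

    # --- plant sites ------------------------------------------------------
    seq = list(genome_seq)
    truth = GroundTruth()
    site_levels: list[tuple[int, int, float]] = []   # conservation overrides
    # grid cells (spaced 2x motif length, hence non-overlapping) already used
    # per isoform, so one factor's planted site never overwrites another's
    used_cells: dict[tuple[int, str], set[int]] = {}

    def plant(start: int, motif: str):
        seq[start:start + len(motif)] = list(motif)

    def pick_cells(iso_idx: int, region: str, grid: np.ndarray, k: int) -> list[int]:
        used = used_cells.setdefault((iso_idx, region), set())
        free = np.array([g for g in grid if g not in used])
        chosen = sorted(int(p) for p in rng.choice(free, size=k, replace=False))
        used.update(chosen)
        return chosen

    for gid in sorted(groups):
        members = groups[gid]
        for fac in support[gid]:
            for i in members:
                m = models[i]
                sites = truth.planted_sites.setdefault(iso_ids[i], {}).setdefault(fac, [])
                k = int(rng.integers(1, 4))
                if fac in tf_names:
                    cons = tf_consensi[tf_names.index(fac)]
                    prom_start = m.tss - tf_binding.PROMOTER_LEN
                    grid = np.arange(
                        0, tf_binding.PROMOTER_LEN - PWM_LENGTH, 2 * PWM_LENGTH
                    )
                    for off in pick_cells(i, "promoter", grid, k):
                        plant(prom_start + off, cons)
                        sites.append([prom_start + off, prom_start + off + PWM_LENGTH])
                else:
                    motif = sf_seqs[sf_names.index(fac)]
                    windows = sf_binding.extract_splice_windows([m])
                    grid = np.concatenate(
                        [np.arange(w.start, w.end - SF_MOTIF_LENGTH, 2 * SF_MOTIF_LENGTH)
                         for w in windows]
                    )
                    for pos in pick_cells(i, "windows", grid, k):
                        plant(pos, motif)
                        sites.append([pos, pos + SF_MOTIF_LENGTH])
                        level = float(rng.uniform(config.conservation_site_mean,
                                                  config.conservation_site_mean + 2.0))
                        site_levels.append((pos, pos + SF_MOTIF_LENGTH, level))
    genome_seq = "".join(seq)
    genome = {CHROM: genome_seq}

    # --- conservation track (per-base; rounded before use so the in-memory
    # track equals what the bedGraph round-trips) --------------------------
    cons = np.clip(
        rng.normal(config.conservation_background_mean, 0.5, size=genome_len), 0.0, None
    )
    for s, e, level in site_levels:
        cons[s:e] = level
    cons = np.round(cons, 3)
    track = ConservationTrack({CHROM: cons})

    # --- strengths as the pipeline will compute them ----------------------
    pwms = [
        tf_binding.PWM(name, _consensus_matrix(c))
        for name, c in zip(tf_names, tf_consensi)
    ]
    prd, _ = tf_binding.extract_promoters(models, genome)
    tf_sites = tf_binding.scan_promoters(prd, pwms)
    tf_mat = tf_binding.tf_strength_matrix(tf_sites, iso_ids, tf_names)
    tf_mat = tf_mat.reindex(columns=tf_names, fill_value=0.0)

    sf_motifs = [SF for SF in (sf_binding.SFMotif(n, s, sc)
                               for n, s, sc in zip(sf_names, sf_seqs, sf_scores))]
    windows = sf_binding.extract_splice_windows(models)
    sf_hits = sf_binding.score_sf_hits(
        windows, sf_binding.filter_sf_motifs(sf_motifs), genome, track
    )
    sf_mat = sf_binding.sf_strength_matrix(sf_hits, iso_ids, sf_names)

    strengths = pd.concat([tf_mat, sf_mat], axis=1)

    # --- expression -------------------------------------------------------
    samples = [f"{c}_{r + 1}" for c in CONDITIONS for r in range(N_REPS)]
    sample_cond = np.array([s.rpartition("_")[0] for s in samples])
    n_samples = len(samples)

    # orthogonal zero-mean group profiles keep cross-group correlation low
    raw = rng.normal(size=(n_samples, config.n_groups))
    raw -= raw.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(raw)

    expr = np.zeros((n_iso, n_samples))
    up_condition = np.array([CONDITIONS[0]] * n_iso, dtype=object)
    de_flag = np.zeros(n_iso, dtype=int)
    protein = np.ones(n_iso, dtype=int)

    for g_index, (gid, members) in enumerate(sorted(groups.items())):
        up = CONDITIONS[g_index % 2]
        facs = support[gid]
        sub = strengths.iloc[members][facs].to_numpy(float)
        mags = rng.uniform(*config.coefficient_magnitude_range, size=len(facs))
        signs = np.where(rng.random(len(facs)) < 0.5, 1.0, -1.0)
        coef = mags * signs
        intercept = 20.0
        y = intercept + sub @ coef      # the linear model read forward
        if y.min() < _Y_MIN:
            delta = _Y_MIN - y.min()
            intercept += delta
            y = y + delta
        y = y + rng.normal(0.0, config.noise_sd, size=len(members))

        u = q[:, g_index]
        amp = 0.25 / np.abs(u).max()
        profile = 1.0 + amp * u
        down_mult = float(rng.uniform(0.25, 0.55))
        profile = np.where(sample_cond == up, profile, profile * down_mult)
        profile = profile / profile[sample_cond == up].mean()

        expr[members] = np.outer(y, profile)
        up_condition[members] = up
        de_flag[members] = 1
        truth.groups.append(
            {
                "group_id": gid,
                "members": [iso_ids[i] for i in members],
                "up_condition": up,
                "factors": [str(f) for f in facs],
                "factor_types": ["TF" if f in tf_names else "SF" for f in facs],
                "coefficients": [float(c) for c in coef],
                "intercept": float(intercept),
                "noise_sd": config.noise_sd,
            }
        )

    # background isoforms: each fails exactly one DEI filter
    for pos, i in enumerate(background):
        base = rng.uniform(6.0, 50.0)
        expr[i] = np.clip(base * (1 + 0.2 * rng.normal(size=n_samples)), 0.1, None)
        up_condition[i] = CONDITIONS[int(rng.integers(2))]
        mode = pos % 3
        de_flag[i] = 0 if mode == 0 else 1
        protein[i] = 0 if mode == 1 else 1
        if mode == 2:
            de_flag[i] = 1
            low_sample = int(np.where(sample_cond == up_condition[i])[0][0])
            expr[i, low_sample] = 3.0   # one up-condition FPKM at/below the cutoff

    expression = pd.DataFrame(
        {
            "isoform_id": iso_ids,
            "gene_id": gene_ids,
            "protein_evidence": protein,
            "de_flag": de_flag,
            "up_condition": up_condition,
        }
    )
    expression = pd.concat(
        [expression, pd.DataFrame(expr, columns=samples)], axis=1
    ).set_index("isoform_id", drop=False)

    # --- write the bundle -------------------------------------------------
    paths = {
        "genome": out / "genome.fa",
        "gtf": out / "isoforms.gtf",
        "pwms": out / "pwms.jaspar",
        "sf_motifs": out / "sf_motifs.tsv",
        "conservation": out / "conservation.bedGraph",
        "expression": out / "expression.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "truth": out / "truth.json",
    }
    with open(paths["genome"], "w") as fh:
        fh.write(f">{CHROM}\n")
        for i in range(0, genome_len, 80):
            fh.write(genome_seq[i:i + 80] + "\n")
    _write_gtf(paths["gtf"], models)
    _write_jaspar(paths["pwms"], tf_names, tf_consensi)
    sf_rows = [{"factor": n, "motif": s, "score": sc}
               for n, s, sc in zip(sf_names, sf_seqs, sf_scores)]
    # decoy rows exercising the motif filters downstream
    sf_rows.append({"factor": "DECOY_WEAK", "motif": "ACGTACG", "score": 3.0})
    sf_rows.append({"factor": "DECOY_LONG", "motif": "A" * 16, "score": 8.0})
    pd.DataFrame(sf_rows).to_csv(paths["sf_motifs"], sep="\t", index=False)
    _write_bedgraph(paths["conservation"], cons)
    expression.to_csv(paths["expression"], sep="\t", index=False, float_format="%.6f")
    group_genes = {
        g["group_id"]: [gene_ids[iso_ids.index(m)] for m in g["members"]]
        for g in truth.groups
    }
    write_gmt(
        paths["gene_sets"],
        generate_gene_sets(group_genes, gene_ids, seed=config.seed + 1),
    )
    with open(paths["truth"], "w") as fh:
        fh.write(truth.to_json() + "\n")

    return FixtureBundle(
        config=config,
        paths=paths,
        truth=truth,
        models=models,
        expression=expression,
        tf_strengths=tf_mat,
        sf_strengths=sf_mat,
    )


def _consensus_matrix(consensus: str) -> np.ndarray:
    mat = np.full((4, len(consensus)), 0.05)
    for j, b in enumerate(consensus):
        mat["ACGT".index(b), j] = 0.85
    return mat


def simulate_design(
    seed: int,
    n_obs: int = 25,
    n_tf: int = 40,
    n_sf: int = 20,
    support: int = 5,
    coefficient_magnitude_range: tuple[float, float] = (0.5, 1.5),
    noise_sd: float = 0.1,
) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Strength-shaped design matrix plus linear response with known support.

    Column statistics mirror what the genome-scale generator actually
    produces. Support factors have planted sites on every isoform of the
    group: TF strengths are sums of 1-3 near-maximal site scores, SF
    strengths are means of 1-3 elevated conservation levels. Non-support
    factors carry only incidental hits — a few percent nonzero for TFs
    (chance consensus matches in a 2-kb promoter) and essentially none for
    SFs (background conservation almost never clears the >= 2 filter). The
    response is intercept + support columns @ beta + Gaussian noise, the
    generative reading of the regression model. Used for fast
    parameter-recovery experiments without genome scanning.
    """
    rng = np.random.default_rng(seed)
    chosen_idx = rng.choice(n_tf + n_sf, size=support, replace=False)
    names = [f"TF{j + 1:02d}" for j in range(n_tf)] + \
            [f"SF{j + 1:02d}" for j in range(n_sf)]
    chosen = sorted(names[int(i)] for i in chosen_idx)
    cols = {}
    for j, name in enumerate(names):
        is_tf = j < n_tf
        if name in chosen:
            k = rng.integers(1, 4, size=n_obs)
            if is_tf:
                vals = np.array([rng.uniform(12.0, 14.0, kk).sum() for kk in k])
            else:
                vals = np.array([rng.uniform(3.0, 5.0, kk).mean() for kk in k])
        else:
            rate = 0.05 if is_tf else 0.01
            present = rng.random(n_obs) < rate
            level = rng.uniform(10.0, 14.0, n_obs) if is_tf else rng.uniform(2.0, 3.0, n_obs)
            vals = np.where(present, level, 0.0)
        cols[name] = vals
    X = pd.DataFrame(cols)
    sub = X[chosen].to_numpy(float)
    mags = rng.uniform(*coefficient_magnitude_range, size=support)
    coef = mags * np.where(rng.random(support) < 0.5, 1.0, -1.0)
    intercept = 20.0
    y = intercept + sub @ coef + rng.normal(0.0, noise_sd, size=n_obs)
    truth = {
        "factors": chosen,
        "coefficients": [float(c) for c in coef],
        "intercept": intercept,
        "noise_sd": noise_sd,
    }
    return X, y, truth
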