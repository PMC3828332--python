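"""Differentially-expressed-isoform (DEI) filtering and co-expression grouping.

Differential calling itself happens upstream (a Cuffdiff-style tool); this
module consumes its output table and applies the evidence/abundance rules:
an isoform is kept only if it was called differentially expressed, has been
validated at the protein level, and has FPKM strictly above 5 in every
sample of the condition in which it is up-regulated. Kept DEIs are then
clustered on Pearson correlation of their expression profiles into
co-expressed groups constrained to 10-30 members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .genomics import expression_samples, sample_condition

log = logging.getLogger(__name__)

FPKM_MIN = 5.0
GROUP_SIZE_RANGE = (10, 30)
#: flat-cut height on d = 1 - r; merges above it join profiles with r < 0.5,
#: which are not "co-expressed" in any useful sense
CORRELATION_CUT = 0.5


@dataclass(frozen=True)
class IsoformRecord:
    isoform_id: str
    gene_id: str
    fpkm: dict[str, float]          # sample -> FPKM
    conditions: dict[str, str]      # sample -> condition label
    protein_evidence: bool
    de_flag: bool
    up_condition: str


@dataclass
class CoexpressionGroup:
    group_id: int
    members: list[str]
    expression: pd.DataFrame        # members x samples
    mean_pairwise_r: float = float("nan")

    def __post_init__(self):
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"group {self.group_id}: duplicate members")


def records_from_frame(df: pd.DataFrame) -> list[IsoformRecord]:
    samples = expression_samples(df)
    conds = {s: sample_condition(s) for s in samples}
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            IsoformRecord(
                isoform_id=d["isoform_id"],
                gene_id=d["gene_id"],
                fpkm={s: float(d[s]) for s in samples},
                conditions=conds,
                protein_evidence=bool(int(d["protein_evidence"])),
                de_flag=bool(int(d["de_flag"])),
                up_condition=str(d["up_condition"]),
            )
        )
    return out


def filter_deis(records: list[IsoformRecord], fpkm_min: float = FPKM_MIN) -> list[IsoformRecord]:
    """Keep records with de_flag, protein-level evidence, and every FPKM of
    the up-regulated condition strictly greater than ``fpkm_min``."""
    kept = []
    for rec in records:
        up_samples = [s for s, c in rec.conditions.items() if c == rec.up_condition]
        if not up_samples:
            raise ValueError(
                f"isoform {rec.isoform_id}: no samples for its up-regulated "
                f"condition {rec.up_condition!r}"
            )
        if not rec.de_flag or not rec.protein_evidence:
            continue
        if all(rec.fpkm[s] > fpkm_min for s in up_samples):
            kept.append(rec)
    log.info("filter_deis: kept %d / %d isoforms", len(kept), len(records))
    return kept


def _recut(linkage_members: list[int], expr: np.ndarray, size_range) -> list[list[int]]:
    """Recursively split an oversized cluster at its own merge heights."""
    lo, hi = size_range
    n = len(linkage_members)
    if n < lo:
        return []
    if n <= hi:
        return [linkage_members]
    sub = expr[linkage_members]
    d = ssd.squareform(1.0 - np.corrcoef(sub), checks=False)
    Z = sch.linkage(d, method="average")
    labels = sch.cut_tree(Z, n_clusters=2).ravel()
    out = []
    for lab in (0, 1):
        child = [m for m, l in zip(linkage_members, labels) if l == lab]
        out.extend(_recut(child, expr, size_range))
    return out


def cluster_coexpressed(
    expression: pd.DataFrame,
    size_range: tuple[int, int] = GROUP_SIZE_RANGE,
    correlation_cut: float = CORRELATION_CUT,
) -> tuple[list[CoexpressionGroup], dict]:
    """Average-linkage hierarchical clustering on d = 1 - Pearson r.

    Flat clusters are cut at ``correlation_cut``; clusters larger than the
    size range are recursively re-cut at their own merge heights, and
    clusters below it are dropped (logged). Signed correlation is used:
    co-expression means positive correlation. Returns the groups and a
    report dict (per-group size and mean pairwise r, plus drop counts).

    Constant-expression rows (undefined correlation) are removed first.
    """
    lo, hi = size_range
    expr = expression.sort_index()
    if len(expr) < lo:
        log.warning("cluster_coexpressed: only %d DEIs (< %d); no groups",
                    len(expr), lo)
        return [], {"n_input": int(len(expr)), "groups": [],
                    "n_dropped_isoforms": int(len(expr))}
    vals = expr.to_numpy(float)
    sds = vals.std(axis=1)
    const = sds <= 1e-12 * max(1.0, float(np.abs(vals).max()))
    if const.any():
        log.warning(
            "cluster_coexpressed: dropping %d constant-expression isoform(s)",
            int(const.sum()),
        )
        expr = expr.loc[~const]
        vals = expr.to_numpy(float)
    n = len(expr)
    report: dict = {"n_input": int(n), "groups": [], "n_dropped_isoforms": 0}
    if n < lo:
        log.warning("cluster_coexpressed: only %d DEIs (< %d); no groups", n, lo)
        report["n_dropped_isoforms"] = int(n)
        return [], report
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples to correlate expression profiles")

    corr = np.corrcoef(vals)
    d = ssd.squareform(np.clip(1.0 - corr, 0.0, 2.0), checks=False)
    Z = sch.linkage(d, method="average")
    labels = sch.fcluster(Z, t=correlation_cut, criterion="distance")

    member_lists: list[list[int]] = []
    for lab in np.unique(labels):
        idx = [int(i) for i in np.where(labels == lab)[0]]
        member_lists.extend(_recut(idx, vals, size_range))

    # deterministic numbering by first member's isoform_id
    member_lists.sort(key=lambda idx: expr.index[idx[0]])
    groups = []
    used = 0
    for gid, idx in enumerate(member_lists, start=1):
        members = [expr.index[i] for i in idx]
        sub = corr[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        mean_r = float(sub[iu].mean())
        groups.append(
            CoexpressionGroup(gid, members, expr.loc[members], mean_pairwise_r=mean_r)
        )
        report["groups"].append({"group_id": gid, "size": len(members), "mean_r": mean_r})
        used += len(idx)
    report["n_dropped_isoforms"] = int(n - used)
    if n - used:
        log.info("cluster_coexpressed: %d isoform(s) in undersized clusters dropped", n - used)
    return groups, report


def expression_frame(records: list[IsoformRecord]) -> pd.DataFrame:
    """Members x samples FPKM matrix for a list of records."""
    if not records:
        return pd.DataFrame()
    samples = list(records[0].fpkm)
    return pd.DataFrame(
        [[r.fpkm[s] for s in samples] for r in records],
        index=[r.isoform_id for r in records],
        columns=samples,
    )
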