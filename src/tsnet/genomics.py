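"""Shared genomic containers and readers.

Sequence, annotation and conservation inputs are small enough in this
workflow (a promoter/splice-window scan over a few hundred isoforms) to be
held fully in memory: the genome as plain strings, the conservation track as
per-contig float arrays. Coordinates are 0-based half-open everywhere
internally; GTF is converted from 1-based inclusive on input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_genome(path) -> dict[str, str]:
    """Load a FASTA into a dict of uppercase contig sequences."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


@dataclass(frozen=True)
class IsoformModel:
    """Genomic structure of one transcript isoform.

    exons are sorted, non-overlapping 0-based half-open intervals on the
    genome (ascending genomic coordinate regardless of strand).
    """

    isoform_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.isoform_id}: strand must be '+' or '-'")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"{self.isoform_id}: malformed exon ({s},{e})")
            if s < prev_end:
                raise ValueError(f"{self.isoform_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def tss(self) -> int:
        """0-based position of the transcription start base."""
        if self.strand == "+":
            return self.exons[0][0]
        return self.exons[-1][1] - 1

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


def read_isoform_models(gtf_path) -> list[IsoformModel]:
    """Parse exon features of a GTF into IsoformModel records.

    Uses gffutils with an in-memory database; GTF coordinates (1-based
    inclusive) are converted to 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_tx: dict[str, dict] = {}
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        tx = feat.attributes["transcript_id"][0]
        gene = feat.attributes.get("gene_id", [tx])[0]
        entry = per_tx.setdefault(
            tx, {"gene": gene, "chrom": feat.seqid, "strand": feat.strand, "exons": []}
        )
        entry["exons"].append((feat.start - 1, feat.end))
    models = []
    for tx in sorted(per_tx):
        e = per_tx[tx]
        models.append(
            IsoformModel(tx, e["gene"], e["chrom"], e["strand"], tuple(sorted(e["exons"])))
        )
    return models


@dataclass
class ConservationTrack:
    """Base-wise conservation scores (phyloP-scale) held as per-contig arrays.

    Uncovered bases are NaN; querying them is an error, because a motif hit
    without conservation evidence cannot be filtered either way.
    """

    arrays: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_bedgraph(cls, path, contig_lengths: dict[str, int] | None = None):
        df = pd.read_csv(
            str(path), sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "score"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "score": float},
        )
        arrays = {}
        for chrom, sub in df.groupby("chrom", sort=True):
            length = (
                contig_lengths[chrom] if contig_lengths else int(sub["end"].max())
            )
            arr = np.full(length, np.nan)
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            scores = sub["score"].to_numpy()
            if (ends - starts == 1).all():      # per-base track: vectorized fill
                arr[starts] = scores
            else:
                for s, e, v in zip(starts, ends, scores):
                    arr[s:e] = v
            arrays[chrom] = arr
        return cls(arrays)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        if chrom not in self.arrays:
            raise KeyError(f"conservation track has no contig {chrom!r}")
        arr = self.arrays[chrom]
        if start < 0 or end > arr.size:
            raise ValueError(
                f"query {chrom}:{start}-{end} outside track coverage (0-{arr.size})"
            )
        out = arr[start:end]
        if np.isnan(out).any():
            raise ValueError(f"uncovered bases in {chrom}:{start}-{end}")
        return out

    def mean(self, chrom: str, start: int, end: int) -> float:
        return float(self.values(chrom, start, end).mean())


def sample_condition(sample_name: str) -> str:
    """Condition label encoded in a sample column name as '<condition>_<rep>'."""
    cond, _, rep = sample_name.rpartition("_")
    if not cond or not rep:
        raise ValueError(f"sample column {sample_name!r} is not '<condition>_<rep>'")
    return cond


META_COLUMNS = ("isoform_id", "gene_id", "protein_evidence", "de_flag", "up_condition")


def read_expression(path) -> pd.DataFrame:
    """Read the per-sample isoform expression table.

    Layout: metadata columns (isoform_id, gene_id, protein_evidence {0,1},
    de_flag {0,1}, up_condition) followed by one FPKM column per sample,
    named '<condition>_<replicate>'.
    """
    df = pd.read_csv(str(path), sep="\t", dtype={"isoform_id": str, "gene_id": str})
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"expression table missing columns: {missing}")
    df = df.set_index("isoform_id", drop=False)
    sample_cols = [c for c in df.columns if c not in META_COLUMNS]
    if (df[sample_cols].to_numpy(float) < 0).any():
        raise ValueError("negative FPKM values in expression table")
    return df


def expression_samples(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in META_COLUMNS]
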