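"""Splicing-factor motif scoring in splice-site-flanking windows.

The exon-intron dataset (EID) gathers 200 bp on both sides of every
internal splice site of each isoform. Splicing-factor motifs are short
literal sequences (SpliceAid-style) carrying a signed affinity score
(positive = enhancer-type, negative = silencer-type); motifs with
|score| < 5 or length > 15 are discarded. Occurrences are exact substring
matches on the isoform's sense strand within its windows; each hit is
scored by the mean base-wise conservation (phyloP-scale) of the spanned
nucleotides and deleted below 2. The SF-isoform interaction strength is the
mean conservation over the retained hits, which removes the trivial effect
of exon number.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomics import ConservationTrack, IsoformModel, reverse_complement

log = logging.getLogger(__name__)

SPLICE_FLANK = 200
MOTIF_ABS_SCORE_MIN = 5.0
MOTIF_LEN_MAX = 15
CONSERVATION_MIN = 2.0

#: paralogous hnRNP factors whose binding profiles are near-identical; their
#: strength columns are averaged into one merged factor
DEFAULT_PARALOG_MERGES = [
    ("hnRNP A1/A2", ["hnRNP A1", "hnRNP A2"]),
    ("hnRNP H1/H2/H3", ["hnRNP H1", "hnRNP H2", "hnRNP H3"]),
    ("hnRNP C/C1/C2", ["hnRNP C", "hnRNP C1", "hnRNP C2"]),
    ("hnRNP E1/E2", ["hnRNP E1", "hnRNP E2"]),
]


@dataclass(frozen=True)
class SFMotif:
    factor: str
    motif: str          # DNA alphabet; U is mapped to T on construction
    score: float        # signed SpliceAid-style affinity

    def __post_init__(self):
        object.__setattr__(self, "motif", self.motif.upper().replace("U", "T"))
        bad = set(self.motif) - set("ACGT")
        if bad:
            raise ValueError(
                f"motif {self.motif!r} of {self.factor}: non-ACGTU characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class SpliceWindow:
    isoform: str
    chrom: str
    start: int
    end: int
    splice_sites: tuple[int, ...]

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError("malformed splice window")


@dataclass(frozen=True)
class SFHit:
    factor: str
    isoform: str
    chrom: str
    start: int
    end: int
    conservation: float


def load_sf_motifs(path) -> list[SFMotif]:
    """Read the factor/motif/score TSV (SpliceAid-style)."""
    df = pd.read_csv(str(path), sep="\t", dtype={"factor": str, "motif": str})
    return [SFMotif(r.factor, r.motif, float(r.score)) for r in df.itertuples()]


def filter_sf_motifs(
    motifs: list[SFMotif],
    min_abs_score: float = MOTIF_ABS_SCORE_MIN,
    max_len: int = MOTIF_LEN_MAX,
) -> list[SFMotif]:
    """Keep motifs with |score| >= 5 and length <= 15 (idempotent)."""
    return [m for m in motifs if abs(m.score) >= min_abs_score and len(m.motif) <= max_len]


def extract_splice_windows(
    isoforms: list[IsoformModel],
    flank: int = SPLICE_FLANK,
    contig_lengths: dict[str, int] | None = None,
) -> list[SpliceWindow]:
    """EID: [p - 200, p + 200) around each internal splice site, clipped to
    contig bounds and merged per isoform when overlapping. Single-exon
    isoforms contribute nothing."""
    windows = []
    for iso in isoforms:
        if len(iso.exons) < 2:
            continue
        sites = []
        for i, (s, e) in enumerate(iso.exons):
            if i < len(iso.exons) - 1:
                sites.append(e)     # donor side of the downstream intron
            if i > 0:
                sites.append(s)     # acceptor side of the upstream intron
        sites = sorted(set(sites))
        limit = contig_lengths.get(iso.chrom) if contig_lengths else None
        raw = []
        for p in sites:
            a = max(0, p - flank)
            b = p + flank if limit is None else min(p + flank, limit)
            raw.append((a, b, p))
        merged: list[list] = []
        for a, b, p in raw:
            if merged and a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
                merged[-1][2].append(p)
            else:
                merged.append([a, b, [p]])
        windows.extend(
            SpliceWindow(iso.isoform_id, iso.chrom, a, b, tuple(ps))
            for a, b, ps in merged
        )
    return windows


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def score_sf_hits(
    windows: list[SpliceWindow],
    motifs: list[SFMotif],
    genome: dict[str, str],
    track: ConservationTrack,
    min_conservation: float = CONSERVATION_MIN,
    isoform_strands: dict[str, str] | None = None,
    sense_only: bool = True,
) -> list[SFHit]:
    """Exact motif matches within windows, conservation-scored and filtered.

    Matches are on the isoform's sense strand (pre-mRNA reading); for a
    minus-strand isoform that means the reverse complement of the motif on
    the forward genome. Set sense_only=False to search both orientations.
    Duplicate coordinates arising from merged/split windows are emitted once.
    """
    strands = isoform_strands or {}
    seen: set[tuple] = set()
    hits = []
    for w in windows:
        seq = genome[w.chrom][w.start:w.end].upper()
        window_cons = track.values(w.chrom, w.start, w.end)   # errors if uncovered
        strand = strands.get(w.isoform, "+")
        for m in motifs:
            queries = [m.motif if strand == "+" else reverse_complement(m.motif)]
            if not sense_only:
                queries.append(reverse_complement(queries[0]))
            for q in dict.fromkeys(queries):
                for off in _find_all(seq, q):
                    gstart, gend = w.start + off, w.start + off + len(q)
                    key = (m.factor, w.isoform, w.chrom, gstart, gend)
                    if key in seen:
                        continue
                    seen.add(key)
                    cons = float(window_cons[off:off + len(q)].mean())
                    if cons >= min_conservation:
                        hits.append(SFHit(m.factor, w.isoform, w.chrom, gstart, gend, cons))
    hits.sort(key=lambda h: (h.isoform, h.factor, h.chrom, h.start))
    return hits


def sf_strength_matrix(
    hits: list[SFHit],
    isoforms: list[str],
    factors: list[str],
) -> pd.DataFrame:
    """Isoforms x SFs matrix: mean hit conservation, 0 when no retained hits."""
    sums = pd.DataFrame(0.0, index=list(isoforms), columns=list(factors))
    counts = pd.DataFrame(0, index=list(isoforms), columns=list(factors))
    for h in hits:
        if h.isoform not in sums.index:
            raise KeyError(f"hit references unknown isoform {h.isoform!r}")
        if h.factor not in sums.columns:
            raise KeyError(f"hit references unknown factor {h.factor!r}")
        sums.loc[h.isoform, h.factor] += h.conservation
        counts.loc[h.isoform, h.factor] += 1
    with np.errstate(invalid="ignore"):
        mat = sums / counts
    return mat.fillna(0.0)


def merge_paralog_factors(
    matrix: pd.DataFrame,
    merge_groups: list[tuple[str, list[str]]] = DEFAULT_PARALOG_MERGES,
) -> pd.DataFrame:
    """Replace each merge group's columns by their element-wise mean."""
    out = matrix.copy()
    for new_name, members in merge_groups:
        missing = [m for m in members if m not in out.columns]
        if missing:
            raise KeyError(f"merge group {new_name!r}: missing columns {missing}")
        merged = out[members].mean(axis=1)
        out = out.drop(columns=members)
        out[new_name] = merged
    return out


def applicable_merges(
    matrix: pd.DataFrame,
    merge_groups: list[tuple[str, list[str]]] = DEFAULT_PARALOG_MERGES,
) -> list[tuple[str, list[str]]]:
    """Subset of merge groups whose members are all present in the matrix."""
    return [
        (name, members)
        for name, members in merge_groups
        if all(m in matrix.columns for m in members)
    ]


def genome_scan_targets(
    motif: SFMotif,
    genes: list[tuple[str, str, int, int]],   # (gene_id, chrom, start, end)
    genome: dict[str, str],
    track: ConservationTrack,
    keep_fraction: float = 1.0 / 3.0,
) -> tuple[list[tuple[str, str, int, int, float]], list[str]]:
    """Genome-wide single-factor target scan.

    All exact motif matches (either orientation) are scored by mean
    conservation; the top ceil(keep_fraction * n) by conservation are kept
    (ties broken by coordinate) and mapped to overlapping gene bodies.
    Returns (kept hits as (gene, chrom, start, end, conservation) with
    gene '' when intergenic, deduplicated gene list).
    """
    if not (0 < keep_fraction <= 1):
        raise ValueError("keep_fraction must be in (0, 1]")
    raw = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        for q in dict.fromkeys([motif.motif, reverse_complement(motif.motif)]):
            for off in _find_all(seq, q):
                raw.append((chrom, off, off + len(q)))
    if not raw:
        log.warning("genome_scan_targets: no occurrences of %s", motif.motif)
        return [], []
    raw = sorted(set(raw))
    scored = [(c, s, e, track.mean(c, s, e)) for c, s, e in raw]
    n_keep = math.ceil(keep_fraction * len(scored))
    scored.sort(key=lambda t: (-t[3], t[0], t[1], t[2]))
    kept = scored[:n_keep]

    results = []
    genes_hit = []
    for chrom, s, e, cons in sorted(kept):
        overlapping = [g for g, gc, gs, ge in genes if gc == chrom and s < ge and gs < e]
        if overlapping:
            for g in overlapping:
                results.append((g, chrom, s, e, cons))
                genes_hit.append(g)
        else:
            results.append(("", chrom, s, e, cons))
    return results, sorted(dict.fromkeys(genes_hit))
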