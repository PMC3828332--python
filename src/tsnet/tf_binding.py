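"""Promoter extraction and TF-isoform interaction strengths from PWM scanning.

The promoter region dataset (PRD) holds the 2000 bp upstream of each
isoform's transcription start site. Each transcription-factor PWM is scanned
over both strands of every promoter with log2 odds scoring against a
background base composition; windows scoring at least a fraction of the
PWM's maximum achievable score are binding sites, and the TF-isoform
interaction strength is the sum of its site scores on that promoter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .genomics import IsoformModel, reverse_complement

log = logging.getLogger(__name__)

PROMOTER_LEN = 2000
THRESHOLD_FRACTION = 0.8
PSEUDOCOUNT = 0.01

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


@dataclass
class PWM:
    """Position weight matrix with log2-odds scoring.

    ``matrix`` holds base probabilities (4 x L, rows A/C/G/T). A pseudocount
    is added and columns renormalized before taking log odds, so zero
    probabilities never produce -inf.
    """

    name: str
    matrix: np.ndarray                  # 4 x L probabilities
    background: np.ndarray = None       # 4 frequencies summing to 1
    pseudocount: float = PSEUDOCOUNT

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4 or self.matrix.shape[1] < 1:
            raise ValueError(f"PWM {self.name}: need a 4 x L probability matrix")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError(f"PWM {self.name}: background must sum to 1")
        if self.pseudocount <= 0:
            raise ValueError(f"PWM {self.name}: pseudocount must be > 0")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        """Pseudocount-regularized probabilities; columns sum to 1."""
        p = self.matrix + self.pseudocount
        return p / p.sum(axis=0, keepdims=True)

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probabilities / self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=0))


def read_jaspar_pwms(path) -> list[PWM]:
    """Parse a JASPAR-format text file of count matrices into PWMs."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    pwms = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in _BASES], dtype=float)
        totals = counts.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError(f"PWM {m.name}: empty count column")
        pwms.append(PWM(name=m.name, matrix=counts / totals))
    return pwms


@dataclass(frozen=True)
class BindingSite:
    factor: str
    isoform: str
    start: int          # promoter-local, 0-based half-open
    end: int
    strand: str
    score: float

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError("malformed site interval")


def extract_promoters(
    isoforms: list[IsoformModel],
    genome: dict[str, str],
    promoter_len: int = PROMOTER_LEN,
) -> tuple[dict[str, str], list[str]]:
    """PRD: isoform -> uppercase promoter sequence (2000 bp upstream of TSS).

    Plus strand with 0-based TSS t yields genome[t-2000, t); minus strand
    the reverse complement of genome[t+1, t+2001). Promoters truncated by a
    contig edge are returned as-is and flagged.
    """
    prd: dict[str, str] = {}
    flagged: list[str] = []
    for iso in isoforms:
        chrom_seq = genome[iso.chrom]
        t = iso.tss
        if iso.strand == "+":
            start = t - promoter_len
            seq = chrom_seq[max(0, start):t]
            truncated = start < 0
        else:
            end = t + 1 + promoter_len
            seq = reverse_complement(chrom_seq[t + 1:end])
            truncated = end > len(chrom_seq)
        if truncated:
            flagged.append(iso.isoform_id)
            log.warning(
                "extract_promoters: %s promoter truncated to %d bp at contig edge",
                iso.isoform_id, len(seq),
            )
        prd[iso.isoform_id] = seq.upper()
    return prd, flagged


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX.get(b, -1) for b in seq), dtype=np.int64, count=len(seq))


def _scan_one_strand(codes: np.ndarray, lom: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores for every offset of one strand; offsets with N are masked out."""
    L = lom.shape[1]
    n_off = codes.size - L + 1
    if n_off <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (win >= 0).all(axis=1)
    offs = np.where(valid)[0]
    scores = lom[win[offs], np.arange(L)].sum(axis=1)
    return offs, scores


def scan_pwm(
    sequence: str,
    pwm: PWM,
    threshold_fraction: float = THRESHOLD_FRACTION,
    isoform: str = "",
) -> list[BindingSite]:
    """Log-odds scan of both strands; emit sites scoring at least
    threshold_fraction x the PWM's maximum achievable score.

    Windows containing N are skipped. Coordinates are promoter-local on the
    forward sequence; minus-strand hits are mapped back to forward
    coordinates.
    """
    if not (0 < threshold_fraction < 1):
        raise ValueError("threshold_fraction must be in (0, 1)")
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    L = pwm.length
    if len(seq) < L:
        return []
    lom = pwm.log_odds
    cutoff = threshold_fraction * pwm.max_score
    n = len(seq)
    sites = []
    fwd = _encode(seq)
    for strand, codes in (("+", fwd), ("-", _encode(reverse_complement(seq)))):
        offs, scores = _scan_one_strand(codes, lom)
        for off, sc in zip(offs, scores):
            if sc >= cutoff:
                start = int(off) if strand == "+" else n - int(off) - L
                sites.append(
                    BindingSite(pwm.name, isoform, start, start + L, strand, float(sc))
                )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def scan_promoters(
    prd: dict[str, str],
    pwms: list[PWM],
    threshold_fraction: float = THRESHOLD_FRACTION,
) -> list[BindingSite]:
    sites = []
    for iso in sorted(prd):
        for pwm in pwms:
            sites.extend(scan_pwm(prd[iso], pwm, threshold_fraction, isoform=iso))
    return sites


def tf_strength_matrix(
    sites: list[BindingSite],
    isoforms: list[str],
    factors: list[str],
) -> pd.DataFrame:
    """Isoforms x TFs strength matrix: entry = sum of site scores.

    TFs with no sites on any promoter are dropped (logged), matching the
    rule that factors with no hits carry no information for the regression.
    """
    mat = pd.DataFrame(0.0, index=list(isoforms), columns=list(factors))
    for s in sites:
        if s.isoform not in mat.index:
            raise KeyError(f"site references unknown isoform {s.isoform!r}")
        if s.factor not in mat.columns:
            raise KeyError(f"site references unknown factor {s.factor!r}")
        # strengths are non-negative affinity mass; thresholded scores are
        # positive already, the floor guards pathological PWMs
        mat.loc[s.isoform, s.factor] += max(s.score, 0.0)
    empty = [c for c in mat.columns if (mat[c] == 0).all()]
    if empty:
        log.info("tf_strength_matrix: dropping %d factor(s) with no sites: %s",
                 len(empty), empty)
        mat = mat.drop(columns=empty)
    return mat
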