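"""SF motif filtering, splice-window extraction and conservation scoring."""

import numpy as np
import pytest

from tsnet.genomics import ConservationTrack, IsoformModel
from tsnet import sf_binding as sfb


def _motif(factor="SFx", motif="ACGTACG", score=6.0):
    return sfb.SFMotif(factor, motif, score)


# ------------------------------------------------------------ motif filter

@pytest.mark.parametrize(
    "score,length,kept",
    [
        (-6.0, 8, True),        # absolute-value rule keeps silencers
        (4.9, 8, False),        # |score| < 5
        (5.0, 8, True),         # boundary: exactly 5 kept
        (7.0, 16, False),       # longer than 15
        (5.0, 15, True),        # boundary: exactly 15 kept
    ],
)
def test_filter_sf_motifs_boundaries(score, length, kept):
    m = _motif(motif="A" * length, score=score)
    assert (sfb.filter_sf_motifs([m]) == [m]) is kept


def test_filter_sf_motifs_idempotent():
    motifs = [_motif(score=s, motif="ACGU"[0] * 6) for s in (-6, 4, 8)]
    once = sfb.filter_sf_motifs(motifs)
    assert sfb.filter_sf_motifs(once) == once


def test_u_mapped_to_t_and_bad_characters_rejected():
    assert _motif(motif="ACGU").motif == "ACGT"
    with pytest.raises(ValueError, match="ACXGT"):
        sfb.SFMotif("SFx", "ACXGT", 6.0)


# ------------------------------------------------------------ windows

def _two_exon(iso="isoA", exons=((0, 1000), (2000, 3000))):
    return IsoformModel(iso, "gA", "chr1", "+", exons)


def test_windows_flank_each_splice_site():
    ws = sfb.extract_splice_windows([_two_exon()])
    assert [(w.start, w.end) for w in ws] == [(800, 1200), (1800, 2200)]
    assert ws[0].splice_sites == (1000,) and ws[1].splice_sites == (2000,)


def test_single_exon_isoform_yields_no_windows():
    iso = IsoformModel("isoA", "gA", "chr1", "+", ((100, 900),))
    assert sfb.extract_splice_windows([iso]) == []


def test_close_splice_sites_merge_into_one_window():
    iso = _two_exon(exons=((0, 1000), (1150, 2000)))   # sites 150 bp apart
    ws = sfb.extract_splice_windows([iso])
    assert [(w.start, w.end) for w in ws] == [(800, 1350)]
    assert ws[0].splice_sites == (1000, 1150)


def test_windows_clip_to_contig_bounds():
    iso = _two_exon(exons=((0, 100), (300, 500)))
    ws = sfb.extract_splice_windows([iso], contig_lengths={"chr1": 450})
    assert [(w.start, w.end) for w in ws] == [(0, 450)]


# ------------------------------------------------------------ hit scoring

def _setup_genome(seq):
    genome = {"chr1": seq}
    track = ConservationTrack({"chr1": np.zeros(len(seq))})
    return genome, track


def test_hit_conservation_is_mean_and_boundary_two_kept():
    genome, track = _setup_genome("T" * 20 + "ACG" + "T" * 20)
    track.arrays["chr1"][20:23] = [1.0, 2.0, 3.0]
    w = sfb.SpliceWindow("isoA", "chr1", 10, 33, (21,))
    hits = sfb.score_sf_hits([w], [_motif(motif="ACG")], genome, track)
    assert len(hits) == 1 and hits[0].conservation == pytest.approx(2.0)

    track.arrays["chr1"][20:23] = [0.0, 1.0, 2.0]
    assert sfb.score_sf_hits([w], [_motif(motif="ACG")], genome, track) == []


def test_hits_equal_brute_force_window_search(bundle, truth):
    """Planted occurrences are found exactly where they were planted."""
    import json
    from tsnet.genomics import read_genome
    genome = read_genome(bundle.paths["genome"])
    track = ConservationTrack.from_bedgraph(
        bundle.paths["conservation"], {c: len(s) for c, s in genome.items()}
    )
    motifs = {m.factor: m for m in sfb.filter_sf_motifs(
        sfb.load_sf_motifs(bundle.paths["sf_motifs"])
    )}
    windows = sfb.extract_splice_windows(bundle.models)
    hits = sfb.score_sf_hits(windows, list(motifs.values()), genome, track)
    found = {(h.factor, h.isoform, h.start, h.end) for h in hits}
    for iso_id, by_factor in truth["planted_sites"].items():
        for fac, spans in by_factor.items():
            if fac not in motifs:        # planted TF sites
                continue
            for s, e in spans:
                assert (fac, iso_id, s, e) in found


def test_duplicate_hits_from_split_windows_emitted_once():
    genome, track = _setup_genome("T" * 10 + "ACGTT" + "T" * 10)
    track.arrays["chr1"][:] = 3.0
    whole = [sfb.SpliceWindow("isoA", "chr1", 5, 20, (10,))]
    split = [
        sfb.SpliceWindow("isoA", "chr1", 5, 16, (10,)),
        sfb.SpliceWindow("isoA", "chr1", 8, 20, (12,)),
    ]
    m = [_motif(motif="ACGTT")]
    h_whole = sfb.score_sf_hits(whole, m, genome, track)
    h_split = sfb.score_sf_hits(split, m, genome, track)
    key = lambda hs: {(h.factor, h.isoform, h.start, h.end) for h in hs}
    assert key(h_whole) == key(h_split) and len(h_split) == 1


def test_window_outside_track_coverage_is_error():
    genome, track = _setup_genome("ACGT" * 10)
    w = sfb.SpliceWindow("isoA", "chr1", 30, 60, (45,))
    with pytest.raises(ValueError, match="outside track coverage"):
        sfb.score_sf_hits([w], [_motif(motif="ACGT")], genome, track)


# ------------------------------------------------------------ strengths

def test_sf_strength_is_mean_of_hit_conservations():
    hits = [
        sfb.SFHit("SF1", "isoA", "chr1", 0, 7, 2.5),
        sfb.SFHit("SF1", "isoA", "chr1", 20, 27, 3.5),
    ]
    mat = sfb.sf_strength_matrix(hits, ["isoA", "isoB"], ["SF1"])
    assert mat.loc["isoA", "SF1"] == pytest.approx(3.0)
    assert mat.loc["isoB", "SF1"] == 0.0


def test_sf_strength_independent_of_exon_number():
    many = [sfb.SFHit("SF1", "isoA", "chr1", 30 * i, 30 * i + 7, 2.7)
            for i in range(10)]
    one = [sfb.SFHit("SF1", "isoB", "chr1", 0, 7, 2.7)]
    mat = sfb.sf_strength_matrix(many + one, ["isoA", "isoB"], ["SF1"])
    assert mat.loc["isoA", "SF1"] == pytest.approx(2.7)
    assert mat.loc["isoB", "SF1"] == pytest.approx(2.7)


def test_nonzero_sf_strengths_at_least_two(bundle):
    vals = bundle.sf_strengths.to_numpy()
    assert (vals[vals > 0] >= 2.0).all()


# ------------------------------------------------------------ paralog merge

def test_merge_averages_columns():
    import pandas as pd
    mat = pd.DataFrame({"hnRNP A1": [1.0, 2.0], "hnRNP A2": [3.0, 6.0],
                        "other": [5.0, 5.0]})
    out = sfb.merge_paralog_factors(mat, [("hnRNP A1/A2", ["hnRNP A1", "hnRNP A2"])])
    assert list(out["hnRNP A1/A2"]) == [2.0, 4.0]
    assert list(out["other"]) == [5.0, 5.0]
    assert "hnRNP A1" not in out.columns


def test_merge_identical_columns_is_identity_in_values():
    import pandas as pd
    mat = pd.DataFrame({"a": [2.0, 4.0], "b": [2.0, 4.0]})
    out = sfb.merge_paralog_factors(mat, [("ab", ["a", "b"])])
    assert list(out["ab"]) == [2.0, 4.0]


def test_merge_three_members():
    import pandas as pd
    mat = pd.DataFrame({"a": [2.0], "b": [4.0], "c": [6.0]})
    out = sfb.merge_paralog_factors(mat, [("abc", ["a", "b", "c"])])
    assert out.loc[0, "abc"] == pytest.approx(4.0)


def test_merge_missing_member_is_error():
    import pandas as pd
    mat = pd.DataFrame({"a": [1.0]})
    with pytest.raises(KeyError, match="missing"):
        sfb.merge_paralog_factors(mat, [("ab", ["a", "b"])])


# ------------------------------------------------------------ genome scan

def _scan_setup(n_sites=9):
    seq = list("T" * (n_sites * 20 + 40))
    cons = np.full(len(seq), 0.0)
    positions = []
    for i in range(n_sites):
        p = 20 * i + 10
        seq[p:p + 4] = "ACGG"
        cons[p:p + 4] = float(i + 1)     # distinct mean conservations 1..9
        positions.append(p)
    genome = {"chr1": "".join(seq)}
    track = ConservationTrack({"chr1": cons})
    return genome, track, positions


def test_top_third_of_hits_kept():
    genome, track, positions = _scan_setup()
    genes = [("gA", "chr1", 0, len(genome["chr1"]))]
    kept, gene_list = sfb.genome_scan_targets(
        _motif(motif="ACGG"), genes, genome, track, keep_fraction=1 / 3
    )
    assert len(kept) == 3
    assert {k[2] for k in kept} == set(positions[-3:])
    assert gene_list == ["gA"]


def test_keep_fraction_one_keeps_all_hits():
    genome, track, positions = _scan_setup()
    kept, _ = sfb.genome_scan_targets(
        _motif(motif="ACGG"), [], genome, track, keep_fraction=1.0
    )
    assert len(kept) == 9


def test_genes_deduplicated_in_scan():
    genome, track, _ = _scan_setup()
    genes = [("gA", "chr1", 0, len(genome["chr1"]))]
    _, gene_list = sfb.genome_scan_targets(
        _motif(motif="ACGG"), genes, genome, track, keep_fraction=1.0
    )
    assert gene_list == ["gA"]
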