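"""Pause scores: offset arithmetic, flat-profile normalisation, flank
exclusion rules, a pure-Python brute-force oracle, and scale invariance."""

import math

import numpy as np
import pandas as pd
import pytest

from ribotekit.annotation import OccupancyTrack, Transcript
from ribotekit.pause import (
    CodonProfile,
    assign_codon_occupancy,
    compare_pause_tables,
    motif_occurrences,
    motif_pause_table,
    site_pause_scores,
)
from ribotekit.simulate import SimConfig, generate_transcriptome, simulate_tracks

from conftest import WT_U


def _tx(n_codons=60, utr5=30, utr3=30, seq=None):
    seq = seq or ("M" + "ACDEFGHIKLNPQRSTVWY" * 10)[:n_codons]
    return Transcript("t1", utr5 + 3 * n_codons + utr3, utr5,
                      utr5 + 3 * n_codons, seq)


def brute_force_scores(track, tx, offset=18, window=50):
    """Independent per-site recomputation with plain Python loops."""
    rpm = [v * 1e6 / track.library_total for v in track.counts]
    L = tx.n_codons
    occ = [0.0] * L
    for p, v in enumerate(rpm):
        q = p - offset
        if tx.cds_start <= q < tx.cds_end:
            occ[(q - tx.cds_start) // 3] += v
    f = math.ceil(window / 3)
    out = {}
    for k in range(L - 2):
        if k - f < 0 or k + 2 + f > L - 1:
            continue  # flank extends beyond the CDS
        flank = occ[k - f:k] + occ[k + 3:k + 3 + f]
        mean = sum(flank) / len(flank)
        if mean > 0:
            out[k] = occ[k] / mean
    return out


class TestAssignment:
    def test_single_footprint_lands_on_codon_zero(self):
        tx = _tx()
        counts = np.zeros(tx.length)
        counts[tx.cds_start + 18 + 2] = 1  # 3' end 20 nt into the CDS
        prof = assign_codon_occupancy(
            OccupancyTrack("t1", counts, 1_000_000), tx, 18
        )
        assert prof.rpm[0] == pytest.approx(1.0)
        assert prof.rpm[1:].sum() == 0

    def test_zero_offset_is_plain_codon_index(self):
        tx = _tx()
        counts = np.zeros(tx.length)
        p = tx.cds_start + 3 * 7 + 1  # inside codon 7
        counts[p] = 4
        prof = assign_codon_occupancy(
            OccupancyTrack("t1", counts, 1_000_000), tx, 0
        )
        assert prof.rpm[7] == pytest.approx(4.0)

    def test_out_of_cds_assignments_dropped_and_tallied(self):
        tx = _tx()
        counts = np.zeros(tx.length)
        counts[tx.cds_start + 2] = 1  # assigns upstream of the CDS
        prof = assign_codon_occupancy(
            OccupancyTrack("t1", counts, 1_000_000), tx, 18
        )
        assert prof.rpm.sum() == 0
        assert prof.dropped == 1

    def test_generator_round_trip_recovers_per_codon_truth(self):
        cfg = SimConfig(seed=5, n_genes=20)
        tx = generate_transcriptome(cfg)
        tracks, truth = simulate_tracks(
            tx, cfg, WT_U, reads_per_gene=pd.Series(2000.0, index=tx.ids)
        )
        lib = tracks[tx.ids[0]].library_total
        for t in tx:
            prof = assign_codon_occupancy(tracks[t.id], t, 18)
            assert np.array_equal(prof.rpm, truth[t.id] * (1e6 / lib))
            assert prof.dropped == 0


class TestSiteScores:
    def test_uniform_profile_gives_exactly_one(self):
        prof = CodonProfile("t1", np.full(80, 3.7), 18)
        scores = site_pause_scores(prof, 50)
        assert len(scores) > 0
        assert np.allclose(scores["score"], 1.0, atol=1e-9)

    def test_elevated_motif_on_flat_background(self):
        occ = np.full(80, 2.0)
        occ[40:43] = 10.0  # motif codons at 5x background
        scores = site_pause_scores(CodonProfile("t1", occ, 18), 50)
        assert scores.set_index("site").loc[40, "score"] == pytest.approx(5.0)

    def test_sites_too_close_to_cds_edges_excluded(self):
        prof = CodonProfile("t1", np.full(80, 1.0), 18)
        sites = site_pause_scores(prof, 50)["site"]
        f = math.ceil(50 / 3)
        assert sites.min() == f
        assert sites.max() == 80 - 3 - f
        # a motif start closer than the window to the CDS start is absent
        assert (sites < f).sum() == 0

    def test_zero_flank_sites_excluded(self):
        occ = np.zeros(80)
        occ[40] = 5.0
        scores = site_pause_scores(CodonProfile("t1", occ, 18), 50)
        # flank around codon 40 is nonzero only via the spike itself,
        # which is excluded from its own flank -> no score there
        assert 40 not in set(scores["site"])


class TestMotifTable:
    def test_rare_motifs_absent(self):
        cfg = SimConfig(seed=5, n_genes=20)
        tx = generate_transcriptome(cfg)
        occurrences = motif_occurrences(tx)
        profiles = [
            CodonProfile(t.id, np.full(t.n_codons, 1.0), 18) for t in tx
        ]
        table = motif_pause_table(profiles, tx, 50, min_occurrence=100)
        assert (table["occurrences"] >= 100).all()
        rare = occurrences[occurrences < 100].index
        assert not table.index.isin(rare).any()
        table99 = motif_pause_table(profiles, tx, 50, min_occurrence=0)
        assert table99.shape[0] > table.shape[0]

    def test_uniform_profiles_give_unit_scores(self):
        cfg = SimConfig(seed=6, n_genes=15)
        tx = generate_transcriptome(cfg)
        profiles = [
            CodonProfile(t.id, np.full(t.n_codons, 2.5), 18) for t in tx
        ]
        table = motif_pause_table(profiles, tx, 50, min_occurrence=1)
        assert np.allclose(table["mean_score"], 1.0, atol=1e-9)

    def test_brute_force_oracle_matches_bit_for_bit(self):
        # library_total 1e6 makes rpm scaling exactly 1, so both paths
        # do identical integer-exact arithmetic
        cfg = SimConfig(seed=7, n_genes=20)
        tx = generate_transcriptome(cfg)
        tracks, _ = simulate_tracks(
            tx, cfg, WT_U, reads_per_gene=pd.Series(3000.0, index=tx.ids)
        )
        for t in tx:
            tr = tracks[t.id]
            tr = OccupancyTrack(t.id, tr.counts, 1_000_000)
            prof = assign_codon_occupancy(tr, t, 18)
            got = dict(zip(*site_pause_scores(prof, 50).to_numpy().T))
            want = brute_force_scores(tr, t, 18, 50)
            assert got.keys() == want.keys()
            for k in want:
                assert got[k] == want[k]  # exact float equality


class TestCompare:
    def _flat_tables(self, tx):
        profiles = [
            CodonProfile(t.id, np.full(t.n_codons, 1.0), 18) for t in tx
        ]
        return motif_pause_table(profiles, tx, 50, min_occurrence=1)

    def test_identical_tables_give_unit_ratios(self):
        cfg = SimConfig(seed=8, n_genes=15)
        tx = generate_transcriptome(cfg)
        table = self._flat_tables(tx)
        cmp = compare_pause_tables(table, table, "V")
        assert np.allclose(cmp["pairs"]["ratio"], 1.0)
        if cmp["n_group"] and not math.isnan(cmp["mannwhitney_p"]):
            assert cmp["mannwhitney_p"] > 0.5

    def test_a_site_group_size_bounded_by_combinatorics(self):
        cfg = SimConfig(seed=9, n_genes=60)
        tx = generate_transcriptome(cfg)
        table = self._flat_tables(tx)
        cmp = compare_pause_tables(table, table, "V")
        assert cmp["n_group"] <= 20 * 20  # at most 400 motifs end in V

    def test_disjoint_tables_rejected(self):
        a = pd.DataFrame({"mean_score": [1.0]}, index=["AAA"])
        b = pd.DataFrame({"mean_score": [1.0]}, index=["CCC"])
        with pytest.raises(ValueError, match="share no motifs"):
            compare_pause_tables(a, b)


class TestScaleInvariance:
    def test_scores_invariant_to_library_scaling(self):
        cfg = SimConfig(seed=10, n_genes=10)
        tx = generate_transcriptome(cfg)
        tracks, _ = simulate_tracks(
            tx, cfg, WT_U, reads_per_gene=pd.Series(1000.0, index=tx.ids)
        )
        c = 5
        for t in tx:
            tr = tracks[t.id]
            scaled = OccupancyTrack(t.id, tr.counts * c, tr.library_total * c)
            s1 = site_pause_scores(assign_codon_occupancy(tr, t), 50)
            s2 = site_pause_scores(assign_codon_occupancy(scaled, t), 50)
            assert np.allclose(s1["score"], s2["score"])
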