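"""Tripeptide pause scores from ribosome-footprint occupancy tracks.

A paused ribosome protects the codons sitting in its E, P and A sites.
Footprint 3'-ends are assigned to codons with a fixed 18-nt shift, which
places the assigned codon as the *first* (E-site) codon of the
tripeptide occupying the ribosome; the A-site codon — the one being
decoded — is therefore the motif's third codon.  The pause score of a
motif site is the footprint density (rpm) assigned to that ribosome
position divided by the mean density of the surrounding coding sequence
(±50 nt by default, the motif's own codons excluded).  Per-motif scores
are site means across the translatome, and motifs rarer than 100
genome-wide occurrences are dropped as too noisy.

Flanks are handled at codon resolution: ±``ceil(window_nt / 3)`` codons
on each side.  Sites whose flank would extend beyond the CDS are
excluded, as are sites over a flank with zero mean density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AA_ALPHABET, OccupancyTrack, Transcript, Transcriptome

__all__ = [
    "CodonProfile",
    "assign_codon_occupancy",
    "site_pause_scores",
    "motif_occurrences",
    "motif_pause_table",
    "compare_pause_tables",
]

_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
_N_AA = len(AA_ALPHABET)


@dataclass
class CodonProfile:
    """Per-codon ribosome occupancy (rpm) over one CDS."""

    transcript_id: str
    rpm: np.ndarray
    offset_nt: int
    dropped: int = 0  # 3'-ends whose assigned codon fell outside the CDS

    def __post_init__(self) -> None:
        self.rpm = np.asarray(self.rpm, dtype=float)
        if np.any(self.rpm < 0):
            raise ValueError(f"{self.transcript_id}: negative occupancy")

    @property
    def n_codons(self) -> int:
        return len(self.rpm)


def assign_codon_occupancy(
    track: OccupancyTrack,
    tx: Transcript,
    offset_nt: int = 18,
) -> CodonProfile:
    """Map footprint 3'-ends onto CDS codons with a fixed 3'-shift.

    A 3'-end at transcript position p contributes to the codon
    containing p - offset_nt.  Contributions landing outside the CDS are
    dropped and tallied in ``dropped``.  Values are scaled to reads per
    million of the track's library total.
    """
    if len(track) != tx.length:
        raise ValueError(
            f"{tx.id}: track length {len(track)} != transcript length "
            f"{tx.length}"
        )
    rpm = track.rpm()
    positions = np.arange(tx.length)
    codon = np.floor_divide(positions - offset_nt - tx.cds_start, 3)
    inside = (codon >= 0) & (codon < tx.n_codons)
    profile = np.bincount(
        codon[inside].astype(int), weights=rpm[inside], minlength=tx.n_codons
    )
    dropped = int(np.count_nonzero(track.counts[~inside]))
    return CodonProfile(tx.id, profile, offset_nt, dropped)


def _flank_codons(window_nt: int) -> int:
    return math.ceil(window_nt / 3)


def site_pause_scores(
    profile: CodonProfile,
    window_nt: int = 50,
) -> pd.DataFrame:
    """Per-site pause scores for every eligible motif start in one CDS.

    The site score at motif start codon k is rpm[k] (the density at the
    ribosome position whose E site is codon k) divided by the mean rpm
    over the flanking codons on both sides.  Returns a table with the
    motif start index and score; ineligible sites (flank beyond the CDS,
    or zero flank mean) are absent.
    """
    occ = profile.rpm
    L = len(occ)
    f = _flank_codons(window_nt)
    first = f
    last = L - 3 - f  # motif spans k..k+2; right flank ends at k+2+f
    if last < first:
        return pd.DataFrame({"site": [], "score": []}).astype(
            {"site": int, "score": float}
        )
    k = np.arange(first, last + 1)
    c = np.concatenate([[0.0], np.cumsum(occ)])
    left = c[k] - c[k - f]
    right = c[k + 3 + f] - c[k + 3]
    flank_mean = (left + right) / (2 * f)
    ok = flank_mean > 0
    scores = occ[k[ok]] / flank_mean[ok]
    return pd.DataFrame({"site": k[ok], "score": scores})


def motif_occurrences(tx: Transcriptome) -> pd.Series:
    """Genome-wide occurrence count of every tripeptide motif present
    in the transcriptome's coding sequences."""
    codes = np.zeros(_N_AA**3, dtype=np.int64)
    for t in tx:
        idx = np.array([_AA_INDEX[a] for a in t.codon_seq], dtype=np.int64)
        if len(idx) < 3:
            continue
        m = idx[:-2] * _N_AA**2 + idx[1:-1] * _N_AA + idx[2:]
        codes += np.bincount(m, minlength=_N_AA**3)
    present = np.nonzero(codes)[0]
    names = [
        AA_ALPHABET[c // _N_AA**2]
        + AA_ALPHABET[(c // _N_AA) % _N_AA]
        + AA_ALPHABET[c % _N_AA]
        for c in present
    ]
    return pd.Series(codes[present], index=names, name="occurrences")


def motif_pause_table(
    profiles: Iterable[CodonProfile] | Mapping[str, CodonProfile],
    tx: Transcriptome,
    window_nt: int = 50,
    min_occurrence: int = 100,
) -> pd.DataFrame:
    """Mean pause score per tripeptide motif across the translatome.

    Site scores from every profile are pooled by motif identity (the
    amino acids at codons k, k+1, k+2 = E, P, A); the table reports the
    mean score, the number of scored sites, and the number of genes
    contributing.  Motifs occurring fewer than ``min_occurrence`` times
    in the transcriptome are excluded.
    """
    if isinstance(profiles, Mapping):
        profiles = list(profiles.values())
    score_sum = np.zeros(_N_AA**3)
    n_sites = np.zeros(_N_AA**3, dtype=np.int64)
    gene_seen = np.zeros(_N_AA**3, dtype=np.int64)
    for profile in profiles:
        t = tx[profile.transcript_id]
        if profile.n_codons != t.n_codons:
            raise ValueError(f"{t.id}: profile/CDS codon count mismatch")
        sites = site_pause_scores(profile, window_nt)
        if sites.empty:
            continue
        idx = np.array([_AA_INDEX[a] for a in t.codon_seq], dtype=np.int64)
        k = sites["site"].to_numpy()
        codes = idx[k] * _N_AA**2 + idx[k + 1] * _N_AA + idx[k + 2]
        score_sum += np.bincount(codes, weights=sites["score"].to_numpy(),
                                 minlength=_N_AA**3)
        n_sites += np.bincount(codes, minlength=_N_AA**3)
        gene_seen += np.bincount(np.unique(codes), minlength=_N_AA**3)

    occurrences = motif_occurrences(tx)
    rows = np.nonzero(n_sites)[0]
    names = [
        AA_ALPHABET[c // _N_AA**2]
        + AA_ALPHABET[(c // _N_AA) % _N_AA]
        + AA_ALPHABET[c % _N_AA]
        for c in rows
    ]
    table = pd.DataFrame(
        {
            "mean_score": score_sum[rows] / n_sites[rows],
            "n_sites": n_sites[rows],
            "n_genes": gene_seen[rows],
            "occurrences": occurrences.reindex(names).fillna(0).astype(int).to_numpy(),
        },
        index=pd.Index(names, name="motif"),
    )
    return table[table["occurrences"] >= min_occurrence]


def compare_pause_tables(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    highlight: str = "V",
) -> dict:
    """Pair two pause tables and summarise the highlighted A-site group.

    The group comprises motifs whose third (A-site) residue equals
    ``highlight``.  Reports per-motif (score_a, score_b) pairs with
    ratios b/a, the group's median ratio, and a Mann-Whitney U p-value
    of the group's ratios against all other motifs.
    """
    shared = table_a.index.intersection(table_b.index)
    if len(shared) == 0:
        raise ValueError("pause tables share no motifs")
    pairs = pd.DataFrame(
        {
            "score_a": table_a.loc[shared, "mean_score"],
            "score_b": table_b.loc[shared, "mean_score"],
        }
    )
    pairs["ratio"] = pairs["score_b"] / pairs["score_a"]
    group = pairs.index.str.endswith(highlight)
    out = {
        "pairs": pairs,
        "highlight": highlight,
        "n_group": int(group.sum()),
        "group_median_ratio": float(pairs.loc[group, "ratio"].median())
        if group.any() else float("nan"),
        "other_median_ratio": float(pairs.loc[~group, "ratio"].median())
        if (~group).any() else float("nan"),
    }
    if group.any() and (~group).any():
        _, p = stats.mannwhitneyu(
            pairs.loc[group, "ratio"], pairs.loc[~group, "ratio"],
            alternative="two-sided",
        )
        out["mannwhitney_p"] = float(p)
    else:
        out["mannwhitney_p"] = float("nan")
    return out
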