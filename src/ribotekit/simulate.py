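"""Synthetic ribosome-profiling data with known ground truth.

The generator emulates the count-level structure of a two-genotype
(WT / mutant) x two-treatment (untreated / treated) x two-replicate
ribosome-profiling experiment in yeast:

* a toy transcriptome (random amino-acid coding sequences, 5'UTRs, and
  AUG- or near-cognate-initiated uORFs with annotated/conserved/
  functional provenance),
* per-gene RPF and mRNA counts drawn NB(mean, Var = mu + alpha*mu^2)
  around log-normal baseline expression, with per-gene translational-
  efficiency effects injectable per condition (including a GCN4-like
  ~40-fold induction),
* per-uORF footprint counts targeting configured relative ribosome
  occupancies (RRO), and
* per-nucleotide footprint 3'-end tracks with motif-specific A-site
  dwell factors, placed so the analysis offset recovers the per-codon
  truth exactly,
* polysome-gradient qRT-PCR measurements generated by the forward
  model of the gradient TE estimator, so the estimator is its exact
  inverse in the noise-free limit.

All randomness flows from a single integer seed through numpy's PCG64
generator; a fixed seed gives byte-identical outputs.  ``noise=False``
replaces every stochastic draw by its expectation (count matrices then
carry exact, possibly fractional, values).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import (
    AA_ALPHABET,
    NCC_CODONS,
    CountMatrix,
    OccupancyTrack,
    SampleMeta,
    Transcript,
    Transcriptome,
    UORF,
)
from .polysome import GradientFractions

__all__ = [
    "SimConfig",
    "GradientSimConfig",
    "SimTruth",
    "SimOutput",
    "generate_transcriptome",
    "simulate_counts",
    "simulate_tracks",
    "simulate_gradient",
]

Condition = tuple[str, str]
GENOTYPES = ("WT", "mutant")
TREATMENTS = ("untreated", "treated")
CONDITIONS: tuple[Condition, ...] = tuple(
    (g, t) for g in GENOTYPES for t in TREATMENTS
)

#: generator-side inverse of the analysis shift: a ribosome decoding
#: A-site codon a leaves its footprint 3'-end where `codon((p - offset))`
#: is the motif's first (E-site) codon, a - 2
A_SITE_TO_E_CODONS = 2


def _cond_label(cond: Condition) -> str:
    return f"{cond[0]}:{cond[1]}"


@dataclass
class SimConfig:
    """Study-condition parameters for the count-level simulation.

    Defaults are the desk-scale analog of the profiled experiment: 2000
    genes, CDS 100-400 codons, 2x2x2 design, log-normal baseline
    expression, and NB dispersion 0.01 per assay — tight enough that
    replicate log-count correlations sit near the r ~ 0.99 reported for
    the biological replicates being emulated.
    """

    seed: int = 0
    n_genes: int = 2000
    cds_codons: tuple[int, int] = (100, 400)
    utr5_length: tuple[int, int] = (90, 250)
    utr3_length: int = 60
    uorf_fraction: float = 0.25
    uorf_codons: tuple[int, int] = (2, 10)
    p_aug: float = 0.5
    source_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)  # annotated/conserved/functional
    effect_probs: tuple[float, float, float] = (0.8, 0.05, 0.15)  # inhibitory/stimulatory/none
    expression_log_mean: float = math.log(150.0)
    expression_log_sd: float = 1.3
    te_log_sd: float = 0.35
    alpha_rpf: float = 0.01
    alpha_rna: float = 0.01
    depth_rpf: float = 1.0
    depth_rna: float = 1.0
    size_factor_sd: float = 0.1
    n_replicates: int = 2
    #: gene id -> {(genotype, treatment): log2 TE change vs (WT, untreated)}
    te_effects: dict = field(default_factory=dict)
    rro_log_mean: float = math.log(0.08)
    rro_log_sd: float = 0.5
    #: uorf id -> {(genotype, treatment): log2 RRO change vs baseline}
    rro_effects: dict = field(default_factory=dict)
    #: tripeptide motif -> multiplicative A-site dwell factor
    dwell_factors: dict = field(default_factory=dict)
    #: conditions in which the dwell factors act
    dwell_conditions: tuple = (("WT", "treated"),)
    noise: bool = True

    def validate(self) -> None:
        if self.alpha_rpf < 0 or self.alpha_rna < 0:
            raise ValueError("dispersions must be >= 0")
        for m, f in self.dwell_factors.items():
            if f <= 0:
                raise ValueError(f"dwell factor for {m!r} must be > 0")
        if 3 * self.uorf_codons[1] > self.utr5_length[0]:
            raise ValueError(
                "uORF longer than 5'UTR requested: "
                f"{self.uorf_codons[1]} codons cannot fit in a "
                f"{self.utr5_length[0]} nt 5'UTR"
            )
        if not (0 <= self.uorf_fraction <= 1):
            raise ValueError("uorf_fraction must be in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth the estimators are expected to recover."""

    te: pd.DataFrame  # genes x condition labels, true relative TE
    rro: pd.DataFrame  # uORF ids x condition labels, true RRO
    dwell: dict  # motif -> factor
    dwell_conditions: tuple
    expression: pd.Series  # per-gene baseline expression
    size_factors: dict  # assay -> per-sample true depth factor

    def to_json_dict(self) -> dict:
        return {
            "te": self.te.to_dict(),
            "rro": self.rro.to_dict(),
            "dwell": dict(self.dwell),
            "dwell_conditions": [list(c) for c in self.dwell_conditions],
            "expression": self.expression.to_dict(),
            "size_factors": {k: dict(v) for k, v in self.size_factors.items()},
        }


@dataclass
class SimOutput:
    rpf: CountMatrix
    rna: CountMatrix
    uorf_rpf: CountMatrix
    truth: SimTruth


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def generate_transcriptome(config: SimConfig) -> Transcriptome:
    """Draw a toy transcriptome consistent with the configured class mix."""
    config.validate()
    rng = _rng(config.seed, 0)
    width = len(str(max(config.n_genes, 1)))
    transcripts = []
    for i in range(config.n_genes):
        tid = f"g{i:0{width}d}"
        n_codons = int(rng.integers(config.cds_codons[0], config.cds_codons[1] + 1))
        utr5 = int(rng.integers(config.utr5_length[0], config.utr5_length[1] + 1))
        length = utr5 + 3 * n_codons + config.utr3_length
        codon_seq = "".join(
            AA_ALPHABET[j] for j in rng.integers(0, len(AA_ALPHABET), n_codons)
        )
        uorfs = []
        if rng.random() < config.uorf_fraction:
            uc = int(rng.integers(config.uorf_codons[0], config.uorf_codons[1] + 1))
            start = int(rng.integers(0, utr5 - 3 * uc + 1))
            if rng.random() < config.p_aug:
                start_class = "AUG"
            else:
                start_class = sorted(NCC_CODONS)[int(rng.integers(0, len(NCC_CODONS)))]
            source = ("annotated", "conserved", "functional")[
                int(rng.choice(3, p=np.array(config.source_probs)))
            ]
            effect = ("inhibitory", "stimulatory", "none")[
                int(rng.choice(3, p=np.array(config.effect_probs)))
            ]
            uorfs.append(
                UORF(tid, start, start + 3 * uc, start_class, source, effect)
            )
        transcripts.append(
            Transcript(tid, length, utr5, utr5 + 3 * n_codons, codon_seq, uorfs)
        )
    return Transcriptome(transcripts)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float,
             noise: bool) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if not noise:
        return mu
    if alpha <= 0:
        return rng.poisson(mu).astype(np.int64)
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p).astype(np.int64)


def _sample_grid(config: SimConfig, assay: str) -> list[SampleMeta]:
    return [
        SampleMeta(
            name=f"{assay}_{g}_{'SM' if t == 'treated' else 'untr'}_{r + 1}",
            genotype=g, treatment=t, replicate=r + 1, assay=assay,
        )
        for (g, t) in CONDITIONS
        for r in range(config.n_replicates)
    ]


def simulate_counts(tx: Transcriptome, config: SimConfig) -> SimOutput:
    """Draw RPF, RNA, and uORF-footprint count matrices plus the truth.

    RNA counts ~ NB(depth * expression, alpha_RNA); CDS RPF counts
    ~ NB(depth * expression * TE, alpha_RPF) with the per-condition TE
    from the configured effect map; uORF RPF means are RRO times the
    parent's RPF mean, so the expected uORF/CDS ratio equals the
    configured RRO.
    """
    config.validate()
    rng = _rng(config.seed, 1)
    ids = tx.ids
    G = len(ids)
    expr = np.exp(rng.normal(config.expression_log_mean,
                             config.expression_log_sd, G))
    base_te = np.exp(rng.normal(0.0, config.te_log_sd, G))

    te_by_cond = {}
    for cond in CONDITIONS:
        fc = np.array([
            2.0 ** config.te_effects.get(gid, {}).get(cond, 0.0) for gid in ids
        ])
        te_by_cond[cond] = base_te * fc
    te_frame = pd.DataFrame(
        {_cond_label(c): te_by_cond[c] for c in CONDITIONS}, index=ids
    )

    uorf_ids = [uid for uid, _, _ in tx.uorfs()]
    uorf_parent = {uid: u.parent_id for uid, _, u in tx.uorfs()}
    base_rro = np.exp(rng.normal(config.rro_log_mean, config.rro_log_sd,
                                 len(uorf_ids)))
    rro_by_cond = {}
    for cond in CONDITIONS:
        fc = np.array([
            2.0 ** config.rro_effects.get(uid, {}).get(cond, 0.0)
            for uid in uorf_ids
        ]) if uorf_ids else np.array([])
        rro_by_cond[cond] = base_rro * fc
    rro_frame = pd.DataFrame(
        {_cond_label(c): rro_by_cond[c] for c in CONDITIONS}, index=uorf_ids
    )

    samples_rpf = _sample_grid(config, "RPF")
    samples_rna = _sample_grid(config, "RNA")
    sf = {"RPF": {}, "RNA": {}}
    for s in samples_rpf + samples_rna:
        depth = config.depth_rpf if s.assay == "RPF" else config.depth_rna
        jitter = (
            np.exp(rng.normal(0.0, config.size_factor_sd))
            if config.noise and config.size_factor_sd > 0 else 1.0
        )
        sf[s.assay][s.name] = depth * jitter

    parent_index = (
        pd.Index(ids).get_indexer([uorf_parent[u] for u in uorf_ids])
        if uorf_ids else np.array([], dtype=int)
    )
    rpf_cols, rna_cols, uorf_cols = {}, {}, {}
    for s in samples_rna:
        mu = sf["RNA"][s.name] * expr
        rna_cols[s.name] = _nb_draw(rng, mu, config.alpha_rna, config.noise)
    for s in samples_rpf:
        mu = sf["RPF"][s.name] * expr * te_by_cond[s.condition]
        rpf_cols[s.name] = _nb_draw(rng, mu, config.alpha_rpf, config.noise)
        if uorf_ids:
            mu_u = mu[parent_index] * rro_by_cond[s.condition]
            uorf_cols[s.name] = _nb_draw(rng, mu_u, config.alpha_rpf,
                                         config.noise)

    exact = not config.noise
    rpf = CountMatrix(pd.DataFrame(rpf_cols, index=ids), samples_rpf, "RPF",
                      exact=exact)
    rna = CountMatrix(pd.DataFrame(rna_cols, index=ids), samples_rna, "RNA",
                      exact=exact)
    if uorf_ids:
        uorf_frame = pd.DataFrame(uorf_cols, index=uorf_ids)
    else:
        uorf_frame = pd.DataFrame(
            {s.name: pd.Series(dtype=np.int64) for s in samples_rpf}
        )
    uorf_rpf = CountMatrix(uorf_frame, samples_rpf, "RPF", exact=exact)
    truth = SimTruth(
        te=te_frame, rro=rro_frame, dwell=dict(config.dwell_factors),
        dwell_conditions=tuple(config.dwell_conditions),
        expression=pd.Series(expr, index=ids, name="expression"),
        size_factors=sf,
    )
    return SimOutput(rpf=rpf, rna=rna, uorf_rpf=uorf_rpf, truth=truth)


def simulate_tracks(
    tx: Transcriptome,
    config: SimConfig,
    condition: Condition,
    reads_per_gene: pd.Series | None = None,
    offset_nt: int = 18,
) -> tuple[dict[str, OccupancyTrack], dict[str, np.ndarray]]:
    """Footprint 3'-end tracks for one condition, with per-codon truth.

    Each gene's footprints are distributed multinomially over A-site
    codons with probabilities proportional to the dwell factor of the
    tripeptide whose A site is that codon (active only in the
    configured dwell conditions).  The 3'-end is placed so that the
    analysis shift assigns the read to the motif's first (E-site)
    codon; returned truth arrays are indexed by that assigned codon.

    ``reads_per_gene`` defaults to a draw around the configured
    expression (times TE); pass the observed condition-summed RPF
    counts to couple tracks to a count simulation.
    """
    config.validate()
    rng = _rng(config.seed, 2 + CONDITIONS.index(tuple(condition)))
    active = tuple(condition) in {tuple(c) for c in config.dwell_conditions}

    tracks: dict[str, OccupancyTrack] = {}
    truth: dict[str, np.ndarray] = {}
    raw = {}
    total = 0
    for t in tx:
        L = t.n_codons
        if reads_per_gene is not None:
            n_reads = int(round(float(reads_per_gene.get(t.id, 0))))
        else:
            expr = math.exp(rng.normal(config.expression_log_mean,
                                       config.expression_log_sd))
            n_reads = int(rng.poisson(
                config.n_replicates * config.depth_rpf * expr
            ))
        # A-site positions 2..L-1 so the full E/P/A motif lies in the CDS
        w = np.ones(L - 2, dtype=float)
        if active and config.dwell_factors:
            seq = t.codon_seq
            for j, a in enumerate(range(2, L)):
                f = config.dwell_factors.get(seq[a - 2:a + 1])
                if f is not None:
                    w[j] = f
        if n_reads > 0:
            counts = rng.multinomial(n_reads, w / w.sum())
        else:
            counts = np.zeros(L - 2, dtype=np.int64)
        # assigned (E-site) codon for A-site codon a is a - 2
        per_codon = np.zeros(L, dtype=np.int64)
        per_codon[: L - 2] = counts
        track = np.zeros(t.length, dtype=np.int64)
        e_codon_nt = t.cds_start + 3 * np.arange(L - 2)
        np.add.at(track, e_codon_nt + offset_nt, counts)
        raw[t.id] = track
        truth[t.id] = per_codon
        total += int(counts.sum())
    for tid, track in raw.items():
        tracks[tid] = OccupancyTrack(tid, track, total)
    return tracks, truth


# ---------------------------------------------------------------------------
# Polysome gradients
# ---------------------------------------------------------------------------

@dataclass
class GradientSimConfig:
    """Forward model for the gradient qRT-PCR measurements.

    mRNAs are spread over 80S/2-mer/.../n-mer pools with ribosome loads
    proportional to their TE (a truncated-Poisson occupancy profile
    rescaled so the expected ribosomes per mRNA equal the TE exactly);
    fraction volumes, extraction losses and gradient loading losses are
    drawn per gradient and encoded into A260 areas, 18S levels and Ct
    values by the exact inverse of the estimator's correction chain.
    """

    seed: int = 0
    n_replicates: int = 3
    max_ribosomes: int = 10
    volume_range: tuple[float, float] = (350.0, 700.0)
    bulk_scale: float = 100.0  # total bulk ribosome signal per gradient
    level_noise: float = 0.0  # relative sd of Ct-derived levels
    extraction_loss_sd: float = 0.0  # lognormal sd of per-fraction recovery
    loading_loss_sd: float = 0.0  # lognormal sd of per-gradient recovery
    #: target -> input mRNA level in the whole-cell extract
    input_levels: dict = field(default_factory=dict)

    def occupancy_profile(self, te: float) -> np.ndarray:
        """Fraction of an mRNA's molecules in each k-mer pool (k=1..K),
        scaled so sum_k p_k * k == te; the remainder is unbound."""
        if te < 0:
            raise ValueError("TE must be >= 0")
        k = np.arange(1, self.max_ribosomes + 1)
        if te == 0:
            return np.zeros(self.max_ribosomes)
        q = stats.poisson.pmf(k, mu=te)
        mean_tr = float((q * k).sum())
        if mean_tr <= 0:
            q = np.zeros(self.max_ribosomes)
            q[0] = 1.0
            mean_tr = 1.0
        p = q * (te / mean_tr)
        if p.sum() > 1.0 + 1e-9:
            raise ValueError(
                f"TE {te} too large for {self.max_ribosomes} ribosome pools"
            )
        return p


def simulate_gradient(
    te_truth: dict[str, dict[Condition, float]],
    config: GradientSimConfig,
) -> list[GradientFractions]:
    """Generate gradient replicate sets for every genotype x treatment.

    ``te_truth`` maps each target mRNA to its true TE per condition.
    Noise-free (all noise parameters zero) output satisfies
    estimate_te(simulate_gradient(te)) == te exactly.
    """
    rng = _rng(config.seed, 10)
    targets = sorted(te_truth)
    K = config.max_ribosomes
    mult = np.arange(0, K + 1)  # 0 = unbound pool, then 1..K
    labels = ["unbound", "80S"] + [f"{k}-mer" for k in range(2, K + 1)]
    # bulk ribosome profile: fixed across gradients, peaked at trimers
    bulk_w = stats.poisson.pmf(np.arange(1, K + 1), mu=3.0)
    bulk = np.concatenate([[0.0], bulk_w / bulk_w.sum() * config.bulk_scale])

    gradients = []
    for genotype in GENOTYPES:
        for treatment in TREATMENTS:
            cond = (genotype, treatment)
            for rep in range(1, config.n_replicates + 1):
                gid = f"{genotype}_{'SM' if treatment == 'treated' else 'untr'}_{rep}"
                lam = (np.exp(rng.normal(0.0, config.loading_loss_sd))
                       if config.loading_loss_sd > 0 else 1.0)
                e_f = (np.exp(rng.normal(0.0, config.extraction_loss_sd, K + 1))
                       if config.extraction_loss_sd > 0 else np.ones(K + 1))
                vols = rng.uniform(*config.volume_range, K + 1)
                # per-fraction target mRNA amounts and ribosome content
                amounts = {}
                target_ribo = np.zeros(K + 1)
                for tgt in targets:
                    te = float(te_truth[tgt][cond])
                    input_level = float(config.input_levels.get(tgt, 1.0))
                    p = config.occupancy_profile(te)
                    a = np.concatenate([[input_level * (1.0 - p.sum())],
                                        input_level * p])
                    amounts[tgt] = a
                    target_ribo += a * mult
                # equal A260 of extract is loaded on every gradient, so the
                # total monosome+polysome signal is fixed: the (untracked)
                # bulk transcriptome makes up the difference
                if target_ribo.sum() >= config.bulk_scale:
                    raise ValueError(
                        "target ribosome load exceeds bulk_scale; raise "
                        "bulk_scale or lower input levels"
                    )
                ribo = target_ribo + bulk / config.bulk_scale * (
                    config.bulk_scale - target_ribo.sum()
                )
                # observables, by the inverse of the estimator chain
                a260 = lam * ribo
                ug_total = ribo * (EXTR := 300.0) / vols * e_f * lam
                ug_total = np.maximum(ug_total, 1e-12)
                evol = 25.0 * 5.0 / ug_total
                s_rt = 1.0  # 18S per RT is fixed by the 5 ug RNA input
                noise = lambda n: (
                    rng.normal(0.0, config.level_noise / math.log(2), n)
                    if config.level_noise > 0 else np.zeros(n)
                )
                frame = pd.DataFrame(
                    {
                        "label": labels,
                        "multiplier": mult,
                        "a260_area": a260,
                        "volume_ul": vols,
                        "extraction_volume_ul": evol,
                        "ct_18s": -np.log2(s_rt) + noise(K + 1),
                    }
                )
                for tgt in targets:
                    m_rt = (lam * amounts[tgt] * (EXTR / vols) * e_f
                            * (evol / 25.0))
                    with np.errstate(divide="ignore"):
                        frame[f"ct:{tgt}"] = -np.log2(np.maximum(m_rt, 1e-300)) \
                            + noise(K + 1)
                input_ct = {
                    tgt: float(-math.log2(max(config.input_levels.get(tgt, 1.0),
                                              1e-300)) + noise(1)[0])
                    for tgt in targets
                }
                gradients.append(
                    GradientFractions(
                        gradient_id=gid,
                        genotype=genotype,
                        treatment=treatment,
                        replicate=rep,
                        fractions=frame,
                        input_ct=input_ct,
                        input_ref_ct=float(noise(1)[0]),
                    )
                )
    return gradients
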