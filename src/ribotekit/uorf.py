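"""uORF translation: relative ribosome occupancy (RRO), its
differential test, uORF-class TE summaries, and set-overlap enrichment.

RRO for a uORF is the ratio of ribosome-footprint counts within the
uORF to footprint counts over its parent main CDS — a per-mRNA measure
of how much initiation is captured upstream.  uORFs are only analysed
when both signals are quantifiable: mean uORF RPF count >= 2 and mean
parent-CDS RPF count >= 32 over the combined samples of the comparison
(boundaries inclusive — counts *below* the cutoffs are excluded).
Differential RRO reuses the NB interaction Wald test with uORF and CDS
counts playing the roles of the two assays.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import CountMatrix, Transcriptome
from .nbglm import NBTestResult, nb_interaction_test

__all__ = [
    "filter_uorfs",
    "compute_rro",
    "delta_rro_test",
    "summarize_uorf_classes",
    "subset_by_fold",
    "enrichment_test",
    "venn_counts",
]

Condition = tuple[str, str]


def _parent_map(uorf_rpf: CountMatrix, cds_rpf: CountMatrix) -> pd.Series:
    """uORF feature -> parent gene id; uORF ids are '<gene>.uORF<k>'."""
    parents = pd.Series(
        [f.rsplit(".uORF", 1)[0] for f in uorf_rpf.features],
        index=uorf_rpf.counts.index,
    )
    missing = set(parents) - set(cds_rpf.features)
    if missing:
        raise ValueError(
            f"uORF(s) without parent CDS counts: {sorted(missing)[:5]}"
        )
    return parents


def filter_uorfs(
    uorf_rpf: CountMatrix,
    cds_rpf: CountMatrix,
    min_uorf_mean: float = 2.0,
    min_cds_mean: float = 32.0,
) -> pd.DataFrame:
    """Eligibility table: which uORFs carry enough signal to quantify.

    Eligible iff mean uORF RPF >= min_uorf_mean AND mean parent-CDS RPF
    >= min_cds_mean, means taken over all samples of the comparison.
    Returns a table with the means, the eligibility flag, and the reason
    for exclusion ("uORF<2", "CDS<32", or both).
    """
    parents = _parent_map(uorf_rpf, cds_rpf)
    u_mean = uorf_rpf.counts.mean(axis=1)
    c_mean = cds_rpf.counts.loc[parents.to_numpy()].mean(axis=1)
    c_mean.index = u_mean.index
    ok_u = u_mean >= min_uorf_mean
    ok_c = c_mean >= min_cds_mean
    reason = pd.Series("", index=u_mean.index, dtype=object)
    reason[~ok_u] = f"uORF<{min_uorf_mean:g}"
    reason[~ok_c] = f"CDS<{min_cds_mean:g}"
    reason[~ok_u & ~ok_c] = (
        f"uORF<{min_uorf_mean:g};CDS<{min_cds_mean:g}"
    )
    return pd.DataFrame(
        {
            "parent": parents,
            "uorf_mean_rpf": u_mean,
            "cds_mean_rpf": c_mean,
            "eligible": ok_u & ok_c,
            "reason": reason,
        }
    )


def compute_rro(
    uorf_rpf: CountMatrix,
    cds_rpf: CountMatrix,
    eligibility: pd.DataFrame | None = None,
    per_replicate_mean: bool = True,
) -> pd.DataFrame:
    """Per-sample and per-condition RRO for eligible uORFs.

    RRO = uORF RPF / parent CDS RPF per sample; the condition value is
    by default the mean of per-replicate ratios (set
    ``per_replicate_mean=False`` for the ratio of replicate-summed
    counts, a second-order difference).
    """
    if eligibility is None:
        eligibility = filter_uorfs(uorf_rpf, cds_rpf)
    keep = eligibility.index[eligibility["eligible"]]
    parents = eligibility.loc[keep, "parent"]

    u = uorf_rpf.counts.loc[keep]
    c = cds_rpf.counts.loc[parents.to_numpy()].set_axis(keep, axis=0)
    assert not (c.to_numpy() == 0).any(), (
        "zero CDS count for an eligible uORF; filter should preclude this"
    )
    out = {}
    conditions: dict[Condition, list[str]] = {}
    for s in uorf_rpf.samples:
        col = f"RRO:{s.genotype}:{s.treatment}:{s.replicate}"
        out[col] = u[s.name] / c[s.name]
        conditions.setdefault(s.condition, []).append(col)
    table = pd.DataFrame(out, index=keep)
    for cond, cols in conditions.items():
        if per_replicate_mean:
            table[f"RRO:{cond[0]}:{cond[1]}:mean"] = table[cols].mean(axis=1)
        else:
            cols_raw = [cc for ss, cc in zip(uorf_rpf.samples, out)
                        if ss.condition == cond]
            names = [ss.name for ss in uorf_rpf.samples if ss.condition == cond]
            table[f"RRO:{cond[0]}:{cond[1]}:mean"] = (
                u[names].sum(axis=1) / c[names].sum(axis=1)
            )
    table.insert(0, "parent", parents)
    return table


def delta_rro_test(
    uorf_rpf: CountMatrix,
    cds_rpf: CountMatrix,
    contrast: tuple[Condition, Condition],
    min_uorf_mean: float = 2.0,
    min_cds_mean: float = 32.0,
) -> NBTestResult:
    """Differential RRO between two conditions (NB interaction Wald).

    uORF and main-CDS footprint counts are the two "assays"; positive
    ``log2fc`` means the uORF gains occupancy relative to its CDS in the
    test condition.  BH-FDR across eligible uORFs.
    """
    cond_test, cond_ref = contrast
    u_sub = uorf_rpf.subset([cond_test, cond_ref])
    eligibility = filter_uorfs(u_sub, cds_rpf, min_uorf_mean, min_cds_mean)
    keep = eligibility.index[eligibility["eligible"]]
    if len(keep) == 0:
        raise ValueError("no eligible uORFs in this comparison")
    parents = eligibility.loc[keep, "parent"]
    ones = lambda cols: np.ones(len(cols))

    def ucell(cond):
        cols = u_sub.columns_for(cond)
        if len(cols) < 2:
            raise ValueError(f"need >=2 replicates for condition {cond}")
        return u_sub.counts.loc[keep, cols].to_numpy(dtype=float), ones(cols)

    def ccell(cond):
        cols = cds_rpf.columns_for(cond)
        arr = cds_rpf.counts.loc[parents.to_numpy(), cols].to_numpy(dtype=float)
        return arr, ones(cols)

    nt, s_nt = ucell(cond_test)
    nr, s_nr = ucell(cond_ref)
    dt, s_dt = ccell(cond_test)
    dr, s_dr = ccell(cond_ref)
    # library size factors cancel in the uORF/CDS ratio (both assays come
    # from the same footprint library), hence unit offsets
    return nb_interaction_test(
        nt, nr, dt, dr, s_nt, s_nr, s_dt, s_dr, keep, contrast=contrast
    )


def summarize_uorf_classes(
    te_result: NBTestResult,
    tx: Transcriptome,
    min_group: int = 5,
) -> pd.DataFrame:
    """Group median log2 ΔTE by uORF source x start class, with notch
    intervals and a Mann-Whitney U p-value against all tested genes.

    Groups are (source, AUG|NCC) over the genes carrying at least one
    uORF of that kind; the background is every gene in the result.
    Groups smaller than ``min_group`` are skipped.  The notch is the
    usual median +/- 1.57*IQR/sqrt(n) interval.
    """
    lfc = te_result.table["log2fc"].dropna()
    groups: dict[tuple[str, str], set[str]] = {}
    for t in tx:
        for u in t.uorfs:
            cls = "AUG" if u.is_aug else "NCC"
            groups.setdefault((u.source, cls), set()).add(t.id)
    rows = []
    bg = lfc.to_numpy()
    for (source, cls), genes in sorted(groups.items()):
        vals = lfc[lfc.index.isin(genes)].to_numpy()
        if len(vals) < min_group:
            continue
        med = float(np.median(vals))
        iqr = float(np.subtract(*np.percentile(vals, [75, 25])))
        notch = 1.57 * iqr / np.sqrt(len(vals))
        _, p = stats.mannwhitneyu(vals, bg, alternative="two-sided")
        rows.append(
            {
                "source": source,
                "start_class": cls,
                "n": len(vals),
                "median_log2fc": med,
                "notch_lo": med - notch,
                "notch_hi": med + notch,
                "mannwhitney_p": float(p),
            }
        )
    return pd.DataFrame(rows)


def subset_by_fold(
    te_result: NBTestResult | pd.Series,
    fold: float = 1.41,
    direction: str = "up",
) -> set[str]:
    """Genes whose TE changes by strictly more than ``fold`` in the
    stated direction (``up``, ``down``, or ``both`` on |log2fc|)."""
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    lfc = (te_result.table["log2fc"] if isinstance(te_result, NBTestResult)
           else te_result)
    thr = np.log2(fold)
    if direction == "up":
        sel = lfc > thr
    elif direction == "down":
        sel = lfc < -thr
    elif direction == "both":
        sel = lfc.abs() > thr
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return set(lfc.index[sel.fillna(False)])


def enrichment_test(hits, annotated, universe) -> float:
    """Upper-tail hypergeometric p for overlap of two gene sets.

    P(X >= |hits & annotated|) drawing |hits| genes from a universe of
    size N containing |annotated| marked genes (exact summation).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(hits) & universe
    annotated = set(annotated) & universe
    overlap = len(hits & annotated)
    N, K, n = len(universe), len(annotated), len(hits)
    return float(stats.hypergeom.sf(overlap - 1, N, K, n))


def venn_counts(hits, annotated) -> dict[str, int]:
    """Two-set Venn tallies for reporting the overlap diagram."""
    hits, annotated = set(hits), set(annotated)
    both = len(hits & annotated)
    return {
        "hits_only": len(hits) - both,
        "annotated_only": len(annotated) - both,
        "overlap": both,
        "hits": len(hits),
        "annotated": len(annotated),
    }
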