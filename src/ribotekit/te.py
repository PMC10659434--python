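"""Translational efficiency: per-gene TE, differential TE, and the
conditional-dependence classifier.

TE for a gene is the ratio of its CDS ribosome-footprint (RPF) reads to
its total-mRNA reads, each normalised by per-library size factors, so
TEs are relative to the library average.  Differential TE between two
strain/condition combinations is tested with the NB assay x condition
interaction Wald test in :mod:`ribotekit.nbglm`, with BH-FDR control
across the tested genes.  The classifier labels genes whose TE drops
only when two perturbations are combined (reduced in the double
perturbation and in treatment-of-mutant, but not in either single
perturbation) — the diagnostic pattern of a factor acting as a
conditional back-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .annotation import CountMatrix
from .nbglm import NBTestResult, nb_interaction_test

__all__ = [
    "size_factors",
    "compute_te",
    "delta_te_test",
    "correlate_delta_te",
    "classify_conditional_dependence",
    "ConditionalLabels",
]

Condition = tuple[str, str]


def size_factors(counts: CountMatrix, method: str = "total-count") -> pd.Series:
    """Per-library normalisation factors.

    ``total-count``: library total over the geometric mean of totals
    (the paper-style normalisation for total read number).
    ``median-of-ratios``: median over features of the count divided by
    the feature's geometric mean across libraries (DESeq-style; requires
    every feature used to be nonzero in all libraries).
    """
    x = counts.values()
    names = counts.sample_names
    totals = x.sum(axis=0)
    if np.any(totals == 0):
        bad = [n for n, t in zip(names, totals) if t == 0]
        raise ValueError(f"all-zero sample(s): {bad}")
    if method == "total-count":
        f = totals / stats.gmean(totals)
    elif method == "median-of-ratios":
        pos = np.all(x > 0, axis=1)
        if not pos.any():
            raise ValueError(
                "median-of-ratios needs at least one feature nonzero in "
                "all samples"
            )
        ref = stats.gmean(x[pos], axis=1)
        f = np.median(x[pos] / ref[:, None], axis=0)
    else:
        raise ValueError(f"unknown size-factor method {method!r}")
    return pd.Series(f, index=names, name="size_factor")


def _detection_mask(rpf: CountMatrix, rna: CountMatrix,
                    min_mean_rpf: float, min_mean_rna: float) -> pd.Series:
    """Gene tested only with mean raw RPF and RNA counts above cutoffs,
    means over all samples of the comparison."""
    mr = rpf.counts.mean(axis=1) >= min_mean_rpf
    mn = rna.counts.mean(axis=1) >= min_mean_rna
    return mr & mn


def compute_te(
    rpf: CountMatrix,
    rna: CountMatrix,
    sf_rpf: pd.Series | None = None,
    sf_rna: pd.Series | None = None,
    min_mean_rpf: float = 1.0,
    min_mean_rna: float = 1.0,
) -> pd.DataFrame:
    """Per-sample and per-condition TE table.

    TE_ij = (rpf_ij / sf_j) / (rna_ij / sf'_j); the condition TE is the
    mean over that condition's replicates.  RPF and RNA samples are
    paired by (genotype, treatment, replicate).  Genes failing the
    detection filter, or with zero normalised RNA in some sample, are
    flagged undetected and carry NaN TEs.
    """
    if list(rpf.features) != list(rna.features):
        raise ValueError("RPF and RNA matrices must share the feature set")
    if sf_rpf is None:
        sf_rpf = size_factors(rpf)
    if sf_rna is None:
        sf_rna = size_factors(rna)

    key = lambda s: (s.genotype, s.treatment, s.replicate)
    rna_by_key = {key(s): s.name for s in rna.samples}
    pairs = []
    for s in rpf.samples:
        if key(s) not in rna_by_key:
            raise ValueError(f"no RNA sample matching RPF sample {s.name}")
        pairs.append((s, rna_by_key[key(s)]))

    detected = _detection_mask(rpf, rna, min_mean_rpf, min_mean_rna)
    out = {}
    conditions: dict[Condition, list[str]] = {}
    for s, rna_name in pairs:
        num = rpf.counts[s.name] / sf_rpf[s.name]
        den = rna.counts[rna_name] / sf_rna[rna_name]
        te = num / den.replace(0, np.nan)
        te[~detected] = np.nan
        col = f"TE:{s.genotype}:{s.treatment}:{s.replicate}"
        out[col] = te
        conditions.setdefault((s.genotype, s.treatment), []).append(col)
    table = pd.DataFrame(out, index=rpf.counts.index)
    for cond, cols in conditions.items():
        table[f"TE:{cond[0]}:{cond[1]}:mean"] = table[cols].mean(axis=1)
    table["detected"] = detected
    return table


def delta_te_test(
    rpf: CountMatrix,
    rna: CountMatrix,
    contrast: tuple[Condition, Condition],
    sf_method: str = "median-of-ratios",
    min_mean_rpf: float = 1.0,
    min_mean_rna: float = 1.0,
) -> NBTestResult:
    """Differential TE between two conditions.

    ``contrast = (cond_test, cond_ref)``; positive ``log2fc`` means TE
    is higher in ``cond_test``.  Size factors are computed per assay on
    the samples of the comparison; the default median-of-ratios
    normalisation is robust to a handful of strongly responding genes
    distorting library totals.  Only genes passing the detection
    filter are tested; BH-FDR is computed across tested genes.
    """
    cond_test, cond_ref = contrast
    rpf_sub = rpf.subset([cond_test, cond_ref])
    rna_sub = rna.subset([cond_test, cond_ref])
    for sub, label in ((rpf_sub, "RPF"), (rna_sub, "RNA")):
        for cond in contrast:
            if len(sub.columns_for(cond)) < 2:
                raise ValueError(
                    f"need >=2 {label} replicates for condition {cond}"
                )
    keep = _detection_mask(rpf_sub, rna_sub, min_mean_rpf, min_mean_rna)
    genes = rpf_sub.counts.index[keep]

    sf_rpf = size_factors(rpf_sub, sf_method)
    sf_rna = size_factors(rna_sub, sf_method)

    def cell(matrix: CountMatrix, sf: pd.Series, cond: Condition):
        cols = matrix.columns_for(cond)
        return (
            matrix.counts.loc[genes, cols].to_numpy(dtype=float),
            sf[cols].to_numpy(),
        )

    nt, s_nt = cell(rpf_sub, sf_rpf, cond_test)
    nr, s_nr = cell(rpf_sub, sf_rpf, cond_ref)
    dt, s_dt = cell(rna_sub, sf_rna, cond_test)
    dr, s_dr = cell(rna_sub, sf_rna, cond_ref)
    return nb_interaction_test(
        nt, nr, dt, dr, s_nt, s_nr, s_dt, s_dr, genes, contrast=contrast
    )


def correlate_delta_te(
    result_a: NBTestResult | pd.Series,
    result_b: NBTestResult | pd.Series,
    gene_set=None,
) -> tuple[float, float]:
    """Pearson correlation of two sets of log2 ΔTE values over shared
    genes, with its t-distribution p-value."""
    a = result_a.table["log2fc"] if isinstance(result_a, NBTestResult) else result_a
    b = result_b.table["log2fc"] if isinstance(result_b, NBTestResult) else result_b
    shared = a.index.intersection(b.index)
    if gene_set is not None:
        shared = shared.intersection(pd.Index(gene_set))
    x = a[shared]
    y = b[shared]
    ok = x.notna() & y.notna()
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need >=3 shared genes with finite log2 ΔTE")
    if float(x.std()) == 0.0 or float(y.std()) == 0.0:
        raise ValueError("zero variance in a ΔTE vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class ConditionalLabels:
    """Per-gene conditional-dependence labels plus a deterministic
    hierarchical-clustering display order of the ΔTE matrix."""

    labels: pd.Series  # "conditional" | "other" | "unclassifiable"
    cluster_order: list[str]

    @property
    def conditional_genes(self) -> list[str]:
        return list(self.labels.index[self.labels == "conditional"])


def classify_conditional_dependence(
    delta: pd.DataFrame,
    t_down: float = 0.5,
    t_tol: float = 0.25,
) -> ConditionalLabels:
    """Label genes whose TE falls only under the double perturbation.

    ``delta`` has one row per gene and four log2 ΔTE columns, in order:

    1. double perturbation vs single (mutant+treated / WT+treated)
    2. treatment within the mutant (mutant+treated / mutant)
    3. treatment within WT (WT+treated / WT)
    4. mutation alone (mutant / WT)

    A gene is "conditional" iff columns 1 and 2 are <= -t_down (clear
    reduction when both perturbations combine) AND columns 3 and 4 are
    >= -t_tol (no appreciable reduction from either alone).  Genes with
    any missing value are "unclassifiable".  The defaults echo the
    1.41-fold (2^0.5) convention for "appreciable".
    """
    if delta.shape[1] != 4:
        raise ValueError("expected exactly four contrast columns")
    delta = delta.sort_index()  # lexicographic tie-break for clustering
    vals = delta.to_numpy(dtype=float)
    complete = np.isfinite(vals).all(axis=1)
    down = (vals[:, 0] <= -t_down) & (vals[:, 1] <= -t_down)
    tol = (vals[:, 2] >= -t_tol) & (vals[:, 3] >= -t_tol)
    labels = np.where(complete & down & tol, "conditional",
                      np.where(complete, "other", "unclassifiable"))
    series = pd.Series(labels, index=delta.index, name="label")

    order_ids = list(delta.index[complete])
    if len(order_ids) > 2:
        link = hierarchy.linkage(vals[complete], method="average",
                                 metric="euclidean")
        leaves = hierarchy.leaves_list(link)
        order_ids = [order_ids[i] for i in leaves]
    order_ids += list(delta.index[~complete])
    return ConditionalLabels(labels=series, cluster_order=order_ids)
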