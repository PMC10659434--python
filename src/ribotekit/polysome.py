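"""Polysome-gradient qRT-PCR estimator of per-mRNA translational
efficiency, with the full normalisation chain, plus bulk P/M ratios.

A sucrose gradient separates mRNAs by the number of ribosomes they
carry (80S monosome, 2-mer, 3-mer, ...).  For each pooled fraction the
target mRNA is quantified by qPCR relative to 18S rRNA (2^-ΔCt), then
corrected for

* the share of the pooled fraction sampled for RNA extraction
  (fraction volume / 300 µl) and the share of the extract reverse
  transcribed (25 µl / volume containing 5 µg RNA),
* per-fraction RNA recovery (the fraction's share of total A260 divided
  by its share of total measured 18S), and
* per-gradient monosome+polysome recovery (mean polysomal A260 across
  the gradients analysed in parallel, divided by this gradient's).

The corrected level is multiplied by the ribosome number of the
fraction and summed: the total ribosome load on the mRNA.  TE is that
load divided by the mRNA's input level in the whole-cell extract,
normalised to a reference mRNA (ACT1-like).  The treated/untreated TE
ratio per replicate gives ΔTE, summarised as mean ± SEM with a Welch
t-test between genotypes.

The cross-gradient recovery correction assumes all samples load the
same monosome+polysome content per A260 of extract; gradients whose
polysomal A260 deviates from the parallel-set mean by more than 25%
are flagged in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EXTRACTION_SAMPLE_UL",
    "RT_EXTRACT_UL",
    "GradientFractions",
    "ct_to_level",
    "volume_corrections",
    "recovery_factors",
    "estimate_te",
    "estimate_te_table",
    "delta_te_with_sem",
    "pm_ratio",
]

#: volume of each pooled fraction sampled for RNA extraction (µl)
EXTRACTION_SAMPLE_UL = 300.0
#: total volume the extracted RNA is eluted into (µl)
RT_EXTRACT_UL = 25.0


@dataclass
class GradientFractions:
    """One gradient: pooled-fraction measurements plus input-WCE Cts.

    ``fractions`` has one row per pooled fraction with columns
    ``label``, ``multiplier`` (ribosomes per mRNA; 0 for an unbound
    pool), ``a260_area``, ``volume_ul``, ``extraction_volume_ul`` (the
    volume of the 25 µl extract containing 5 µg RNA), ``ct_18s`` and
    one ``ct:<target>`` column per measured mRNA.  ``input_ct`` maps
    each target to its Ct in the unfractionated extract and
    ``input_ref_ct`` is the reference-mRNA (ACT1-equivalent) input Ct.
    """

    gradient_id: str
    genotype: str
    treatment: str
    replicate: int
    fractions: pd.DataFrame
    input_ct: dict[str, float] = field(default_factory=dict)
    input_ref_ct: float = 0.0

    def __post_init__(self) -> None:
        need = {"label", "multiplier", "a260_area", "volume_ul",
                "extraction_volume_ul", "ct_18s"}
        missing = need - set(self.fractions.columns)
        if missing:
            raise ValueError(f"{self.gradient_id}: missing column(s) {sorted(missing)}")
        mult = self.fractions["multiplier"].to_numpy()
        bound = mult[mult > 0]
        if len(bound) and np.any(np.diff(bound) <= 0):
            raise ValueError(
                f"{self.gradient_id}: ribosome multipliers must increase "
                "across bound fractions"
            )
        if np.any(self.fractions["volume_ul"].to_numpy() <= 0):
            raise ValueError(f"{self.gradient_id}: nonpositive fraction volume")

    @property
    def targets(self) -> list[str]:
        return [c[3:] for c in self.fractions.columns if c.startswith("ct:")]

    @property
    def polysomal_a260(self) -> float:
        """Total A260 in ribosome-bound (multiplier >= 1) fractions."""
        f = self.fractions
        return float(f.loc[f["multiplier"] >= 1, "a260_area"].sum())


def ct_to_level(ct_target, ct_reference):
    """Relative level by the 2^-ΔCt method: 2^-(ct_target - ct_reference)."""
    return 2.0 ** (-(np.asarray(ct_target, dtype=float)
                     - np.asarray(ct_reference, dtype=float)))


def volume_corrections(volume_ul, extraction_volume_ul):
    """Sampling corrections: (fraction volume / 300 µl) x (25 µl /
    volume of extract used for RT)."""
    v = np.asarray(volume_ul, dtype=float)
    e = np.asarray(extraction_volume_ul, dtype=float)
    if np.any(v <= 0) or np.any(e <= 0):
        raise ValueError("volumes must be positive")
    return (v / EXTRACTION_SAMPLE_UL) * (RT_EXTRACT_UL / e)


def recovery_factors(
    gradient: GradientFractions,
    parallel: list[GradientFractions] | None = None,
) -> tuple[pd.Series, float]:
    """Per-fraction RNA-recovery factors and the per-gradient factor.

    Fraction factor = (fraction's share of total A260) / (its share of
    total measured 18S, volume-corrected, within this gradient).
    Gradient factor = mean polysomal A260 over the parallel gradient set
    (defaulting to just this gradient) divided by this gradient's.
    """
    f = gradient.fractions
    a260 = f["a260_area"].to_numpy(dtype=float)
    if a260.sum() <= 0:
        raise ValueError(f"{gradient.gradient_id}: zero total A260")
    vc = volume_corrections(f["volume_ul"], f["extraction_volume_ul"])
    s18 = ct_to_level(f["ct_18s"], 0.0) * vc
    if s18.sum() <= 0:
        raise ValueError(f"{gradient.gradient_id}: zero total 18S")
    a_share = a260 / a260.sum()
    s_share = s18 / s18.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(s_share > 0, a_share / s_share, np.nan)
    if np.any(~np.isfinite(frac) & (a_share > 0)):
        raise ValueError(
            f"{gradient.gradient_id}: fraction with A260 signal but no 18S"
        )
    frac_series = pd.Series(frac, index=f.index, name="recovery_factor")

    gradients = parallel if parallel else [gradient]
    totals = np.array([g.polysomal_a260 for g in gradients])
    if gradient.polysomal_a260 <= 0:
        raise ValueError(f"{gradient.gradient_id}: zero polysomal A260")
    grad_factor = float(totals.mean() / gradient.polysomal_a260)
    return frac_series, grad_factor


def estimate_te(
    gradient: GradientFractions,
    parallel: list[GradientFractions] | None = None,
) -> pd.Series:
    """Per-target TE from one gradient's measurements.

    Ribosome load = sum over fractions of
    level x volume corrections x recovery factor x gradient factor x
    ribosome multiplier, with level = 2^-(ct_target - ct_18s); TE is the
    load divided by the input level (2^-ΔCt against the reference mRNA).
    """
    f = gradient.fractions
    vc = volume_corrections(f["volume_ul"], f["extraction_volume_ul"])
    frac_factor, grad_factor = recovery_factors(gradient, parallel)
    mult = f["multiplier"].to_numpy(dtype=float)
    out = {}
    for target in gradient.targets:
        level = ct_to_level(f[f"ct:{target}"], f["ct_18s"])
        load = float(np.nansum(
            level * vc * frac_factor.to_numpy() * grad_factor * mult
        ))
        if target not in gradient.input_ct:
            raise ValueError(f"{gradient.gradient_id}: no input Ct for {target}")
        input_level = float(
            ct_to_level(gradient.input_ct[target], gradient.input_ref_ct)
        )
        if input_level <= 0:
            raise ValueError(f"{gradient.gradient_id}: zero input level for {target}")
        out[target] = load / input_level
    return pd.Series(out, name=gradient.gradient_id)


def estimate_te_table(gradients: list[GradientFractions]) -> pd.DataFrame:
    """TEs for a set of gradients analysed in parallel.

    Returns one row per gradient (genotype, treatment, replicate, one
    column per target) plus a ``recovery_flag`` marking gradients whose
    polysomal A260 deviates > 25% from the parallel-set mean — a sign
    the equal-loading assumption behind the cross-gradient correction
    may not hold.
    """
    totals = np.array([g.polysomal_a260 for g in gradients])
    mean_total = totals.mean()
    rows = []
    for g, tot in zip(gradients, totals):
        te = estimate_te(g, gradients)
        row = {"gradient_id": g.gradient_id, "genotype": g.genotype,
               "treatment": g.treatment, "replicate": g.replicate,
               "recovery_flag": bool(abs(tot / mean_total - 1) > 0.25)}
        row.update(te.to_dict())
        rows.append(row)
    return pd.DataFrame(rows).set_index("gradient_id")


def delta_te_with_sem(te_table: pd.DataFrame, target: str) -> pd.DataFrame:
    """Treated/untreated TE ratios per replicate, per genotype.

    Returns one row per genotype with the per-replicate ratios, their
    mean and SEM (sd/sqrt(n), n >= 2 required), and a Welch t-test p
    comparing the two genotypes' ratio sets (NaN when both sets have
    zero variance, which is reported as no difference).
    """
    rows = []
    ratio_sets = {}
    for genotype, sub in te_table.groupby("genotype", sort=True):
        tr = sub[sub["treatment"] == "treated"].set_index("replicate")[target]
        un = sub[sub["treatment"] == "untreated"].set_index("replicate")[target]
        reps = tr.index.intersection(un.index)
        if len(reps) < 2:
            raise ValueError(
                f"{genotype}: need >=2 paired replicates for a SEM, "
                f"got {len(reps)}"
            )
        ratios = (tr[reps] / un[reps]).to_numpy(dtype=float)
        ratio_sets[genotype] = ratios
        rows.append({
            "genotype": genotype,
            "n": len(ratios),
            "mean_ratio": float(ratios.mean()),
            "sem": float(ratios.std(ddof=1) / np.sqrt(len(ratios))),
        })
    out = pd.DataFrame(rows).set_index("genotype")
    if len(ratio_sets) == 2:
        a, b = ratio_sets.values()
        if np.var(a) == 0 and np.var(b) == 0:
            p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
        else:
            _, p = stats.ttest_ind(a, b, equal_var=False)
        out["welch_p"] = float(p)
    return out


def pm_ratio(monosome_area: float, polysome_area: float) -> float:
    """Bulk polysome-to-monosome ratio from trace areas."""
    if monosome_area <= 0:
        raise ValueError("monosome area must be positive")
    if polysome_area < 0:
        raise ValueError("polysome area must be non-negative")
    return polysome_area / monosome_area
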