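import numpy as np
import pandas as pd
import pytest

from ribotekit.annotation import (
    CountMatrix,
    SampleMeta,
    Transcript,
    Transcriptome,
    UORF,
)

WT_U = ("WT", "untreated")
WT_T = ("WT", "treated")
MUT_U = ("mutant", "untreated")
MUT_T = ("mutant", "treated")
CONDITIONS = (WT_U, WT_T, MUT_U, MUT_T)


def make_samples(assay: str, conditions=CONDITIONS, n_reps: int = 2):
    """2x2xn sample grid for one assay."""
    return [
        SampleMeta(
            name=f"{assay}_{g}_{'SM' if t == 'treated' else 'untr'}_{r + 1}",
            genotype=g, treatment=t, replicate=r + 1, assay=assay,
        )
        for (g, t) in conditions
        for r in range(n_reps)
    ]


def make_matrix(values, features, samples, assay, exact=False):
    frame = pd.DataFrame(
        np.asarray(values), index=features, columns=[s.name for s in samples]
    )
    return CountMatrix(frame, samples, assay, exact=exact)


@pytest.fixture
def toy_tx():
    """Three hand-built transcripts, two carrying uORFs."""
    return Transcriptome([
        Transcript(
            "tA", 100, 30, 60, "MKVLDEQWRH",
            [UORF("tA", 3, 12, "AUG", "annotated", "inhibitory")],
        ),
        Transcript(
            "tB", 80, 24, 72, "MACDEFGHIKLNPQST",
            [UORF("tB", 0, 6, "CUG", "functional", "none")],
        ),
        Transcript("tC", 60, 12, 48, "MAAAAAAAAAAY"),
    ])


@pytest.fixture
def paired_counts():
    """Matched RPF/RNA matrices over two conditions, hand-enterable."""
    samples_rpf = make_samples("RPF", (WT_U, WT_T))
    samples_rna = make_samples("RNA", (WT_U, WT_T))
    features = ["g1", "g2", "g3"]
    rpf = make_matrix(
        [[100, 110, 200, 190],
         [50, 55, 50, 45],
         [10, 12, 40, 44]],
        features, samples_rpf, "RPF",
    )
    rna = make_matrix(
        [[50, 52, 50, 49],
         [50, 51, 50, 52],
         [20, 22, 20, 21]],
        features, samples_rna, "RNA",
    )
    return rpf, rna
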