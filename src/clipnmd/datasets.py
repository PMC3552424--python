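"""Packaged reference data.

``qpcr_validation_folds.tsv`` transcribes the published qRT-PCR validation of
transcripts with NOVA-dependent steady-state changes in WT vs Nova1/Nova2
double-knockout mouse brain: per gene, the measured qRT-PCR fold change
(WT relative to DKO), its standard deviation, the exon-array-predicted fold,
and whether the transcript sits in the "larger" or "smaller" predicted
fold-change section of the validation set. Folds > 1 mean higher levels in WT.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_validation_folds() -> pd.DataFrame:
    with resources.files("clipnmd.data").joinpath(
            "qpcr_validation_folds.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def fold_filter_count(folds: pd.DataFrame, threshold: float = 1.5,
                      section: str = "larger",
                      column: str = "array_fold") -> int:
    """Number of transcripts in a section whose predicted fold exceeds ``threshold``.

    With the default >1.5x up-regulation filter on the microarray-predicted
    fold this recovers the experimentally validated up-regulated gene count.
    """
    sub = folds[folds["section"] == section]
    return int((sub[column] > threshold).sum())


def direction_concordance_count(folds: pd.DataFrame,
                                section: str = "larger") -> int:
    """Transcripts whose qRT-PCR and microarray folds fall on the same side of 1."""
    sub = folds[folds["section"] == section]
    same = ((sub["qpcr_fold"] > 1.0) & (sub["array_fold"] > 1.0)) | (
        (sub["qpcr_fold"] < 1.0) & (sub["array_fold"] < 1.0))
    return int(same.sum())
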