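"""Expression heatmap matrix preparation: TPM, log transform, per-gene scaling.

TPM (transcripts per million): per-gene count rates (count / transcript
length) rescaled so each sample column sums to one million. Heatmap values
are log2(TPM + 1) followed by per-gene centring and scaling by the sample
SD across samples — the classic row z-score display. Effective length is
the annotated transcript length; no fragment-length correction is applied
(the dialect of this module, documented rather than inherited from any
particular quantifier).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InputError

VALUE_KINDS = ("raw_count", "tpm", "log_tpm", "scaled")


@dataclass
class ExpressionMatrix:
    """Gene x sample value matrix tagged with what the values are."""

    values: pd.DataFrame  # genes rows x samples columns
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in VALUE_KINDS:
            raise InputError(f"kind must be one of {VALUE_KINDS}")
        if self.kind in ("raw_count", "tpm") and (self.values.to_numpy() < 0).any():
            raise InputError(f"{self.kind} values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id",
                           float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id", comment="#")
        return cls(values=df, kind=kind)


def read_gene_lengths(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise InputError("gene-length TSV needs two columns: gene_id, length_bp")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="length_bp")
    return s


def tpm_from_counts(
    counts: ExpressionMatrix, effective_lengths: pd.Series
) -> ExpressionMatrix:
    """Convert raw counts to TPM using per-gene effective lengths (bp).

    Every output sample column sums to 1e6; an all-zero input column stays
    all-zero and triggers a warning.
    """
    if counts.kind != "raw_count":
        raise InputError("tpm_from_counts expects a raw_count matrix")
    lengths = effective_lengths.reindex(counts.values.index)
    if lengths.isna().any():
        missing = list(counts.values.index[lengths.isna()])[:5]
        raise InputError(f"missing effective length for genes: {missing} ...")
    if (lengths <= 0).any():
        raise InputError("effective lengths must be positive")

    rate = counts.values.div(lengths, axis=0)
    colsum = rate.sum(axis=0)
    zero_cols = colsum[colsum == 0].index.tolist()
    if zero_cols:
        warnings.warn(
            f"all-zero count columns stay all-zero in TPM: {zero_cols}",
            stacklevel=2,
        )
        colsum = colsum.replace(0.0, np.nan)
    tpm = rate.div(colsum, axis=1).fillna(0.0) * 1e6
    return ExpressionMatrix(values=tpm, kind="tpm")


def log_scale_matrix(tpm: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1), then per-gene row z-scores across samples.

    Scaling uses the sample SD (n-1 denominator); constant rows — including
    all-zero genes — map to all-zero rows. Requires >= 2 samples.
    """
    if tpm.kind != "tpm":
        raise InputError("log_scale_matrix expects a tpm matrix")
    if tpm.values.shape[1] < 2:
        raise InputError("scaling needs at least 2 samples (SD undefined)")
    logv = np.log2(tpm.values + 1.0)
    mu = logv.mean(axis=1)
    sd = logv.std(axis=1, ddof=1)
    scaled = logv.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
    return ExpressionMatrix(values=scaled, kind="scaled")


def plot_heatmap(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Optional heatmap image; the numeric matrix is the primary output."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * len(matrix.sample_ids)),
                 max(3, 0.3 * len(matrix.gene_ids)))
    )
    im = ax.imshow(matrix.values.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(len(matrix.sample_ids)))
    ax.set_xticklabels(matrix.sample_ids, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.gene_ids)))
    ax.set_yticklabels(matrix.gene_ids, fontsize=7)
    fig.colorbar(im, ax=ax, label=matrix.kind)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
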