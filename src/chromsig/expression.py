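"""Expression-level gene categories: TPM, expressed calls, tau breadth, sex bias.

TPM is computed from raw counts and gene lengths; a gene counts as expressed
when it reaches its sample's 5th-percentile TPM threshold in at least one
sample (configurable to require all samples); expression breadth across
conditions is the specificity index tau, with tau < 0.25 broad
(housekeeping) and tau > 0.75 narrow; sex bias is called from a supplied
differential-expression table at |fold change| >= 2 and FDR < 0.05 with
TPM > 1 in the favoured sex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TPM_TRANSCRIBED = 1.0
TAU_BROAD = 0.25
TAU_NARROW = 0.75
DEFAULT_LOG2FC = 1.0   # |log2 FC| >= 1, i.e. 2-fold
DEFAULT_FDR = 0.05


@dataclass
class ExpressionTable:
    """Genes x samples TPM with sample metadata (sex, replicate)."""

    tpm: pd.DataFrame                 # index gene_id, columns sample names
    metadata: pd.DataFrame            # index sample name; columns incl. 'sex'
    counts: pd.DataFrame | None = None
    lengths: pd.Series | None = None

    def samples_of_sex(self, sex: str) -> list[str]:
        return list(self.metadata.index[self.metadata["sex"] == sex])

    def mean_tpm(self, sex: str | None = None) -> pd.Series:
        cols = self.samples_of_sex(sex) if sex else list(self.tpm.columns)
        return self.tpm[cols].mean(axis=1)


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series,
                metadata: pd.DataFrame | None = None) -> ExpressionTable:
    """Transcripts per million from raw counts and gene lengths (bp)."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise ValueError(f"genes without length: {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be >= 0")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"all-zero samples: {list(totals.index[zero])}")
    tpm = rate.div(totals.where(~zero, 1.0), axis=1) * 1e6
    tpm.loc[:, zero] = 0.0
    if metadata is None:
        metadata = pd.DataFrame(index=counts.columns)
        metadata["sex"] = ""
    return ExpressionTable(tpm=tpm, metadata=metadata, counts=counts, lengths=lengths)


def call_expressed(table: ExpressionTable, percentile: float = 5.0,
                   combine: str = "any") -> pd.Series:
    """Expressed flag per gene: TPM at or above its sample's percentile
    threshold in at least one sample (``combine='any'``) or every sample."""
    tpm = table.tpm
    if tpm.empty:
        raise ValueError("empty expression table")
    if len(tpm) < 20:
        warnings.warn("fewer than 20 genes: percentile threshold is degenerate")
    thresholds = tpm.apply(lambda col: np.percentile(col, percentile), axis=0)
    above = tpm.ge(thresholds, axis=1)
    if combine == "any":
        return above.any(axis=1)
    if combine == "all":
        return above.all(axis=1)
    raise ValueError(f"combine must be 'any' or 'all', got {combine!r}")


def compute_tau(profile: pd.DataFrame) -> pd.DataFrame:
    """Expression-breadth index tau across N >= 2 conditions.

    tau = sum_i (1 - x_i / max_i x_i) / (N - 1); 0 for uniform profiles,
    1 for single-condition expression.  All-zero genes get tau = NaN and
    breadth missing.  Breadth: tau < 0.25 housekeeping, tau > 0.75 narrow,
    else intermediate (strict inequalities).
    """
    X = profile.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("tau needs at least 2 conditions")
    if (X < 0).any():
        raise ValueError("expression values must be >= 0")
    mx = X.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        xhat = np.where(mx[:, None] > 0, X / np.where(mx[:, None] > 0, mx[:, None], 1.0),
                        np.nan)
    tau = (1.0 - xhat).sum(axis=1) / (X.shape[1] - 1)
    tau = np.where(mx > 0, tau, np.nan)
    breadth = np.select(
        [np.isnan(tau), tau < TAU_BROAD, tau > TAU_NARROW],
        ["MISSING", "HOUSEKEEPING", "NARROW"],
        default="INTERMEDIATE",
    )
    return pd.DataFrame({"tau": tau, "breadth": breadth}, index=profile.index)


def expression_categories(table: ExpressionTable,
                          tissue_profile: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-gene expressed flag, transcribed flag (TPM >= 1 in any sample),
    and — when a multi-condition profile is given — tau breadth labels."""
    out = pd.DataFrame(index=table.tpm.index)
    out["expressed"] = call_expressed(table)
    out["transcribed"] = (table.tpm >= TPM_TRANSCRIBED).any(axis=1)
    if tissue_profile is not None:
        tau = compute_tau(tissue_profile.reindex(out.index).fillna(0.0))
        out["tau"] = tau["tau"]
        out["breadth"] = tau["breadth"]
    return out


@dataclass
class SexBiasTable:
    table: pd.DataFrame  # gene_id index: log2fc, fdr, bias

    def genes_with(self, label: str) -> list[str]:
        return list(self.table.index[self.table["bias"] == label])

    def counts(self) -> pd.Series:
        return self.table["bias"].value_counts()


def call_sex_bias(
    de_table: pd.DataFrame,
    table: ExpressionTable,
    log2fc_threshold: float = DEFAULT_LOG2FC,
    fdr_threshold: float = DEFAULT_FDR,
    min_tpm: float = TPM_TRANSCRIBED,
) -> SexBiasTable:
    """Sex-bias labels from a differential-expression table.

    ``de_table`` is indexed by gene_id with columns ``log2fc`` (male over
    female) and ``fdr``.  MALE_BIASED needs log2fc >= threshold, FDR below
    cutoff and male mean TPM > ``min_tpm``; FEMALE_BIASED is symmetric; genes
    failing either or absent from the table are UNBIASED.
    """
    fdr = de_table["fdr"]
    if ((fdr < 0) | (fdr > 1)).any():
        raise ValueError("adjusted p-values outside [0, 1]")
    male_mean = table.mean_tpm("male")
    female_mean = table.mean_tpm("female")
    out = pd.DataFrame(index=table.tpm.index)
    out["log2fc"] = de_table["log2fc"].reindex(out.index)
    out["fdr"] = fdr.reindex(out.index)
    sig = out["fdr"] < fdr_threshold
    male = sig & (out["log2fc"] >= log2fc_threshold) & (male_mean > min_tpm)
    female = sig & (out["log2fc"] <= -log2fc_threshold) & (female_mean > min_tpm)
    out["bias"] = np.select([male.fillna(False), female.fillna(False)],
                            ["MALE_BIASED", "FEMALE_BIASED"], default="UNBIASED")
    return SexBiasTable(table=out)
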