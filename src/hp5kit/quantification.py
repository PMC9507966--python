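"""Spike-in normalization and mean ribosome load (MRL).

MRL for an mRNA over polysome fractions 1..8 (fraction 8 pools everything
with eight or more ribosomes) is the count-weighted mean ribosome number

    MRL = sum_i i * c_i / sum_i c_i,   i = 1..8,

computed on spike-in normalized counts.  Size factors are median-of-ratios
on the external-control (spike-in) rows only, making the normalization
immune to global shifts in translation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "spikein_size_factors",
    "normalize_counts",
    "mean_ribosome_load",
    "mrl_table",
    "filter_low_abundance",
    "gene_level_profile",
    "split_spike_rows",
]


def split_spike_rows(counts: pd.DataFrame, spike_prefix: str = "ERCC-"):
    """Partition a count matrix into (mRNA rows, spike-in rows)."""
    is_spike = counts.index.astype(str).str.startswith(spike_prefix)
    return counts.loc[~is_spike], counts.loc[is_spike]


def spikein_size_factors(spike_counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors from the spike-in submatrix.

    The reference is the per-row geometric mean across samples (rows with
    any zero count are excluded from the reference, the median-of-ratios
    convention); the factor for sample s is the median over rows of
    count_rs / reference_r.
    """
    mat = spike_counts.to_numpy(dtype=float)
    if mat.shape[0] < 3:
        raise ValueError("need >= 3 spike-in species to estimate size factors")
    zero_samples = spike_counts.columns[(mat == 0).all(axis=0)]
    if len(zero_samples):
        raise ValueError(
            f"sample(s) {list(zero_samples)} have all-zero spike-in counts"
        )
    pos = (mat > 0).all(axis=1)
    if not pos.any():
        raise ValueError("no spike-in row has nonzero counts in every sample")
    logref = np.log(mat[pos]).mean(axis=1)
    ratios = mat[pos] / np.exp(logref)[:, None]
    factors = np.median(ratios, axis=0)
    if (factors <= 0).any():
        raise ValueError("non-positive size factor estimated")
    return pd.Series(factors, index=spike_counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    f = factors.reindex(counts.columns)
    if f.isna().any() or (f <= 0).any():
        raise ValueError("every sample needs a positive size factor")
    return counts / f


def mean_ribosome_load(profile) -> float:
    """MRL of one normalized 8-fraction profile; NaN for an all-zero profile."""
    c = np.asarray(profile, dtype=float)
    if c.shape[-1] != 8:
        raise ValueError("profile must cover fractions 1..8")
    tot = c.sum()
    if tot <= 0:
        return float("nan")
    return float((np.arange(1, 9) * c).sum() / tot)


def mrl_table(
    normalized: pd.DataFrame,
    samples: pd.DataFrame,
    aggregate: str = "mean_of_replicates",
) -> pd.DataFrame:
    """Per-row, per-condition MRL from a normalized fraction count matrix.

    ``samples`` maps each column to (condition, replicate, fraction).  The
    default computes one MRL per replicate and averages replicates within a
    condition (undefined replicate profiles are dropped from the mean);
    ``aggregate='pooled'`` sums normalized counts over replicates first.
    """
    meta = samples.set_index("sample")
    out = {}
    for cond, cond_meta in meta.groupby("condition", sort=True):
        if aggregate == "pooled":
            prof = _condition_profiles(normalized, cond_meta)
            out[cond] = prof.apply(mean_ribosome_load, axis=1)
        elif aggregate == "mean_of_replicates":
            per_rep = []
            for _, rep_meta in cond_meta.groupby("replicate", sort=True):
                prof = _condition_profiles(normalized, rep_meta)
                per_rep.append(prof.apply(mean_ribosome_load, axis=1))
            out[cond] = pd.concat(per_rep, axis=1).mean(axis=1, skipna=True)
        else:
            raise ValueError(f"unknown aggregate mode {aggregate!r}")
    df = pd.DataFrame(out)
    df.index.name = "row_id"
    return df


def _condition_profiles(normalized: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Rows x fractions 1..8, summing any duplicate fraction columns."""
    prof = pd.DataFrame(0.0, index=normalized.index, columns=range(1, 9))
    for sample, row in meta.iterrows():
        prof[int(row["fraction"])] += normalized[sample]
    return prof


def filter_low_abundance(
    counts: pd.DataFrame, min_count: int = 6, min_samples: int = 7
) -> pd.Index:
    """Rows with raw count >= ``min_count`` in at least ``min_samples`` samples.

    The defaults implement the rule that an mRNA needs six read counts in
    more than six samples of the comparison set to enter MRL estimation.
    """
    ok = (counts >= min_count).sum(axis=1) >= min_samples
    return counts.index[ok]


def gene_level_profile(
    normalized: pd.DataFrame, isoform_to_gene: pd.Series
) -> pd.DataFrame:
    """Sum isoform rows per gene (gene MRL = usage-weighted mean of isoform MRLs)."""
    genes = isoform_to_gene.reindex(normalized.index)
    if genes.isna().any():
        missing = list(normalized.index[genes.isna()])
        raise ValueError(f"isoforms without gene assignment: {missing[:5]}")
    out = normalized.groupby(genes).sum()
    out.index.name = "gene_id"
    return out
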