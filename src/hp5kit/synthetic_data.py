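"""Synthetic 5'-end-seq / polysome-profiling experiments with known ground truth.

The generator builds a small genome with single-exon genes, each carrying
one to four transcription start sites (annotated transcripts), then emulates

* per-base 5'-end read-count tracks for unfractionated libraries, with a
  per-base fraction of reads carrying a non-genomic 5' G (high at capped
  starts, low at planted internal-priming artifact clusters), and
* isoform x polysome-fraction count matrices (8 fractions, fraction 8
  pooling everything with >= 8 ribosomes) with external spike-in rows,
  per-sample library factors and Dirichlet-multinomial replicate noise.

Every isoform has a true mean ribosome load (MRL) per condition in [1, 8];
fraction weights are a discretized logit-normal over fractions 1..8 whose
mean is matched to the target MRL by 1-D root finding, giving smooth
unimodal polysome traces.  All randomness flows from ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import logit
from scipy.stats import beta as beta_dist

from hp5kit.io import Annotation, Gene, Transcript

__all__ = [
    "SimConfig",
    "generate_reference",
    "plant_truth",
    "fraction_weights",
    "simulate_end5_counts",
    "simulate_polysome_experiment",
]

_STOPS = ("TAA", "TAG", "TGA")
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass
class SimConfig:
    """Study conditions for the simulated experiments.

    ``spikein_fraction`` defaults to 0.1% of reads, the level used for the
    external control RNA in the assay this emulates.  ``dispersion`` is the
    Dirichlet-multinomial overdispersion of fraction proportions between
    replicates (concentration = 1/dispersion); the default corresponds to a
    few percent replicate CV of fraction shares, typical of replicate
    polysome preparations.  ``kernel_sd`` is the positional spread (bp) of
    5' ends around a true TSS; real data do not pin this down, so it is a
    free simulation parameter.
    """

    n_genes: int = 50
    isoforms_per_gene: tuple[int, int] = (1, 4)
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {f"chr{i}": 100_000 for i in range(1, 9)}
    )
    fractions: int = 8
    replicates: int = 3
    library_size: int = 1_000_000
    spikein_fraction: float = 0.001
    dispersion: float = 0.002
    seed: int = 1
    conditions: tuple[str, ...] = ("A", "B")
    kernel_sd: float = 1.2
    artifact_rate: float = 0.5
    usage_shift_fraction: float = 0.2
    te_shift_fraction: float = 0.2
    n_spike_species: int = 20
    logit_sigma: float = 1.0
    library_factor_sd: float = 0.15

    def validate(self) -> None:
        if self.fractions != 8:
            raise ValueError("the assay uses exactly 8 polysome fractions")
        if not 0 < self.spikein_fraction < 0.05:
            raise ValueError("spikein_fraction must be in (0, 0.05)")
        for name, val in [
            ("n_genes", self.n_genes),
            ("replicates", self.replicates),
            ("library_size", self.library_size),
            ("n_spike_species", self.n_spike_species),
        ]:
            if val < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.isoforms_per_gene[0] < 1 or self.isoforms_per_gene[1] < self.isoforms_per_gene[0]:
            raise ValueError("isoforms_per_gene must be a range with min >= 1")
        if min(self.chrom_lengths.values()) < 10_000:
            raise ValueError("chromosomes must be >= 10 kb")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def _seeds(self) -> dict[str, np.random.SeedSequence]:
        children = np.random.SeedSequence(self.seed).spawn(4)
        return dict(zip(["reference", "truth", "end5", "polysome"], children))


# ---------------------------------------------------------------------------
# Reference genome + annotation
# ---------------------------------------------------------------------------

def generate_reference(config: SimConfig) -> tuple[dict[str, str], Annotation]:
    """Random genome and single-exon gene annotation.

    Genes have 1-4 transcripts whose annotated TSSs are >= 60 bp apart,
    a shared CDS (AUG..stop, coding length >= 102 nt, no internal in-frame
    stop) and a 5' UTR of at least ~20 nt for the 5'-least isoform.
    Deterministic for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config._seeds()["reference"])
    chroms = sorted(config.chrom_lengths)
    genome = {
        c: "".join(rng.choice(list("ACGT"), size=config.chrom_lengths[c]))
        for c in chroms
    }
    cursors = {c: 2_000 for c in chroms}
    genes = []
    lo, hi = config.isoforms_per_gene
    for gi in range(config.n_genes):
        chrom = chroms[gi % len(chroms)]
        strand = "+" if rng.random() < 0.5 else "-"
        n_iso = int(rng.integers(lo, hi + 1))
        # transcript-space layout (offset 0 = 5'-most TSS)
        tss_off = np.concatenate([[0], np.cumsum(rng.integers(60, 200, size=n_iso - 1))])
        utr_last = int(rng.integers(20, 80))
        cds_off = int(tss_off[-1]) + utr_last
        n_codons = int(rng.integers(35, 130))  # incl. stop => coding >= 102 nt
        cds_len = 3 * n_codons
        utr3 = int(rng.integers(30, 100))
        length = cds_off + cds_len + utr3

        local = (
            "".join(rng.choice(list("ACGT"), size=cds_off))
            + "ATG"
            + "".join(rng.choice(_CODONS, size=n_codons - 2))
            + "TAA"
            + "".join(rng.choice(list("ACGT"), size=utr3))
        )

        start = cursors[chrom] + int(rng.integers(1_000, 3_000))
        end = start + length
        if end > config.chrom_lengths[chrom] - 2_000:
            raise ValueError(
                f"chromosome {chrom} too short to place gene {gi + 1} of "
                f"{config.n_genes}; enlarge chrom_lengths or reduce n_genes"
            )
        cursors[chrom] = end

        gid = f"G{gi + 1:04d}"
        if strand == "+":
            genome[chrom] = genome[chrom][:start] + local + genome[chrom][end:]
            exon = lambda off: (start + int(off), end)  # noqa: E731
            cds = (start + cds_off, start + cds_off + cds_len)
        else:
            genome[chrom] = genome[chrom][:start] + _revcomp(local) + genome[chrom][end:]
            exon = lambda off: (start, end - int(off))  # noqa: E731
            cds = (end - cds_off - cds_len, end - cds_off)
        txs = [
            Transcript(f"{gid}.{k + 1}", gid, chrom, strand, [exon(tss_off[k])], cds=cds)
            for k in range(n_iso)
        ]
        genes.append(Gene(gid, chrom, strand, min(t.start for t in txs),
                          max(t.end for t in txs), txs))
    return genome, Annotation(genes)


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def plant_truth(annotation: Annotation, config: SimConfig) -> pd.DataFrame:
    """Per-isoform ground truth: TSS, usage and MRL per condition, flags.

    Planted isoform usages are a floored simplex (every isoform >= ~12% of
    its gene), so that the minor-isoform behaviour of the clustering filter
    is exercised by dedicated constructions rather than by chance here.
    Usage-shift genes swap their two most-used isoforms between conditions;
    TE-shift genes move every isoform's MRL by a common offset.  Artifact
    rows model internal-priming 5'-end clusters inside the gene body; their
    abundance is a fraction of the gene total, well above the minor-isoform
    cutoff.
    """
    config.validate()
    rng = np.random.default_rng(config._seeds()["truth"])
    cond_a, cond_b = config.conditions[:2]
    rows = []
    for gid in sorted(annotation.genes):
        gene = annotation.genes[gid]
        k = len(gene.transcripts)
        usage_a = 0.5 * rng.dirichlet(np.ones(k)) + 0.5 / k
        usage_shift = bool(k >= 2 and rng.random() < config.usage_shift_fraction)
        usage_b = usage_a.copy()
        if usage_shift:
            i, j = np.argsort(usage_a)[-2:]
            usage_b[i], usage_b[j] = usage_a[j], usage_a[i]
        te_shift = bool(rng.random() < config.te_shift_fraction)
        mrl_a = rng.uniform(2.0, 7.0, size=k)
        if te_shift:
            delta = rng.choice([-1.0, 1.0]) * rng.uniform(1.0, 2.5)
            mrl_b = np.clip(mrl_a + delta, 1.2, 7.8)
        else:
            mrl_b = mrl_a.copy()
        expr = float(rng.lognormal(0.0, 1.0))
        for t, ua, ub, ma, mb in zip(gene.transcripts, usage_a, usage_b, mrl_a, mrl_b):
            rows.append(
                dict(
                    gene_id=gid, isoform_id=t.transcript_id, chrom=gene.chrom,
                    strand=gene.strand, tss=t.tss, is_artifact=False,
                    rel_abundance=float("nan"), gene_expr=expr,
                    usage_shift=usage_shift, te_shift=te_shift,
                    **{f"usage_{cond_a}": float(ua), f"usage_{cond_b}": float(ub),
                       f"mrl_{cond_a}": float(ma), f"mrl_{cond_b}": float(mb)},
                )
            )
        if rng.random() < config.artifact_rate:
            cds = gene.transcripts[0].cds
            pos = int(rng.integers(cds[0] + 10, cds[1] - 10))
            rows.append(
                dict(
                    gene_id=gid, isoform_id=f"{gid}.art", chrom=gene.chrom,
                    strand=gene.strand, tss=pos, is_artifact=True,
                    rel_abundance=float(rng.uniform(0.15, 0.35)), gene_expr=expr,
                    usage_shift=usage_shift, te_shift=te_shift,
                    **{f"usage_{cond_a}": 0.0, f"usage_{cond_b}": 0.0,
                       f"mrl_{cond_a}": float("nan"), f"mrl_{cond_b}": float("nan")},
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 5'-end tracks
# ---------------------------------------------------------------------------

def simulate_end5_counts(
    reference: tuple[dict[str, str], Annotation],
    truth: pd.DataFrame,
    config: SimConfig,
) -> dict[str, pd.DataFrame]:
    """Per-sample unfractionated 5'-end tracks (chrom,pos,strand,count,g_fraction).

    5' ends are drawn around each true TSS with a discretized Gaussian
    kernel.  Per-base non-genomic-G fractions come from Beta(8,4) truncated
    to >= 0.3 for capped starts and Beta(1,19) for internal-priming
    artifacts, cleanly separating the two around the 15% threshold used by
    the artifact filter.  Total mRNA reads per sample are
    ``library_size * (1 - spikein_fraction)``.
    """
    config.validate()
    genome, _ = reference
    ss = config._seeds()["end5"].spawn(len(config.conditions) * config.replicates)
    tracks: dict[str, pd.DataFrame] = {}
    si = 0
    for cond in config.conditions:
        ucol = f"usage_{cond}"
        expected = np.where(
            truth["is_artifact"],
            truth["gene_expr"] * truth["rel_abundance"].fillna(0.0),
            truth["gene_expr"] * truth[ucol],
        ).astype(float)
        p = expected / expected.sum()
        for rep in range(1, config.replicates + 1):
            rng = np.random.default_rng(ss[si]); si += 1
            n_mrna = int(round(config.library_size * (1 - config.spikein_fraction)))
            reads = rng.multinomial(n_mrna, p)
            recs = []
            for (_, row), n in zip(truth.iterrows(), reads):
                if n == 0:
                    continue
                if config.kernel_sd > 0:
                    off = np.rint(rng.normal(0.0, config.kernel_sd, size=n)).astype(int)
                else:
                    off = np.zeros(n, dtype=int)
                pos = np.clip(row["tss"] + off, 0, len(genome[row["chrom"]]) - 1)
                upos, cnt = np.unique(pos, return_counts=True)
                g = _draw_g_fractions(rng, len(upos), artifact=bool(row["is_artifact"]))
                recs.append(
                    pd.DataFrame(
                        {"chrom": row["chrom"], "pos": upos,
                         "strand": row["strand"], "count": cnt, "g_fraction": g}
                    )
                )
            track = pd.concat(recs, ignore_index=True)
            track = (
                track.assign(weighted=track["count"] * track["g_fraction"])
                .groupby(["chrom", "pos", "strand"], as_index=False)
                .agg(count=("count", "sum"), weighted=("weighted", "sum"))
            )
            track["g_fraction"] = track["weighted"] / track["count"]
            track = track.drop(columns="weighted").sort_values(
                ["chrom", "pos", "strand"], kind="mergesort", ignore_index=True
            )
            tracks[f"{cond}_rep{rep}"] = track
    return tracks


def _draw_g_fractions(rng: np.random.Generator, n: int, artifact: bool) -> np.ndarray:
    if artifact:
        return rng.beta(1.0, 19.0, size=n)
    # Beta(8,4) truncated to >= 0.3 via inverse-CDF sampling
    lo = beta_dist.cdf(0.3, 8, 4)
    u = rng.uniform(lo, 1.0, size=n)
    return beta_dist.ppf(u, 8, 4)


# ---------------------------------------------------------------------------
# Polysome fraction counts
# ---------------------------------------------------------------------------

def fraction_weights(target_mrl: float, sigma: float = 1.0) -> np.ndarray:
    """Expected fraction proportions over fractions 1..8 with the given mean.

    A Gaussian kernel on the logit of the fraction midpoints (i-0.5)/8; its
    location is matched to the target mean ribosome load by root finding.
    Targets of exactly 1 or 8 return the corresponding one-hot profile.
    """
    if not 1.0 <= target_mrl <= 8.0:
        raise ValueError(f"target MRL {target_mrl} outside [1, 8]")
    i = np.arange(1, 9)
    if target_mrl <= 1.0 + 1e-9:
        return (i == 1).astype(float)
    if target_mrl >= 8.0 - 1e-9:
        return (i == 8).astype(float)
    li = logit((i - 0.5) / 8.0)

    def mean_at(mu: float) -> float:
        w = np.exp(-((li - mu) ** 2) / (2 * sigma**2))
        w /= w.sum()
        return float((i * w).sum())

    mu = brentq(lambda m: mean_at(m) - target_mrl, -40.0, 40.0, xtol=1e-12)
    w = np.exp(-((li - mu) ** 2) / (2 * sigma**2))
    return w / w.sum()


def simulate_polysome_experiment(
    truth: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Isoform x (condition, replicate, fraction) counts plus spike-ins.

    Returns ``(counts, samples, truth_out)`` where ``counts`` has one row
    per TSS isoform and per ERCC- spike species and one column per
    fraction-sample, and ``samples`` is the sample sheet (sample, condition,
    replicate, fraction, library factor).  Each isoform's RNA mass is
    spread over fractions 1..8 by a Dirichlet draw around its target-MRL
    weights (one draw per replicate); every fraction is then sequenced as
    its own library to a depth of ``library_size/8`` times a lognormal
    library factor, with a fixed amount of external spike-in RNA added to
    each fraction sample, so spike-in counts trace the sequencing depth per
    RNA mass and median-of-ratios on the spike rows recovers the mass scale.
    """
    config.validate()
    iso = truth[~truth["is_artifact"]].reset_index(drop=True)
    for cond in config.conditions:
        bad = ~iso[f"mrl_{cond}"].between(1.0, 8.0)
        if bad.any():
            raise ValueError(
                f"true MRL outside [1, 8] for isoforms "
                f"{iso.loc[bad, 'isoform_id'].tolist()} in condition {cond}"
            )
    rng = np.random.default_rng(config._seeds()["polysome"])
    spike_base = rng.lognormal(0.0, 0.8, size=config.n_spike_species)
    spike_base /= spike_base.sum()
    spike_ids = [f"ERCC-{i + 1:04d}" for i in range(config.n_spike_species)]

    expr = iso["gene_expr"].to_numpy()
    depth = config.library_size / 8.0
    cols: dict[str, np.ndarray] = {}
    meta = []
    for cond in config.conditions:
        usage = iso[f"usage_{cond}"].to_numpy()
        mass_iso = expr * usage  # relative RNA mass per isoform
        mass_iso = mass_iso / mass_iso.sum()
        weights = np.stack([fraction_weights(m, config.logit_sigma)
                            for m in iso[f"mrl_{cond}"]])
        # equal spike-in mass added to every fraction sample, sized so that
        # spike reads make up ~spikein_fraction of the library overall
        spike_mass = (
            spike_base * config.spikein_fraction / (1 - config.spikein_fraction) / 8.0
        )
        for rep in range(1, config.replicates + 1):
            if config.dispersion > 0:
                conc = weights / config.dispersion
                props = np.stack([rng.dirichlet(np.maximum(c, 1e-9)) for c in conc])
            else:
                props = weights
            mass = mass_iso[:, None] * props  # isoform x fraction RNA mass
            for frac in range(1, 9):
                f_s = float(rng.lognormal(0.0, config.library_factor_sd))
                n_reads = int(round(depth * f_s))
                m = np.concatenate([mass[:, frac - 1], spike_mass])
                name = f"{cond}_rep{rep}_f{frac}"
                cols[name] = rng.multinomial(n_reads, m / m.sum())
                meta.append(dict(sample=name, condition=cond, replicate=rep,
                                 fraction=frac, lib_factor=f_s))
    counts = pd.DataFrame(cols, index=list(iso["isoform_id"]) + spike_ids)
    counts.index.name = "row_id"
    return counts, pd.DataFrame(meta), iso.copy()
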