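"""End-to-end pipeline driver: simulate -> cluster -> quantify -> features ->
differential -> decompose -> model, with on-disk artifacts and provenance.

Every stage writes TSV outputs plus a JSON provenance sidecar (tool,
version, seed, thresholds, stage inputs); reruns with the same
configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hp5kit import io
from hp5kit import synthetic_data as sd
from hp5kit import tss_clustering as tc
from hp5kit import quantification as qt
from hp5kit import features as ft
from hp5kit import differential as dif
from hp5kit import decomposition as dc
from hp5kit import model as gam

__all__ = ["RunConfig", "write_simulation", "run_pipeline"]


@dataclass
class RunConfig:
    genome: str = ""
    annotation: str = ""
    tracks_dir: str = ""
    counts: str = ""
    samples: str = ""
    outdir: str = "hp5_out"
    seed: int = 1
    # clustering
    min_stability: float = 2.0
    min_count: float = 30.0
    max_length: int = 200
    min_separation: int = 5
    min_rel_height: float = 0.10
    g_threshold: float = 0.15
    minor_max_relative: float = 0.10
    # quantification
    spike_prefix: str = "ERCC-"
    low_count: int = 6
    low_count_samples: int = 7
    # differential
    fdr: float = 0.1
    # model
    gam_basis: int = 4
    gam_repeats: int = 10
    gam_holdout_chroms: int = 4

    def validate(self) -> None:
        for name in ("genome", "annotation", "tracks_dir", "counts", "samples"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"config path {name!r} missing: {p}")


def _write(df: pd.DataFrame, path: Path, config: RunConfig, stage: str, **extra):
    io.write_table(df, path)
    block = io.provenance_block(seed=config.seed, stage=stage,
                                **{**_thresholds(config), **extra})
    io.write_json(block, path.with_suffix(path.suffix + ".provenance.json"))


def _thresholds(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return {k: v for k, v in d.items()
            if k not in ("genome", "annotation", "tracks_dir", "counts",
                         "samples", "outdir", "seed")}


def write_simulation(config: sd.SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate the synthetic study and write it as a file fixture."""
    outdir = Path(outdir)
    (outdir / "tracks").mkdir(parents=True, exist_ok=True)
    genome, annotation = sd.generate_reference(config)
    truth = sd.plant_truth(annotation, config)
    tracks = sd.simulate_end5_counts((genome, annotation), truth, config)
    counts, samples, truth_iso = sd.simulate_polysome_experiment(truth, config)
    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "annotation.gtf",
        "counts": outdir / "polysome_counts.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
    }
    io.write_fasta(genome, paths["genome"])
    io.write_gtf(annotation, paths["annotation"])
    io.write_table(counts.reset_index(), paths["counts"])
    io.write_table(samples, paths["samples"])
    io.write_table(truth, paths["truth"])
    for name in sorted(tracks):
        io.write_end5_bed(tracks[name], outdir / "tracks" / f"{name}.bed")
    meta = {k: (v if not isinstance(v, dict) else dict(v))
            for k, v in dataclasses.asdict(config).items() if k != "seed"}
    io.write_json(io.provenance_block(seed=config.seed, **meta),
                  outdir / "simulation.provenance.json")
    paths["tracks_dir"] = outdir / "tracks"
    return paths


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute cluster -> MRL -> features -> diffusage/de/polyshift ->
    decompose -> model on the configured inputs.

    Returns the result tables; each is also written under ``outdir``.
    Raises at the failing stage (partial outputs are retained on disk).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    genome = io.read_fasta(config.genome)
    annotation = io.load_annotation(config.annotation)
    track_files = sorted(Path(config.tracks_dir).glob("*.bed"))
    tracks = {p.stem: io.read_end5_bed(p) for p in track_files}
    counts = io.read_table(config.counts).set_index("row_id")
    samples = io.read_table(config.samples)
    conditions = sorted({name.rsplit("_rep", 1)[0] for name in tracks})
    results: dict[str, pd.DataFrame] = {}

    # --- stage: cluster ---------------------------------------------------
    stage = "cluster"
    analyses = {
        cond: tc.pool_tracks({k: v for k, v in tracks.items()
                              if k.rsplit("_rep", 1)[0] == cond})
        for cond in conditions
    }
    clusters = tc.cluster_tss(
        tracks, annotation, genome, analyses=analyses,
        min_stability=config.min_stability, min_count=config.min_count,
        max_length=config.max_length, min_separation=config.min_separation,
        min_rel_height=config.min_rel_height, g_threshold=config.g_threshold,
        minor_max_relative=config.minor_max_relative,
    )
    cl_frame = tc.clusters_to_frame(clusters)
    results["clusters"] = cl_frame
    _write(cl_frame, outdir / "clusters.tsv", config, stage)

    # --- stage: mrl -------------------------------------------------------
    stage = "mrl"
    mrna, spikes = qt.split_spike_rows(counts, config.spike_prefix)
    factors = qt.spikein_size_factors(spikes)
    norm = qt.normalize_counts(counts, factors)
    kept = qt.filter_low_abundance(mrna, config.low_count, config.low_count_samples)
    iso_mrl = qt.mrl_table(norm.loc[kept], samples)
    iso_gene = pd.Series({i: i.rsplit(".", 1)[0] for i in kept})
    gene_norm = qt.gene_level_profile(norm.loc[kept], iso_gene)
    gene_mrl = qt.mrl_table(gene_norm, samples)
    results["isoform_mrl"] = iso_mrl.reset_index()
    results["gene_mrl"] = gene_mrl.reset_index()
    _write(results["isoform_mrl"], outdir / "isoform_mrl.tsv", config, stage)
    _write(results["gene_mrl"], outdir / "gene_mrl.tsv", config, stage)

    # --- stage: features --------------------------------------------------
    stage = "features"
    feats = ft.compute_feature_table(clusters, annotation, genome)
    results["features"] = feats
    _write(feats, outdir / "features.tsv", config, stage)

    # --- stage: diffusage -------------------------------------------------
    stage = "diffusage"
    tss_counts = _cluster_sample_counts(clusters, tracks)
    tss_gene = pd.Series({c.cluster_id: c.gene_id for c in clusters
                          if c.gene_id is not None})
    cond_of = pd.Series({s: s.rsplit("_rep", 1)[0] for s in tss_counts.columns})
    kept_tss, _ = dif.prefilter_usage(tss_counts.loc[tss_gene.index], tss_gene)
    gene_tab, tss_tab = dif.test_usage_all(
        tss_counts.loc[kept_tss], tss_gene, cond_of
    )
    if len(tss_tab):
        gene_p = gene_tab.set_index("gene_id")["p_gene"]
        tss_p = tss_tab.set_index("tss_id")["p_tss"]
        tg = tss_tab.set_index("tss_id")["gene_id"]
        gene_q, tss_q = dif.stagewise_adjust(gene_p, tss_p, tg, config.fdr)
        tss_tab["q"] = tss_q.reindex(tss_tab["tss_id"]).to_numpy()
        shrunk, sd_post = dif.shrink_log2fc(
            tss_tab.set_index("tss_id")["log2fc"], tss_tab.set_index("tss_id")["se"]
        )
        tss_tab["shrunk_lfc"] = shrunk.reindex(tss_tab["tss_id"]).to_numpy()
        tss_tab["shrunk_sd"] = sd_post.reindex(tss_tab["tss_id"]).to_numpy()
        gene_tab["q_gene"] = gene_q.reindex(gene_tab["gene_id"]).to_numpy()
        alt = dif.select_alternative_tss(tss_tab, fdr=config.fdr)
    else:
        alt = pd.DataFrame()
    results["usage_genes"], results["usage_tss"], results["alt_tss"] = gene_tab, tss_tab, alt
    _write(gene_tab, outdir / "usage_genes.tsv", config, stage)
    _write(tss_tab, outdir / "usage_tss.tsv", config, stage)
    _write(alt, outdir / "alternative_tss.tsv", config, stage)

    # --- stage: de --------------------------------------------------------
    stage = "de"
    gene_counts = tss_counts.groupby(
        pd.Series({c.cluster_id: c.gene_id or "unassigned" for c in clusters})
    ).sum()
    de = dif.test_differential_expression(gene_counts, cond_of, fdr=config.fdr)
    results["de"] = de.reset_index(names="gene_id")
    _write(results["de"], outdir / "differential_expression.tsv", config, stage)

    # --- stage: polyshift -------------------------------------------------
    stage = "polyshift"
    gene_frac = mrna.groupby(
        pd.Series({i: i.rsplit(".", 1)[0] for i in mrna.index})
    ).sum()
    poly = dif.test_polysome_shift(gene_frac, samples, fdr=config.fdr)
    results["polyshift"] = poly.reset_index()
    _write(results["polyshift"], outdir / "polysome_shift.tsv", config, stage)

    # --- stage: decompose -------------------------------------------------
    stage = "decompose"
    summary = _decomposition_summary(clusters, iso_mrl, tss_counts, cond_of, conditions)
    decomposed = dc.decompose_table(summary)
    results["decomposition"] = decomposed
    results["attribution"] = dc.attribute_mode(decomposed)
    _write(decomposed, outdir / "decomposition.tsv", config, stage)
    _write(results["attribution"], outdir / "attribution.tsv", config, stage)

    # --- stage: gam -------------------------------------------------------
    stage = "gam"
    mrl_ref = iso_mrl[conditions[0]]
    mrl_by_tx = _mrl_by_transcript(clusters, mrl_ref)
    try:
        design = gam.prepare_model_matrix(
            feats.assign(isoform_id=feats["transcript_id"]), mrl_by_tx
        )
        expr = gene_counts.sum(axis=1)
        cv = gam.cross_validate(
            design, expr, n_repeats=config.gam_repeats,
            n_holdout_chroms=config.gam_holdout_chroms, seed=config.seed,
            k=config.gam_basis,
        )
        gam_summary = pd.DataFrame(
            dict(repeat=range(1, len(cv["r2_per_repeat"]) + 1), r2=cv["r2_per_repeat"])
        )
        gam_summary.attrs["median_r2"] = cv["median_r2"]
        io.write_json(
            io.provenance_block(seed=config.seed, stage=stage,
                                median_r2=cv["median_r2"], **_thresholds(config)),
            outdir / "gam_summary.json",
        )
    except ValueError as err:
        gam_summary = pd.DataFrame()
        io.write_json(io.provenance_block(seed=config.seed, stage=stage,
                                          skipped=str(err)),
                      outdir / "gam_summary.json")
    results["gam"] = gam_summary
    _write(gam_summary, outdir / "gam_cv.tsv", config, stage)
    return results


def _cluster_sample_counts(clusters, tracks) -> pd.DataFrame:
    cols = {}
    for name in sorted(tracks):
        cols[name] = tc.cluster_abundances(clusters, {name: tracks[name]})[name]
    return pd.DataFrame(cols)


def _decomposition_summary(clusters, iso_mrl, tss_counts, cond_of, conditions):
    rows = []
    cond_a, cond_b = conditions[:2]
    samp_a = [s for s in tss_counts.columns if cond_of[s] == cond_a]
    samp_b = [s for s in tss_counts.columns if cond_of[s] == cond_b]
    for c in clusters:
        if c.gene_id is None or c.transcript_id is None:
            continue
        mrl_a = iso_mrl[cond_a].get(c.transcript_id, np.nan)
        mrl_b = iso_mrl[cond_b].get(c.transcript_id, np.nan)
        rows.append(
            dict(gene_id=c.gene_id, isoform_id=c.cluster_id,
                 mrl_a=mrl_a, mrl_b=mrl_b,
                 abundance_a=float(tss_counts.loc[c.cluster_id, samp_a].sum()),
                 abundance_b=float(tss_counts.loc[c.cluster_id, samp_b].sum()))
        )
    return pd.DataFrame(rows)


def _mrl_by_transcript(clusters, mrl_ref: pd.Series) -> pd.Series:
    out = {}
    for c in clusters:
        if c.transcript_id is not None and c.transcript_id in mrl_ref.index:
            out[c.transcript_id] = float(mrl_ref[c.transcript_id])
    return pd.Series(out)
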