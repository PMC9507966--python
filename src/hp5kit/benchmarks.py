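"""Simulation studies quantifying the toolkit's accuracy on known truth.

Each function generates data with the synthetic module (or a matched
direct construction), runs the corresponding analysis and measures the
result against the planted truth.  They back both the acceptance test
suite and ``scripts/acceptance.py``; all randomness is derived from the
single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from hp5kit import differential as dif
from hp5kit import model as gam
from hp5kit import quantification as qt
from hp5kit import tss_clustering as tc
from hp5kit.decomposition import decompose_gene, measured_log2fc_mrl
from hp5kit.synthetic_data import (
    SimConfig,
    fraction_weights,
    generate_reference,
    plant_truth,
    simulate_end5_counts,
    simulate_polysome_experiment,
)

__all__ = [
    "clustering_recovery",
    "mrl_recovery",
    "usage_null_calibration",
    "usage_power",
    "polysome_null_calibration",
    "de_performance",
    "decomposition_identity",
    "gam_noise_r2",
    "gam_calibrated_r2",
]


def _spawn(seed: int, n: int):
    return np.random.SeedSequence(seed).spawn(n)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def clustering_recovery(
    seed: int = 1, n_genes: int = 50, library_size: int = 1_000_000,
    tolerance_bp: int = 5,
) -> dict:
    """TSS recovery and artifact removal of the clustering pipeline.

    Runs the full cluster caller on a synthetic genome and reports the
    percentage of planted capped TSSs recovered within ``tolerance_bp``
    of a final cluster summit, and the percentage of planted
    internal-priming clusters removed.
    """
    config = SimConfig(n_genes=n_genes, library_size=library_size, seed=seed)
    genome, annotation = generate_reference(config)
    truth = plant_truth(annotation, config)
    tracks = simulate_end5_counts((genome, annotation), truth, config)
    analyses = {
        cond: tc.pool_tracks({k: v for k, v in tracks.items()
                              if k.rsplit("_rep", 1)[0] == cond})
        for cond in config.conditions
    }
    clusters = tc.cluster_tss(tracks, annotation, genome, analyses=analyses,
                              assign_transcripts=False)
    summits: dict[tuple, list[int]] = {}
    for c in clusters:
        summits.setdefault((c.chrom, c.strand), []).append(c.summit)

    def hit(row) -> bool:
        near = summits.get((row["chrom"], row["strand"]), [])
        return any(abs(s - row["tss"]) <= tolerance_bp for s in near)

    capped = truth[~truth["is_artifact"]]
    artifacts = truth[truth["is_artifact"]]
    recovered = capped.apply(hit, axis=1).sum()
    retained = artifacts.apply(hit, axis=1).sum()
    return dict(
        n_capped=int(len(capped)),
        n_artifacts=int(len(artifacts)),
        recovery_pct=100.0 * recovered / len(capped),
        artifact_removal_pct=100.0 * (len(artifacts) - retained) / len(artifacts),
    )


# ---------------------------------------------------------------------------
# MRL
# ---------------------------------------------------------------------------

def mrl_recovery(
    seed: int = 1, n_genes: int = 200, library_size: int = 20_000_000,
    min_reads: float = 1e4, target_isoforms: int = 500,
) -> dict:
    """Median |estimated - true| MRL for well-covered isoforms.

    Simulates the polysome experiment, runs the spike-in normalization
    and MRL estimation, and summarizes the error over isoforms with at
    least ``min_reads`` raw reads.
    """
    config = SimConfig(
        n_genes=n_genes, library_size=library_size, seed=seed,
        chrom_lengths={f"chr{i}": 250_000 for i in range(1, 9)},
    )
    _, annotation = generate_reference(config)
    truth = plant_truth(annotation, config)
    counts, samples, iso = simulate_polysome_experiment(truth, config)
    mrna, spikes = qt.split_spike_rows(counts)
    factors = qt.spikein_size_factors(spikes)
    norm = qt.normalize_counts(counts, factors)
    kept = qt.filter_low_abundance(mrna)
    mrl = qt.mrl_table(norm.loc[kept], samples)
    tr = iso.set_index("isoform_id")
    reads = mrna.loc[kept].sum(axis=1)
    covered = reads.index[reads >= min_reads]
    errs = []
    for cond in config.conditions:
        errs.append((mrl.loc[covered, cond]
                     - tr.loc[covered, f"mrl_{cond}"]).abs())
    err = pd.concat(errs)
    err = err.iloc[: 2 * target_isoforms]
    return dict(
        n_isoforms=int(len(err)),
        median_abs_error=float(err.median()),
    )


# ---------------------------------------------------------------------------
# Differential usage
# ---------------------------------------------------------------------------

def _null_usage_counts(rng, n_tss, total, concentration, n_samples=6):
    pi = 0.5 * rng.dirichlet(np.ones(n_tss)) + 0.5 / n_tss
    rows = []
    for _ in range(n_samples):
        p = rng.dirichlet(concentration * pi) if np.isfinite(concentration) else pi
        rows.append(rng.multinomial(total, p))
    return np.stack(rows, axis=1)  # TSS x samples


def usage_null_calibration(
    seed: int = 1, n_genes: int = 2000, alpha: float = 0.01,
    concentration: float = float("inf"),
) -> dict:
    """Type-I error of the gene-level usage LRT on null genes.

    Null genes have 2-4 TSSs with condition-independent proportions,
    sampled multinomially per sample as in the synthetic track generator
    (a finite ``concentration`` adds replicate-level Dirichlet noise).
    """
    rng = np.random.default_rng(_spawn(seed, 1)[0])
    cols = [f"A_rep{i}" for i in (1, 2, 3)] + [f"B_rep{i}" for i in (1, 2, 3)]
    conds = pd.Series({c: c[0] for c in cols})
    ps = []
    for _ in range(n_genes):
        k = int(rng.integers(2, 5))
        total = int(rng.integers(200, 2000))
        x = _null_usage_counts(rng, k, total, concentration)
        counts = pd.DataFrame(x, columns=cols,
                              index=[f"t{j}" for j in range(k)])
        ps.append(dif.test_usage(counts, conds).p_gene)
    ps = np.array(ps)
    return dict(
        n_genes=n_genes,
        typeI_at_alpha=float((ps < alpha).mean()),
        alpha=alpha,
        ks_uniform_p=float(stats.kstest(ps, "uniform").pvalue),
    )


def usage_power(seed: int = 1, n_reps: int = 3, gene_total: int = 1000) -> dict:
    """Gene p value for a planted 0.30 -> 0.70 usage swap (two TSSs)."""
    rng = np.random.default_rng(_spawn(seed, 1)[0])
    cols = [f"A_rep{i}" for i in range(1, n_reps + 1)] + [
        f"B_rep{i}" for i in range(1, n_reps + 1)
    ]
    conds = pd.Series({c: c[0] for c in cols})
    x = np.stack(
        [rng.multinomial(gene_total, [0.3, 0.7]) for _ in range(n_reps)]
        + [rng.multinomial(gene_total, [0.7, 0.3]) for _ in range(n_reps)],
        axis=1,
    )
    counts = pd.DataFrame(x, columns=cols, index=["t1", "t2"])
    return dict(p_gene=float(dif.test_usage(counts, conds).p_gene))


# ---------------------------------------------------------------------------
# Polysome distribution
# ---------------------------------------------------------------------------

def _polysome_cohort(rng, n_genes, shift_flags, dispersion=0.002,
                     library_factor_sd=0.15, depth=125_000):
    cols = [f"{c}_rep{r}_f{f}" for c in "AB" for r in (1, 2, 3)
            for f in range(1, 9)]
    samples = pd.DataFrame(
        [dict(sample=s, condition=s[0],
              replicate=int(s.split("_rep")[1][0]),
              fraction=int(s.split("_f")[1])) for s in cols]
    )
    w_ref = fraction_weights(4.0)
    libf = {s: rng.lognormal(0, library_factor_sd) for s in cols}
    rows = []
    for shifted in shift_flags:
        if shifted:
            mrl_a, mrl_b = 6.0, 2.0
        else:
            mrl_a = mrl_b = rng.uniform(2.0, 7.0)
        share = rng.lognormal(np.log(2e-3), 0.8)
        y = {}
        for cond, mrl in (("A", mrl_a), ("B", mrl_b)):
            w = fraction_weights(mrl)
            for rep in (1, 2, 3):
                pr = rng.dirichlet(w / dispersion) if dispersion > 0 else w
                for f in range(1, 9):
                    s = f"{cond}_rep{rep}_f{f}"
                    y[s] = rng.poisson(depth * libf[s] * share
                                       * pr[f - 1] / w_ref[f - 1])
        rows.append(y)
    return pd.DataFrame(rows, columns=cols), samples


def polysome_null_calibration(
    seed: int = 1, n_genes: int = 2000, alpha: float = 0.01
) -> dict:
    """Type-I error of the polysome fraction x condition LRT on nulls."""
    rng = np.random.default_rng(_spawn(seed, 1)[0])
    counts, samples = _polysome_cohort(rng, n_genes, [False] * n_genes)
    res = dif.test_group_fraction_interaction(
        counts, samples, dif.median_of_ratios(counts)
    )
    ps = res["p"].dropna().to_numpy()
    return dict(
        n_genes=int(len(ps)),
        typeI_at_alpha=float((ps < alpha).mean()),
        alpha=alpha,
    )


def polysome_power(seed: int = 1, n_genes: int = 200, frac_shift: float = 0.1) -> dict:
    """Detection of planted MRL 6 -> 2 shifts and their classification."""
    rng = np.random.default_rng(_spawn(seed, 1)[0])
    flags = [i < int(n_genes * frac_shift) for i in range(n_genes)]
    counts, samples = _polysome_cohort(rng, n_genes, flags)
    res = dif.test_polysome_shift(counts, samples)
    flags = np.array(flags)
    sig = (res["fdr"] < 0.1).to_numpy()
    hyper = (res["class"] == "hypersensitive").to_numpy()
    return dict(
        power=float(sig[flags].mean()),
        false_positive_rate=float(sig[~flags].mean()),
        hypersensitive_frac=float(hyper[flags].mean()),
    )


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def de_performance(
    seed: int = 1, n_null: int = 1800, n_de: int = 200,
    true_log2fc: float = 2.0, mean: float = 200.0, dispersion: float = 0.05,
) -> dict:
    """Sensitivity and empirical FDR of the NB Wald caller.

    Null genes have no change; planted genes change by ``true_log2fc``
    (both directions); three replicates per condition.
    """
    rng = np.random.default_rng(_spawn(seed, 1)[0])
    cols = [f"A_rep{i}" for i in (1, 2, 3)] + [f"B_rep{i}" for i in (1, 2, 3)]
    conds = pd.Series({c: c[0] for c in cols})

    def nb(mu, size):
        r = 1.0 / dispersion
        return rng.negative_binomial(r, r / (r + mu), size)

    mus = rng.lognormal(np.log(mean), 1.0, n_null + n_de)
    fcs = np.ones(n_null + n_de)
    fcs[n_null:] = 2.0 ** (true_log2fc * rng.choice([-1, 1], n_de))
    rows = [np.concatenate([nb(m, 3), nb(m * f, 3)]) for m, f in zip(mus, fcs)]
    counts = pd.DataFrame(rows, columns=cols,
                          index=[f"g{i}" for i in range(len(rows))])
    res = dif.test_differential_expression(counts, conds)
    called = res["call"].isin(["up", "down"]).to_numpy()
    tp = called[n_null:].sum()
    fp = called[:n_null].sum()
    return dict(
        sensitivity=float(tp / n_de),
        empirical_fdr=float(fp / max(tp + fp, 1)),
        n_called=int(tp + fp),
    )


# ---------------------------------------------------------------------------
# Decomposition
# ---------------------------------------------------------------------------

def decomposition_identity(seed: int = 1, n_genes: int = 200) -> dict:
    """Worst-case agreement of the decomposition identities on random genes.

    Checks that the measured log2 MRL change equals the gene-level change
    computed from per-fraction sums, and the antisymmetry of both
    counterfactual simulations under condition swap.
    """
    rng = np.random.default_rng(_spawn(seed, 1)[0])
    worst_measured = worst_antisym = 0.0
    for _ in range(n_genes):
        k = int(rng.integers(1, 5))
        mrl_a = rng.uniform(1.2, 7.8, k)
        mrl_b = rng.uniform(1.2, 7.8, k)
        ab_a = rng.uniform(10, 1000, k)
        ab_b = rng.uniform(10, 1000, k)
        summary = pd.DataFrame(dict(mrl_a=mrl_a, mrl_b=mrl_b,
                                    abundance_a=ab_a, abundance_b=ab_b))
        # gene-level MRL route: per-fraction sums of abundance-weighted profiles
        prof_a = np.zeros(8)
        prof_b = np.zeros(8)
        for i in range(k):
            prof_a += ab_a[i] * fraction_weights(mrl_a[i])
            prof_b += ab_b[i] * fraction_weights(mrl_b[i])
        gene_route = np.log2(qt.mean_ribosome_load(prof_b)
                             / qt.mean_ribosome_load(prof_a))
        measured = measured_log2fc_mrl(summary)
        worst_measured = max(worst_measured, abs(measured - gene_route))
        d_ab = decompose_gene(summary)
        swapped = summary.rename(columns=dict(
            mrl_a="mrl_b", mrl_b="mrl_a",
            abundance_a="abundance_b", abundance_b="abundance_a"))
        d_ba = decompose_gene(swapped)
        for key in ("measured", "omit_te", "omit_usage"):
            worst_antisym = max(worst_antisym, abs(d_ab[key] + d_ba[key]))
    return dict(
        max_identity_error=float(worst_measured),
        max_antisymmetry_error=float(worst_antisym),
        n_genes=n_genes,
    )


# ---------------------------------------------------------------------------
# Additive model
# ---------------------------------------------------------------------------

def _synthetic_feature_table(rng, n_rows, n_chroms=12):
    """Feature marginals resembling the real preprocessed design."""
    utr5 = rng.integers(20, 600, n_rows).astype(float)
    cds = rng.integers(150, 3000, n_rows).astype(float)
    table = pd.DataFrame(
        dict(
            isoform_id=[f"i{j}" for j in range(n_rows)],
            gene_id=[f"g{j}" for j in range(n_rows)],
            chrom=rng.choice([f"chr{i}" for i in range(1, n_chroms + 1)], n_rows),
            log10_utr5_length=np.log10(utr5),
            log10_cds_length=np.log10(cds),
            uorf_count=rng.poisson(0.7, n_rows).astype(float),
            kozak_score=rng.uniform(0.2, 1.0, n_rows),
            structure_cap_norm=-rng.uniform(0.0, 0.45, n_rows),
            structure_distal_norm=-rng.uniform(0.0, 0.45, n_rows),
            top_length=rng.geometric(0.45, n_rows).astype(float) - 1.0,
        )
    )
    expression = pd.Series(rng.lognormal(3.0, 1.0, n_rows),
                           index=table["gene_id"])
    return table, expression


def _additive_truth(table: pd.DataFrame) -> np.ndarray:
    """A smooth additive signal in the model's terms."""
    return (
        -0.8 * (table["log10_utr5_length"] - 2.0) ** 2
        + 0.6 * np.tanh(2.0 * (table["log10_cds_length"] - 2.8))
        - 0.5 * np.minimum(table["uorf_count"], 3.0)
        + 1.2 * table["kozak_score"]
        + 1.5 * table["structure_cap_norm"]
        - 0.8 * np.minimum(table["top_length"], 6.0) / 6.0
    ).to_numpy()


def gam_noise_r2(seed: int = 1, n_rows: int = 5000) -> dict:
    """Median held-out R^2 when the response is pure noise (should be ~0)."""
    ss = _spawn(seed, 2)
    rng = np.random.default_rng(ss[0])
    table, expression = _synthetic_feature_table(rng, n_rows)
    table["mrl"] = rng.normal(4.5, 1.0, n_rows)
    cv = gam.cross_validate(table, expression,
                            seed=int(ss[1].generate_state(1)[0] % 2**31))
    return dict(median_r2=float(cv["median_r2"]), n_rows=n_rows)


def gam_calibrated_r2(
    seed: int = 1, n_rows: int = 5000, target_r2: float = 0.36
) -> dict:
    """Median held-out R^2 with an additive truth built to explain
    ``target_r2`` of the response variance."""
    ss = _spawn(seed, 2)
    rng = np.random.default_rng(ss[0])
    table, expression = _synthetic_feature_table(rng, n_rows)
    signal = _additive_truth(table)
    signal = signal - signal.mean()
    noise_sd = float(np.std(signal) * np.sqrt((1 - target_r2) / target_r2))
    table["mrl"] = 4.5 + signal + rng.normal(0.0, noise_sd, n_rows)
    cv = gam.cross_validate(table, expression,
                            seed=int(ss[1].generate_state(1)[0] % 2**31))
    return dict(median_r2=float(cv["median_r2"]), target_r2=target_r2,
                n_rows=n_rows)
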