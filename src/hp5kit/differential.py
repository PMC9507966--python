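"""Differential analyses: TSS usage, expression, and polysome distribution.

* Differential TSS usage: per-gene Dirichlet-multinomial likelihood-ratio
  test of condition-dependent TSS proportions, per-TSS beta-binomial
  (TSS-vs-rest) tests at the gene's estimated concentration, and a
  two-stage (screen genes, confirm TSSs) adjustment targeting an overall
  FDR; the alternative TSS of a significant gene is the significant TSS
  with the largest shrunken fold change, the base TSS the most-used TSS in
  the reference condition, with stringency filters (proportional change
  > 5%, |fold change| > 1.5, non-overlapping 95% CIs).
* Differential expression: negative-binomial Wald test with
  median-of-ratios library normalization and trend-shrunken moment
  dispersions; up/down calls at FDR < 0.1 and |log2FC| > log2(1.5).
* Polysome distribution: negative-binomial likelihood-ratio test of the
  fraction x condition interaction (internal library normalization);
  significant genes are classified mTOR-hypersensitive or -resistant by
  whether their log2 change in mean ribosome load falls below or above the
  cohort median.
* Nonparametric class comparisons: Mann-Whitney U / Wilcoxon signed-rank
  with Holm adjustment and the matched-pairs rank-biserial correlation as
  the paired effect size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, psi
from statsmodels.stats.multitest import multipletests

__all__ = [
    "prefilter_usage",
    "expression_filter",
    "dirichlet_multinomial_loglik",
    "test_usage",
    "test_usage_all",
    "stagewise_adjust",
    "shrink_log2fc",
    "select_alternative_tss",
    "median_of_ratios",
    "test_differential_expression",
    "test_polysome_shift",
    "test_isoform_vs_rest",
    "test_group_fraction_interaction",
    "class_comparison",
    "UsageTestResult",
]


# ---------------------------------------------------------------------------
# Prefilter (differential TSS usage)
# ---------------------------------------------------------------------------

def prefilter_usage(
    counts: pd.DataFrame,
    tss_gene: pd.Series,
    min_samps_feature_expr: int = 2,
    min_feature_expr: float = 5.0,
    min_samps_feature_prop: int = 2,
    min_feature_prop: float = 0.05,
    min_samps_gene_expr: int = 2,
    min_gene_expr: float = 20.0,
) -> tuple[pd.Index, pd.Index]:
    """Drop very-low-abundance TSSs and genes before usage testing.

    A TSS is kept iff its count is >= min_feature_expr in at least
    min_samps_feature_expr samples AND its within-gene proportion is
    >= min_feature_prop in at least min_samps_feature_prop samples; a gene
    is kept iff its total is >= min_gene_expr in at least
    min_samps_gene_expr samples and it retains at least two TSSs.
    Returns (kept TSS index, kept gene index).
    """
    genes = tss_gene.reindex(counts.index)
    gene_tot = counts.groupby(genes).transform("sum")
    prop = counts / gene_tot.replace(0, np.nan)
    tss_ok = ((counts >= min_feature_expr).sum(axis=1) >= min_samps_feature_expr) & (
        (prop >= min_feature_prop).sum(axis=1) >= min_samps_feature_prop
    )
    gene_tot_u = counts.groupby(genes).sum()
    gene_ok = (gene_tot_u >= min_gene_expr).sum(axis=1) >= min_samps_gene_expr
    kept_tss = counts.index[tss_ok & genes.map(gene_ok).fillna(False)]
    surviving = genes.loc[kept_tss].value_counts()
    kept_genes = surviving.index[surviving >= 2]
    kept_tss = kept_tss[genes.loc[kept_tss].isin(kept_genes)]
    return kept_tss, pd.Index(sorted(kept_genes))


def expression_filter(
    gene_counts: pd.DataFrame, min_count: float = 20.0, min_samples: int = 2
) -> pd.Index:
    """Genes with >= ``min_count`` reads in more than one sample (cross-
    condition comparison sets)."""
    ok = (gene_counts >= min_count).sum(axis=1) >= min_samples
    return gene_counts.index[ok]


# ---------------------------------------------------------------------------
# Dirichlet-multinomial usage test
# ---------------------------------------------------------------------------

def dirichlet_multinomial_loglik(x: np.ndarray, alpha: np.ndarray) -> float:
    """Log likelihood of count rows ``x`` (samples x K) under DM(alpha).

    ``alpha`` may be one vector or one row per sample.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    alpha = np.broadcast_to(np.atleast_2d(alpha), x.shape)
    n = x.sum(axis=1)
    a0 = alpha.sum(axis=1)
    return float(
        (gammaln(a0) - gammaln(a0 + n)
         + (gammaln(alpha + x) - gammaln(alpha)).sum(axis=1)).sum()
    )


def _fit_dm(x: np.ndarray, groups: list[np.ndarray], x0=None, offsets=None):
    """ML fit of a DM with per-group proportions and shared concentration.

    ``groups`` lists row-index arrays; params are (K-1) logits per group
    plus log concentration.  ``offsets`` (rows x K, optional) are known
    multiplicative composition offsets per sample — e.g. relative
    sequencing depth per category when the categories were sequenced as
    separate libraries: the proportion vector of sample s in group g is
    pi_g * offsets_s renormalized.  Returns (loglik, proportions per
    group, a0, params).
    """
    x = np.asarray(x, dtype=float)
    k = x.shape[1]
    c = len(groups)
    if offsets is None:
        off = np.ones_like(x)
    else:
        off = np.asarray(offsets, dtype=float)

    def unpack(theta):
        pis = []
        for g in range(c):
            z = np.concatenate([[0.0], theta[g * (k - 1) : (g + 1) * (k - 1)]])
            z = z - z.max()
            pi = np.exp(z)
            pis.append(pi / pi.sum())
        a0 = np.exp(theta[-1])
        return pis, a0

    def negll_grad(theta):
        pis, a0 = unpack(theta)
        ll = 0.0
        grad = np.zeros_like(theta)
        for g, rows in enumerate(groups):
            xg = x[rows]
            tilted = pis[g][None, :] * off[rows]
            pis_s = tilted / tilted.sum(axis=1, keepdims=True)
            alpha = a0 * pis_s  # per-sample alphas
            ll += dirichlet_multinomial_loglik(xg, alpha)
            ng = xg.sum(axis=1)
            gal = (
                (psi(alpha.sum(axis=1)) - psi(alpha.sum(axis=1) + ng))[:, None]
                + psi(alpha + xg) - psi(alpha)
            )  # d ll / d alpha_sk
            inner = (gal * pis_s).sum(axis=1, keepdims=True)
            gz = a0 * (pis_s * (gal - inner)).sum(axis=0)
            grad[g * (k - 1) : (g + 1) * (k - 1)] += -gz[1:]
            grad[-1] += -(gal * alpha).sum()
        return -ll, grad

    if x0 is None:
        pooled = (x / off).sum(axis=0) + 0.5
        pooled /= pooled.sum()
        z0 = np.log(pooled[1:] / pooled[0])
        x0 = np.concatenate([np.tile(z0, c), [np.log(50.0)]])
    res = optimize.minimize(
        negll_grad, x0, jac=True, method="L-BFGS-B",
        bounds=[(-30, 30)] * (c * (k - 1)) + [(np.log(1e-2), np.log(1e6))],
    )
    pis, a0 = unpack(res.x)
    return -res.fun, pis, a0, res.x


@dataclass
class UsageTestResult:
    gene_id: str
    p_gene: float
    p_tss: pd.Series  # per TSS
    proportions: pd.DataFrame  # TSS x condition, pseudo-profile shrunk
    concentration: float
    log2fc: pd.Series  # per TSS raw usage log2 fold change (B vs A)
    se: pd.Series


def test_usage(
    counts: pd.DataFrame, conditions: pd.Series, gene_id: str = ""
) -> UsageTestResult:
    """Dirichlet-multinomial LRT of condition-dependent TSS usage for one gene.

    ``counts``: TSS x sample; ``conditions``: sample -> condition label
    (two conditions; the first in sorted order is the reference).  Reported
    proportions are shrunk by one uniform pseudo-count profile per
    condition.  Per-TSS p values come from TSS-vs-rest beta-binomial LRTs
    at the gene's estimated concentration.
    """
    if counts.shape[0] < 2:
        raise ValueError(f"gene {gene_id}: needs >= 2 TSSs after filtering")
    conds = sorted(conditions.unique())
    if len(conds) != 2:
        raise ValueError("exactly two conditions are required")
    x = counts.T.to_numpy(dtype=float)  # samples x K
    sample_cond = conditions.reindex(counts.columns)
    groups = [np.flatnonzero((sample_cond == c).to_numpy()) for c in conds]
    if min(len(g) for g in groups) < 2:
        raise ValueError("needs >= 2 replicates per condition")

    ll0, _, _, theta0 = _fit_dm(x, [np.arange(x.shape[0])])
    k = x.shape[1]
    warm = np.concatenate([np.tile(theta0[: k - 1], 2), [theta0[-1]]])
    ll1, pis, a0, _ = _fit_dm(x, groups, x0=warm)
    lrt = max(0.0, 2.0 * (ll1 - ll0))
    df = k - 1
    p_gene = float(stats.chi2.sf(lrt, df))

    # pseudo-profile-shrunk proportions and usage fold changes
    prop = {}
    for c, rows in zip(conds, groups):
        tot = x[rows].sum(axis=0)
        prop[c] = (tot + 1.0) / (tot.sum() + k)
    proportions = pd.DataFrame(prop, index=counts.index)
    log2fc = np.log2(proportions[conds[1]] / proportions[conds[0]])
    # delta-method SE on log usage with the DM design effect
    se = {}
    for tss in counts.index:
        parts = []
        for c, rows in zip(conds, groups):
            n_c = x[rows].sum()
            pi = proportions.loc[tss, c]
            deff = 1.0 + (x[rows].sum(axis=1).mean() - 1.0) / (a0 + 1.0)
            parts.append(deff * (1.0 - pi) / max(pi * n_c, 1e-9))
        se[tss] = float(np.sqrt(sum(parts)) / np.log(2))
    se = pd.Series(se)

    p_tss = {}
    for j, tss in enumerate(counts.index):
        x2 = np.stack([x[:, j], x.sum(axis=1) - x[:, j]], axis=1)
        l0 = _fit_bb_fixed_conc(x2, [np.arange(x.shape[0])], a0)
        l1 = _fit_bb_fixed_conc(x2, groups, a0)
        p_tss[tss] = float(stats.chi2.sf(max(0.0, 2 * (l1 - l0)), 1))
    return UsageTestResult(
        gene_id=gene_id, p_gene=p_gene, p_tss=pd.Series(p_tss),
        proportions=proportions, concentration=a0,
        log2fc=log2fc, se=se,
    )


def _fit_bb_fixed_conc(x2: np.ndarray, groups, a0: float) -> float:
    """Profile loglik of a 2-category DM with fixed concentration."""
    ll = 0.0
    for rows in groups:
        xg = x2[rows]

        def nll(logitp):
            p = 1.0 / (1.0 + np.exp(-logitp))
            return -dirichlet_multinomial_loglik(xg, a0 * np.array([p, 1 - p]))

        res = optimize.minimize_scalar(nll, bounds=(-30, 30), method="bounded")
        ll -= res.fun
    return ll


def test_usage_all(
    counts: pd.DataFrame, tss_gene: pd.Series, conditions: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the usage LRT on every gene; returns (gene table, TSS table).

    Degenerate genes (a single TSS after filtering) are skipped with a
    reason in the gene table.
    """
    genes = tss_gene.reindex(counts.index)
    gene_rows, tss_rows = [], []
    for gid, idx in counts.groupby(genes, sort=True).groups.items():
        sub = counts.loc[idx]
        if sub.shape[0] < 2:
            gene_rows.append(dict(gene_id=gid, p_gene=np.nan, skipped="single TSS"))
            continue
        r = test_usage(sub, conditions, gene_id=str(gid))
        gene_rows.append(dict(gene_id=gid, p_gene=r.p_gene,
                              concentration=r.concentration, skipped=""))
        conds = sorted(conditions.unique())
        for tss in sub.index:
            tss_rows.append(
                dict(tss_id=tss, gene_id=gid, p_tss=r.p_tss[tss],
                     log2fc=r.log2fc[tss], se=r.se[tss],
                     prop_ref=r.proportions.loc[tss, conds[0]],
                     prop_alt=r.proportions.loc[tss, conds[1]])
            )
    return pd.DataFrame(gene_rows), pd.DataFrame(tss_rows)


# ---------------------------------------------------------------------------
# Stagewise (two-stage) FDR
# ---------------------------------------------------------------------------

def stagewise_adjust(
    gene_p: pd.Series, tss_p: pd.Series, tss_gene: pd.Series,
    target_ofdr: float = 0.1,
) -> tuple[pd.Series, pd.Series]:
    """Screen genes by BH, confirm TSSs within screened genes.

    Stage 1 BH-adjusts the gene p values at ``target_ofdr``; stage 2
    Holm-adjusts the TSS p values within each screened gene and scales by
    the screening fraction (m / n_screened).  TSSs of non-screened genes
    get q = 1.  Returns (gene q, TSS q); TSS q is never below its gene q.
    """
    valid = gene_p.dropna()
    gene_q = pd.Series(1.0, index=gene_p.index)
    if len(valid):
        gene_q.loc[valid.index] = multipletests(valid, method="fdr_bh")[1]
    screened = gene_q.index[gene_q <= target_ofdr]
    m, r = len(valid), len(screened)
    tss_q = pd.Series(1.0, index=tss_p.index)
    genes = tss_gene.reindex(tss_p.index)
    for gid in screened:
        idx = tss_p.index[genes == gid]
        if not len(idx):
            continue
        holm = multipletests(tss_p.loc[idx], method="holm")[1]
        q = np.minimum(1.0, holm * m / max(r, 1))
        tss_q.loc[idx] = np.maximum(q, gene_q[gid])
    return gene_q, tss_q


# ---------------------------------------------------------------------------
# Fold-change shrinkage and alternative-TSS selection
# ---------------------------------------------------------------------------

def shrink_log2fc(fc: pd.Series, se: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Empirical-Bayes normal shrinkage of log2 fold changes.

    The zero-centred normal prior scale is fit by marginal likelihood
    across features; posterior means are conservative (never exceed the raw
    estimate in magnitude).  Returns (shrunken fc, posterior sd).
    """
    fc_v = fc.to_numpy(dtype=float)
    se_v = np.maximum(se.to_numpy(dtype=float), 1e-6)

    def negll(log_tau):
        v = np.exp(2 * log_tau) + se_v**2
        return 0.5 * np.sum(np.log(v) + fc_v**2 / v)

    res = optimize.minimize_scalar(negll, bounds=(-10, 5), method="bounded")
    tau2 = float(np.exp(2 * res.x))
    w = tau2 / (tau2 + se_v**2)
    post = fc_v * w
    post_sd = np.sqrt(tau2 * se_v**2 / (tau2 + se_v**2))
    return pd.Series(post, index=fc.index), pd.Series(post_sd, index=fc.index)


def select_alternative_tss(
    tss_table: pd.DataFrame,
    fdr: float = 0.1,
    min_prop_change: float = 0.05,
    min_fold_change: float = 1.5,
) -> pd.DataFrame:
    """Per-gene alternative and base TSS with stringency flag.

    ``tss_table`` needs columns tss_id, gene_id, q, shrunk_lfc, shrunk_sd,
    prop_ref, prop_alt.  The alternative TSS is the significant TSS with
    the largest |shrunken log2FC| (ties -> smaller q, then 5'-most by
    table order); the base TSS has the highest usage in the reference
    condition.  The stringency flag requires a proportional change
    strictly > ``min_prop_change``, |FC| strictly > ``min_fold_change``
    and non-overlapping 95% CIs of alternative and base fold changes.
    """
    out = []
    for gid, sub in tss_table.groupby("gene_id", sort=True):
        sig = sub[sub["q"] < fdr]
        if sig.empty:
            continue
        order = sig.assign(_mag=sig["shrunk_lfc"].abs(), _row=np.arange(len(sig)))
        alt = order.sort_values(["_mag", "q", "_row"],
                                ascending=[False, True, True]).iloc[0]
        base_order = sub.sort_values("prop_ref", ascending=False)
        base = base_order.iloc[0]
        note = ""
        if base["tss_id"] == alt["tss_id"] and len(base_order) > 1:
            base = base_order.iloc[1]
            note = "base reassigned to next-highest"
        ci = lambda r: (r["shrunk_lfc"] - 1.96 * r["shrunk_sd"],
                        r["shrunk_lfc"] + 1.96 * r["shrunk_sd"])  # noqa: E731
        a_lo, a_hi = ci(alt)
        b_lo, b_hi = ci(base)
        dprop = abs(alt["prop_alt"] - alt["prop_ref"])
        stringent = (
            dprop > min_prop_change
            and abs(alt["shrunk_lfc"]) > np.log2(min_fold_change)
            and (a_hi < b_lo or b_hi < a_lo)
        )
        out.append(
            dict(gene_id=gid, alternative_tss=alt["tss_id"], base_tss=base["tss_id"],
                 alt_log2fc=alt["shrunk_lfc"], alt_q=alt["q"],
                 prop_change=dprop, passes_stringency=bool(stringent), note=note)
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Negative-binomial differential expression
# ---------------------------------------------------------------------------

def median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Internal library size factors (median-of-ratios over all rows)."""
    mat = counts.to_numpy(dtype=float)
    pos = (mat > 0).all(axis=1)
    if not pos.any():
        raise ValueError("no row with nonzero counts in all samples")
    logref = np.log(mat[pos]).mean(axis=1)
    sf = np.median(mat[pos] / np.exp(logref)[:, None], axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _moment_dispersions(
    norm: pd.DataFrame,
    groups: list[np.ndarray],
    size_factors: np.ndarray | None = None,
    prior_df: float = 8.0,
) -> pd.Series:
    """Per-gene moment estimate of the NB dispersion, shrunk to a trend.

    On the normalized scale a count y_s = sf_s * q has variance
    q / sf_s + alpha * q^2, so the Poisson (shot-noise) part subtracted
    from the within-group sum of squares must account for the size
    factors.  Raw estimates are shrunk toward a fitted
    ``alpha(mu) = a1/mu + a0`` trend with ``prior_df`` pseudo-degrees of
    freedom, the usual few-replicates stabilization.
    """
    y = norm.to_numpy(dtype=float)
    sf = np.ones(y.shape[1]) if size_factors is None else np.asarray(size_factors, float)
    num = np.zeros(len(y))
    den = np.zeros(len(y))
    dof, mu_all, wsum = 0, np.zeros(len(y)), 0.0
    for rows in groups:
        n = len(rows)
        if n < 2:
            continue
        sub = y[:, rows]
        q = sub.mean(axis=1)
        dev2 = ((sub - q[:, None]) ** 2).sum(axis=1)
        shot = (1.0 - 1.0 / n) * q * (1.0 / sf[rows]).sum()
        num += dev2 - shot
        den += (1.0 - 1.0 / n) * n * q**2
        dof += n - 1
        mu_all += q * n
        wsum += n
    mu_all /= max(wsum, 1.0)
    raw = np.clip(num / np.maximum(den, 1e-12), 0.0, 10.0)
    ok = mu_all > 1.0
    if ok.sum() >= 10:
        A = np.stack([1.0 / mu_all[ok], np.ones(ok.sum())], axis=1)
        coef, _ = optimize.nnls(A, raw[ok])
        trend = np.maximum(coef[0] / np.maximum(mu_all, 1e-8) + coef[1], 1e-8)
    else:
        trend = np.full(len(y), max(float(np.median(raw)), 1e-8))
    w = dof / (dof + prior_df)
    alpha = np.maximum(w * raw + (1 - w) * trend, 1e-8)
    return pd.Series(alpha, index=norm.index)


def test_differential_expression(
    counts: pd.DataFrame,
    conditions: pd.Series,
    fdr: float = 0.1,
    fold_change: float = 1.5,
) -> pd.DataFrame:
    """NB Wald test per gene; calls at FDR < ``fdr`` and |log2FC| strictly
    greater than log2(``fold_change``).

    Returns a table with log2fc, se, p, padj and the up/down call; genes
    with all-zero counts are skipped.
    """
    conds = sorted(conditions.unique())
    if len(conds) != 2:
        raise ValueError("exactly two conditions are required")
    nonzero = counts.sum(axis=1) > 0
    skipped = counts.index[~nonzero]
    counts = counts.loc[nonzero]
    sf = median_of_ratios(counts)
    norm = counts / sf
    sample_cond = conditions.reindex(counts.columns)
    groups = [np.flatnonzero((sample_cond == c).to_numpy()) for c in conds]
    alpha = _moment_dispersions(norm, groups, sf.to_numpy())

    y = norm.to_numpy(dtype=float)
    mu_a = y[:, groups[0]].mean(axis=1)
    mu_b = y[:, groups[1]].mean(axis=1)
    floor = 0.25
    lfc = np.log2(np.maximum(mu_b, floor) / np.maximum(mu_a, floor))
    a = alpha.to_numpy()
    var_log = (
        (1.0 / np.maximum(mu_a, floor) + a) / len(groups[0])
        + (1.0 / np.maximum(mu_b, floor) + a) / len(groups[1])
    )
    se = np.sqrt(var_log) / np.log(2)
    z = lfc / se
    p = 2 * stats.norm.sf(np.abs(z))
    padj = multipletests(p, method="fdr_bh")[1]
    call = np.where(
        (padj < fdr) & (np.abs(lfc) > np.log2(fold_change)),
        np.where(lfc > 0, "up", "down"),
        "ns",
    )
    res = pd.DataFrame(
        dict(log2fc=lfc, se=se, p=p, padj=padj, call=call,
             base_mean=(mu_a + mu_b) / 2, dispersion=a),
        index=counts.index,
    )
    if len(skipped):
        res = pd.concat(
            [res, pd.DataFrame({"call": ["skipped"] * len(skipped)}, index=skipped)]
        )
    return res


# ---------------------------------------------------------------------------
# Polysome-distribution LRT
# ---------------------------------------------------------------------------

def _nb_loglik(y, mu, alpha):
    """NB log likelihood; ``alpha`` may be scalar or per-observation."""
    mu = np.maximum(mu, 1e-8)
    r = 1.0 / np.maximum(np.asarray(alpha, dtype=float), 1e-10)
    return float(
        (gammaln(y + r) - gammaln(r) - gammaln(y + 1)
         + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))).sum()
    )


def _fit_cell_means(y, sf, cell, n_cells):
    """Per-cell mean of sf-normalized counts (the Poisson MLE of a
    saturated cell-mean model with sample offsets)."""
    mu = np.zeros(n_cells)
    for c in range(n_cells):
        rows = cell == c
        if rows.any() and sf[rows].sum() > 0:
            mu[c] = y[rows].sum() / sf[rows].sum()
    return mu


def _fit_product_model(y, sf, frac, grp, n_frac, n_grp, n_iter=60):
    """mu = sf * beta_fraction * gamma_group by iterative proportional
    fitting (the Poisson MLE of the main-effects model)."""
    beta, gamma = np.ones(n_frac), np.ones(n_grp)
    for _ in range(n_iter):
        for f in range(n_frac):
            rows = frac == f
            d = (sf[rows] * gamma[grp[rows]]).sum()
            beta[f] = y[rows].sum() / d if d > 0 else 0.0
        for g in range(n_grp):
            rows = grp == g
            d = (sf[rows] * beta[frac[rows]]).sum()
            gamma[g] = y[rows].sum() / d if d > 0 else 0.0
    return sf * beta[frac] * gamma[grp]


def test_group_fraction_interaction(
    counts: pd.DataFrame, samples: pd.DataFrame, size_factors: pd.Series,
    group_col: str = "condition",
    dispersion_shrink: float = 0.5,
) -> pd.DataFrame:
    """NB LRT of the ``group x fraction`` interaction, one row per gene.

    The null model has fraction and group main effects (overall abundance
    changes do not register); the full model has free (group, fraction)
    cell means.  Replicate noise of a polysome profile acts on the
    *proportion* scale, so the NB dispersion of a cell is structured as
    ``alpha_gf = a_g / share_gf``: relative variability is largest in the
    fractions carrying the smallest share of the gene's mRNA.  The
    per-gene proportion-dispersion ``a_g`` is a moment estimate shrunk
    toward the cohort median (weight ``1 - dispersion_shrink``).
    df = (n_fractions - 1) * (n_groups - 1).
    """
    meta = samples.set_index("sample").loc[counts.columns]
    frac_lab = sorted(meta["fraction"].unique())
    grp_lab = sorted(meta[group_col].unique())
    nf, ng = len(frac_lab), len(grp_lab)
    frac = meta["fraction"].map({f: i for i, f in enumerate(frac_lab)}).to_numpy()
    grp = meta[group_col].map({g: i for i, g in enumerate(grp_lab)}).to_numpy()
    cell = grp * nf + frac
    sf = size_factors.reindex(counts.columns).to_numpy(dtype=float)
    norm = counts.to_numpy(dtype=float) / sf
    df = (nf - 1) * (ng - 1)
    resid_dof = len(counts.columns) - nf * ng
    has_all = len(np.unique(cell)) == nf * ng

    # pass 1: per-gene fraction shares and raw proportion-dispersions
    shares, raw_a, valid = [], [], []
    for i in range(len(counts)):
        q = norm[i]
        pi = np.array([q[cell == c].mean() if (cell == c).any() else 0.0
                       for c in range(nf * ng)])
        share = pi.reshape(ng, nf)
        tot = share.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            share = np.where(tot > 0, share / tot, np.nan)
        pif = share.reshape(-1)[cell]
        num = den = 0.0
        for c in range(nf * ng):
            rows = np.flatnonzero(cell == c)
            if len(rows) < 2:
                continue
            sub = q[rows]
            mu_ = sub.mean()
            dev2 = ((sub - mu_) ** 2).sum()
            shot = (1 - 1 / len(rows)) * mu_ * (1.0 / sf[rows]).sum()
            num += (dev2 - shot) * pif[rows[0]]
            den += (1 - 1 / len(rows)) * len(rows) * mu_**2
        shares.append(pif)
        raw_a.append(num / den if den > 0 else np.nan)
        valid.append(has_all and counts.iloc[i].sum() > 0
                     and np.isfinite(pif).all())
    raw_a = np.array(raw_a, dtype=float)
    finite = raw_a[np.isfinite(raw_a)]
    a_cohort = float(np.median(np.clip(finite, 0, None))) if len(finite) else 0.0

    rows_out = []
    for i, gene in enumerate(counts.index):
        if not valid[i]:
            reason = "missing fractions" if not has_all else "no data"
            rows_out.append(dict(gene_id=gene, lrt=np.nan, p=np.nan,
                                 skipped=reason))
            continue
        y = counts.iloc[i].to_numpy(dtype=float)
        a_raw = raw_a[i] if np.isfinite(raw_a[i]) else a_cohort
        a = max(dispersion_shrink * max(a_raw, 0.0)
                + (1 - dispersion_shrink) * a_cohort, 1e-8)
        alpha = a / np.maximum(shares[i], 1e-4)
        mu_full = sf * _fit_cell_means(y, sf, cell, nf * ng)[cell]
        mu_null = _fit_product_model(y, sf, frac, grp, nf, ng)
        lrt = max(0.0, 2 * (_nb_loglik(y, mu_full, alpha)
                            - _nb_loglik(y, mu_null, alpha)))
        # F reference (LRT/df vs residual dof) accounts for the estimated
        # dispersions at few replicates, where the chi2 tail is too light
        p = float(stats.f.sf(lrt / df, df, resid_dof)) if resid_dof > 0 else \
            float(stats.chi2.sf(lrt, df))
        rows_out.append(dict(gene_id=gene, lrt=lrt, p=p, skipped=""))
    out = pd.DataFrame(rows_out).set_index("gene_id")
    ok = out["p"].notna()
    out["fdr"] = np.nan
    if ok.any():
        out.loc[ok, "fdr"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def test_isoform_vs_rest(
    iso_counts: pd.DataFrame,
    rest_counts: pd.DataFrame,
    samples: pd.DataFrame,
    size_factors: pd.Series,
) -> pd.DataFrame:
    """Polysome-distribution LRT of isoforms against the rest of their gene.

    ``iso_counts``/``rest_counts``: isoform x fraction-sample matrices with
    matching rows (the rest row is the sum of the gene's other isoforms).
    Each physical sample contributes an isoform and a rest column sharing
    its size factor; the test is the fraction x part interaction, i.e.
    whether the isoform's polysome distribution differs from its gene's.
    Combine with :func:`stagewise_adjust` for overall-FDR control across
    genes and isoforms.
    """
    if not iso_counts.index.equals(rest_counts.index):
        raise ValueError("isoform and rest matrices must share rows")
    meta = samples.set_index("sample").loc[iso_counts.columns]
    combined = pd.concat(
        [iso_counts.rename(columns=lambda s: f"iso::{s}"),
         rest_counts.rename(columns=lambda s: f"rest::{s}")], axis=1
    )
    rows = []
    for part in ("iso", "rest"):
        for s in iso_counts.columns:
            rows.append(dict(sample=f"{part}::{s}", part=part,
                             replicate=meta.loc[s, "replicate"],
                             fraction=meta.loc[s, "fraction"]))
    meta2 = pd.DataFrame(rows)
    sf2 = pd.Series(
        {f"{part}::{s}": float(size_factors[s])
         for part in ("iso", "rest") for s in iso_counts.columns}
    )
    return test_group_fraction_interaction(combined, meta2, sf2, group_col="part")


def test_polysome_shift(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Differential polysome distribution between two conditions, per gene.

    Uses internal (not spike-in) median-of-ratios normalization, the
    fraction x condition NB LRT, and classifies significant genes as
    ``hypersensitive`` or ``resistant`` by whether their log2 change in
    mean ribosome load is below or above the median over all genes tested.
    """
    from hp5kit.quantification import mrl_table

    sf = median_of_ratios(counts)
    res = test_group_fraction_interaction(counts, samples, sf)
    mrl = mrl_table(counts / sf, samples)
    conds = sorted(samples["condition"].unique())
    d_mrl = np.log2(mrl[conds[1]] / mrl[conds[0]]).reindex(res.index)
    med = float(d_mrl.median())
    res["log2_delta_mrl"] = d_mrl
    res["class"] = "unclassified"
    sig = res["fdr"] < fdr
    res.loc[sig & (d_mrl < med), "class"] = "hypersensitive"
    res.loc[sig & (d_mrl >= med), "class"] = "resistant"
    return res


# ---------------------------------------------------------------------------
# Nonparametric class comparisons
# ---------------------------------------------------------------------------

def matched_pairs_rank_biserial(x: np.ndarray, y: np.ndarray) -> float:
    """Matched-pairs rank-biserial correlation r = (W+ - W-)/(W+ + W-)."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        return 0.0
    ranks = stats.rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    w_neg = ranks[d < 0].sum()
    return float((w_pos - w_neg) / (w_pos + w_neg))


def class_comparison(
    values: dict[str, np.ndarray],
    reference: str | None = None,
    paired: bool = False,
) -> pd.DataFrame:
    """Per-class two-sided tests vs a reference class (or the rest), with
    Holm adjustment across the family.

    Unpaired classes use the Mann-Whitney U test; ``paired=True`` uses the
    Wilcoxon signed-rank test on (class, reference) value pairs and reports
    the matched-pairs rank-biserial correlation as effect size.  Classes
    with fewer than two values are skipped.
    """
    names = [k for k in values if k != reference]
    rows = []
    for name in names:
        v = np.asarray(values[name], dtype=float)
        if reference is not None:
            other = np.asarray(values[reference], dtype=float)
        else:
            other = np.concatenate([np.asarray(values[k], float)
                                    for k in values if k != name])
        if len(v) < 2 or len(other) < 2:
            rows.append(dict(**{"class": name}, p=np.nan, effect_size=np.nan,
                             skipped="class size < 2"))
            continue
        if paired:
            if len(v) != len(other):
                raise ValueError("paired comparison needs equal-length pairs")
            diffs = v - other
            if np.all(diffs == 0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(v, other).pvalue)
            eff = matched_pairs_rank_biserial(v, other)
        else:
            p = float(stats.mannwhitneyu(v, other, alternative="two-sided").pvalue)
            n1, n2 = len(v), len(other)
            u = stats.mannwhitneyu(v, other, alternative="two-sided").statistic
            eff = float(2 * u / (n1 * n2) - 1)  # rank-biserial (unpaired)
        rows.append(dict(**{"class": name}, p=p, effect_size=eff, skipped=""))
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["p_holm"] = np.nan
    if ok.any():
        out.loc[ok, "p_holm"] = multipletests(out.loc[ok, "p"], method="holm")[1]
    return out
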