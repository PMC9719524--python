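"""Population structure: strict autosomal filtering, PCA, F_ST, Nei distance
and a two-level (allele-within-individual-within-cluster) AMOVA.

Cluster-level divergence uses the Weir & Cockerham (1984) F_ST estimator
(multi-locus ratio of sums of the a/b/c variance components) and Nei's (1972)
standard genetic distance D = -ln(J_xy / sqrt(J_x * J_y)).  Individual-level
distance is 1 minus the mean proportion of shared alleles across co-called
loci.

The AMOVA treats each individual as two allele vectors (0/1 per locus) with
squared-Euclidean (mismatch-count) distances and three strata: between
clusters, between individuals within clusters, within individuals.  Variance
components follow the method-of-moments equations; significance is assessed
by permutation (individuals across clusters for the between-cluster
component, alleles among individuals within clusters for the
between-individuals component).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import HET, HOM_ALT, HOM_REF, MISSING, SnpMatrix


@dataclass
class PcaResult:
    scores: pd.DataFrame              # samples x components
    explained_variance_ratio: np.ndarray


@dataclass
class AmovaResult:
    table: pd.DataFrame   # rows: between_clusters, between_samples_within_clusters,
    #                       within_samples, total; columns: df, sum_sq, mean_sq,
    #                       sigma, sigma_raw, percent_variance
    p_between_clusters: Optional[float]
    p_within: Optional[float]


def filter_autosomal_strict(snp: SnpMatrix, sexlink_ids: Sequence) -> SnpMatrix:
    """Drop sex-linked loci, then keep only loci with perfect call rate and
    perfect reproducibility (call_rate == 1.0 recomputed, rep_avg == 1.0)."""
    sexlink = set(map(str, sexlink_ids))
    keep = np.array([str(l) not in sexlink for l in snp.locus_ids])
    keep &= snp.call_rate() == 1.0
    if "rep_avg" in snp.meta.columns:
        keep &= snp.meta["rep_avg"].to_numpy(dtype=float) == 1.0
    else:
        warnings.warn("no RepAvg metadata; reproducibility filter skipped")
    out = snp.subset_loci(snp.locus_ids[keep])
    if out.n_loci == 0:
        raise ValueError(
            "strict autosomal filter removed every locus; relax the "
            "call-rate/reproducibility requirement or check the input"
        )
    return out


def _imputed_centered_dosage(snp: SnpMatrix) -> np.ndarray:
    """Samples x loci dosage with per-locus mean imputation and centering."""
    d = snp.dosage().T  # samples x loci
    mu = np.nanmean(d, axis=0, keepdims=True)
    d = np.where(np.isnan(d), mu, d)
    d = np.nan_to_num(d - np.nanmean(d, axis=0, keepdims=True))
    return d


def pca_scores(snp: SnpMatrix, n_components: int = 10) -> PcaResult:
    """PCA of mean-imputed, centred allele dosages (samples as observations)."""
    if snp.n_samples < 2 or snp.n_loci < 2:
        raise ValueError("PCA needs at least 2 samples and 2 loci")
    d = _imputed_centered_dosage(snp)
    if np.allclose(d, 0.0):
        raise ValueError("constant genotype matrix; PCA undefined")
    k = min(n_components, snp.n_samples - 1, snp.n_loci)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(d)
    cols = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=list(snp.sample_ids), columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def _allele_counts_by_group(snp: SnpMatrix, labels: np.ndarray):
    """Per group: called sample counts, alt-allele freqs, het freqs (loci arrays)."""
    labels = np.asarray(labels)
    groups = [g for g in pd.unique(labels) if not pd.isna(g)]
    ns, ps, hs = [], [], []
    for g in groups:
        sel = labels == g
        calls = snp.calls[:, sel]
        called = calls != MISSING
        n = called.sum(axis=1).astype(float)
        het = (calls == HET).sum(axis=1)
        alt = (calls == HOM_ALT).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = (2 * alt + het) / (2 * n)
            h = het / n
        ns.append(n)
        ps.append(p)
        hs.append(h)
    return groups, np.array(ns), np.array(ps), np.array(hs)


def _wc_components(n: np.ndarray, p: np.ndarray, h: np.ndarray):
    """Weir–Cockerham per-locus a, b, c for r groups (arrays: groups x loci)."""
    r = n.shape[0]
    nbar = n.mean(axis=0)
    nsum = n.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (nsum - (n**2).sum(axis=0) / nsum) / (r - 1)
        pbar = (n * p).sum(axis=0) / nsum
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / nsum
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
    return a, b, c


def pairwise_fst(snp: SnpMatrix, labels) -> pd.DataFrame:
    """Weir–Cockerham multi-locus F_ST for every cluster pair.

    The estimate is the ratio of sums sum(a) / sum(a + b + c) over loci that
    are usable in both clusters (called in >= 2 samples per cluster and not
    entirely monomorphic across the pair).
    """
    groups, n, p, h = _allele_counts_by_group(snp, np.asarray(labels))
    if len(groups) < 2:
        raise ValueError("need at least two clusters")
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            ni, pi, hi = n[[i, j]], p[[i, j]], h[[i, j]]
            usable = (ni >= 2).all(axis=0) & ~np.isnan(pi).any(axis=0)
            poly = ~((pi == 0).all(axis=0) | (pi == 1).all(axis=0))
            usable &= poly
            if not usable.any():
                warnings.warn("no polymorphic loci usable for F_ST; undefined")
                fst = np.nan
            else:
                a, b, c = _wc_components(ni[:, usable], pi[:, usable], hi[:, usable])
                denom = np.nansum(a + b + c)
                fst = float(np.nansum(a) / denom) if denom != 0 else np.nan
            rows.append({"cluster_a": groups[i], "cluster_b": groups[j],
                         "fst": fst, "n_loci_used": int(usable.sum())})
    return pd.DataFrame(rows)


def nei_distance_from_frequencies(p_x: np.ndarray, p_y: np.ndarray) -> float:
    """Nei (1972) standard distance from per-locus alt-allele frequencies."""
    p_x, p_y = np.asarray(p_x, dtype=float), np.asarray(p_y, dtype=float)
    ok = ~(np.isnan(p_x) | np.isnan(p_y))
    p_x, p_y = p_x[ok], p_y[ok]
    if p_x.size == 0:
        raise ValueError("no co-typed loci for Nei distance")
    jx = np.mean(p_x**2 + (1 - p_x) ** 2)
    jy = np.mean(p_y**2 + (1 - p_y) ** 2)
    jxy = np.mean(p_x * p_y + (1 - p_x) * (1 - p_y))
    return float(-np.log(jxy / np.sqrt(jx * jy)))


def nei_distance(snp: SnpMatrix, labels) -> pd.DataFrame:
    """Nei standard distance for every cluster pair."""
    groups, n, p, h = _allele_counts_by_group(snp, np.asarray(labels))
    if len(groups) < 2:
        raise ValueError("need at least two clusters")
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append({
                "cluster_a": groups[i], "cluster_b": groups[j],
                "nei_d": nei_distance_from_frequencies(p[i], p[j]),
            })
    return pd.DataFrame(rows)


def allele_sharing_distance(snp: SnpMatrix) -> np.ndarray:
    """Individual-pair distance 1 - mean proportion of shared alleles.

    Per locus the sharing proportion is 1 - |dosage_i - dosage_j| / 2
    (identical genotypes 1, het vs hom 0.5, opposite homozygotes 0), averaged
    over co-called loci.
    """
    d = snp.dosage()  # loci x samples
    n = snp.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(d[:, i][:, None] - d[:, i + 1:])
        share = 1.0 - diff / 2.0
        m = np.nanmean(share, axis=0)
        out[i, i + 1:] = out[i + 1:, i] = 1.0 - m
    return out


def mean_within_cluster_distance(snp: SnpMatrix, labels) -> dict:
    """Mean allele-sharing distance between individuals of each cluster."""
    dm = allele_sharing_distance(snp)
    labels = np.asarray(labels)
    out = {}
    for g in pd.unique(labels):
        if pd.isna(g):
            continue
        sel = np.where(labels == g)[0]
        if len(sel) < 2:
            out[g] = np.nan
            continue
        iu = np.triu_indices(len(sel), k=1)
        out[g] = float(dm[np.ix_(sel, sel)][iu].mean())
    return out


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def _allele_vectors(snp: SnpMatrix) -> np.ndarray:
    """Two 0/1 allele vectors per individual, shape (2N, loci).

    Heterozygotes contribute one 0 and one 1; the matrix must be complete
    (apply the strict autosomal filter first).
    """
    if (snp.calls == MISSING).any():
        raise ValueError("AMOVA requires a complete matrix (no missing calls); "
                         "apply filter_autosomal_strict first")
    d = snp.calls.T  # samples x loci
    a1 = np.where(d == HOM_ALT, 1.0, 0.0)          # HOM_REF/HET -> 0
    a2 = np.where(d == HOM_REF, 0.0, 1.0)          # HOM_ALT/HET -> 1
    n, L = d.shape
    out = np.empty((2 * n, L))
    out[0::2], out[1::2] = a1, a2
    return out


def _ss_within_groups(x: np.ndarray, groups: np.ndarray) -> float:
    """Sum over groups of squared deviations from the group centroid."""
    ss = 0.0
    for g in np.unique(groups):
        xg = x[groups == g]
        ss += float(((xg - xg.mean(axis=0)) ** 2).sum())
    return ss


def _amova_components(alleles: np.ndarray, ind_of_allele: np.ndarray,
                      cluster_of_allele: np.ndarray):
    """(df, SS, MS, sigma) for the three strata plus totals."""
    n_alleles = alleles.shape[0]
    n_ind = len(np.unique(ind_of_allele))
    clusters, counts = np.unique(cluster_of_allele, return_counts=True)
    k = len(clusters)

    ss_total = float(((alleles - alleles.mean(axis=0)) ** 2).sum())
    ss_within_clusters = _ss_within_groups(alleles, cluster_of_allele)
    ss_within_ind = _ss_within_groups(alleles, ind_of_allele)
    ss_between_clusters = ss_total - ss_within_clusters
    ss_between_samples = ss_within_clusters - ss_within_ind

    df_a, df_b, df_c = k - 1, n_ind - k, n_ind
    df_t = n_alleles - 1
    ms_a, ms_b, ms_c = (ss_between_clusters / df_a, ss_between_samples / df_b,
                        ss_within_ind / df_c)
    sigma_c = ms_c
    sigma_b = (ms_b - ms_c) / 2.0
    n_c = (n_alleles - (counts**2).sum() / n_alleles) / (k - 1)
    sigma_a = (ms_a - sigma_c - 2.0 * sigma_b) / n_c
    return ((df_a, df_b, df_c, df_t),
            (ss_between_clusters, ss_between_samples, ss_within_ind, ss_total),
            (ms_a, ms_b, ms_c),
            (sigma_a, sigma_b, sigma_c))


def amova(snp: SnpMatrix, labels, permutations: int = 99,
          seed: Optional[int] = None) -> AmovaResult:
    """Two-level hierarchical AMOVA (clusters / individuals / alleles).

    Negative variance-component estimates are truncated at zero for the
    percentage column; the raw estimates are kept in ``sigma_raw``.
    Permutation p-values: individuals are permuted across clusters for the
    between-cluster component, and alleles among individuals within clusters
    for the between-individuals component.
    """
    labels = np.asarray(labels)
    clusters, counts = np.unique(labels, return_counts=True)
    if len(clusters) < 2:
        raise ValueError("AMOVA needs at least two clusters")
    if (counts < 2).any():
        raise ValueError("every cluster needs at least two individuals")

    alleles = _allele_vectors(snp)
    n_ind = snp.n_samples
    ind_of_allele = np.repeat(np.arange(n_ind), 2)
    cluster_of_ind = labels
    cluster_of_allele = np.repeat(labels, 2)

    dfs, sss, mss, sigmas = _amova_components(alleles, ind_of_allele,
                                              cluster_of_allele)
    sigma_trunc = np.maximum(sigmas, 0.0)
    total_sigma = float(sigma_trunc.sum())
    pct = 100.0 * sigma_trunc / total_sigma if total_sigma > 0 else np.full(3, np.nan)

    rows = ["between_clusters", "between_samples_within_clusters",
            "within_samples", "total"]
    table = pd.DataFrame({
        "df": dfs,
        "sum_sq": sss,
        "mean_sq": list(mss) + [sss[3] / dfs[3]],
        "sigma": list(sigma_trunc) + [total_sigma],
        "sigma_raw": list(sigmas) + [float(np.sum(sigmas))],
        "percent_variance": list(pct) + [float(np.nansum(pct))],
    }, index=rows)

    p_a = p_b = None
    if permutations > 0:
        rng = np.random.default_rng(seed)
        obs_a, obs_b = sigmas[0], sigmas[1]
        hits_a = hits_b = 0
        for _ in range(permutations):
            perm_labels = rng.permutation(cluster_of_ind)
            _, _, _, s = _amova_components(
                alleles, ind_of_allele, np.repeat(perm_labels, 2))
            if s[0] >= obs_a - 1e-12:
                hits_a += 1
            # alleles among individuals within clusters
            new_ind = ind_of_allele.copy()
            for g in clusters:
                sel = np.where(cluster_of_allele == g)[0]
                new_ind[sel] = new_ind[sel][rng.permutation(len(sel))]
            _, _, _, s = _amova_components(alleles, new_ind, cluster_of_allele)
            if s[1] >= obs_b - 1e-12:
                hits_b += 1
        p_a = (hits_a + 1) / (permutations + 1)
        p_b = (hits_b + 1) / (permutations + 1)
    return AmovaResult(table=table, p_between_clusters=p_a, p_within=p_b)
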