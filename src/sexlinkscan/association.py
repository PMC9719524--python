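"""Association of candidate loci with phenotypic sex.

Implements pairwise-complete normalized Hamming distances between
individuals, within/between-sex distance summaries, and the Cochran–Armitage
trend test (classic 1-df chi-square, ``chi2 = N * r^2`` where ``r`` is the
Pearson correlation between allele-dosage score and the binary sex
indicator), with an optional seeded permutation p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    HET, HOM_ALT, HOM_REF, MISSING,
    PaMatrix, SampleSheet, SnpMatrix, SEX_FEMALE, SEX_MALE,
)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise-complete normalized distance matrix.

    ``values[i, j]`` is the fraction of co-called loci at which samples i and
    j differ; entries with no co-called loci are NaN and flagged by
    ``n_overlap[i, j] == 0``.
    """

    sample_ids: np.ndarray
    values: np.ndarray     # (n, n) float, diagonal 0, NaN where undefined
    n_overlap: np.ndarray  # (n, n) int, co-called locus counts

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.sample_ids)
        return pd.DataFrame(self.values, index=ids, columns=ids)


@dataclass
class TrendTestResult:
    locus_id: str
    chi2: float              # NaN when degenerate (zero-variance input)
    p_asymptotic: float
    p_permutation: Optional[float]
    n_used: int


@dataclass
class GroupDistanceSummary:
    mean_within_males: float
    mean_within_females: float
    mean_between: float


def hamming_matrix(matrix: Union[SnpMatrix, PaMatrix],
                   locus_subset: Optional[Sequence] = None) -> DistanceMatrix:
    """Normalized Hamming distance between samples over a locus subset.

    Genotype codes are compared as categorical states (heterozygote differs
    from either homozygote); loci missing in either member of a pair are
    excluded from both numerator and denominator.
    """
    if locus_subset is not None:
        locus_subset = list(locus_subset)
        if len(locus_subset) == 0:
            raise ValueError("locus_subset must be non-empty")
        matrix = matrix.subset_loci(locus_subset)
    if matrix.n_loci == 0:
        raise ValueError("no loci to compare")
    calls = matrix.calls
    called = calls != MISSING
    n = matrix.n_samples
    values = np.zeros((n, n))
    overlap = np.zeros((n, n), dtype=int)
    for i in range(n):
        both = called[:, i][:, None] & called[:, i + 1:]
        diff = (calls[:, i][:, None] != calls[:, i + 1:]) & both
        ov = both.sum(axis=0)
        overlap[i, i + 1:] = overlap[i + 1:, i] = ov
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(ov > 0, diff.sum(axis=0) / np.maximum(ov, 1), np.nan)
        values[i, i + 1:] = values[i + 1:, i] = d
    overlap[np.diag_indices(n)] = called.sum(axis=0)
    if np.isnan(values[~np.eye(n, dtype=bool)]).any():
        warnings.warn("some sample pairs share no co-called loci; "
                      "their distances are undefined (NaN)")
    return DistanceMatrix(sample_ids=matrix.sample_ids.copy(),
                          values=values, n_overlap=overlap)


def group_distance_summary(dm: DistanceMatrix,
                           sheet: SampleSheet) -> GroupDistanceSummary:
    """Mean distances within males, within females and between the sexes.

    Arithmetic means over defined (non-NaN) off-diagonal entries of each pair
    category; UNKNOWN-sex samples are ignored.
    """
    sexes = sheet.sex_of(dm.sample_ids)
    males = np.asarray(sexes, dtype=object) == SEX_MALE
    females = np.asarray(sexes, dtype=object) == SEX_FEMALE
    if not males.any() or not females.any():
        raise ValueError("both sexes must be present")

    def mean_over(mask_i, mask_j, within):
        v = dm.values[np.ix_(mask_i, mask_j)]
        if within:
            iu = np.triu_indices(v.shape[0], k=1)
            entries = v[iu]
        else:
            entries = v.ravel()
        entries = entries[~np.isnan(entries)]
        if entries.size == 0:
            warnings.warn("a pair category has no defined distances")
            return np.nan
        return float(entries.mean())

    return GroupDistanceSummary(
        mean_within_males=mean_over(males, males, within=True),
        mean_within_females=mean_over(females, females, within=True),
        mean_between=mean_over(males, females, within=False),
    )


def _dosage_scores(genotypes: np.ndarray, scores) -> np.ndarray:
    """Map genotype codes to trend scores (indexed by alt-allele dosage)."""
    out = np.full(genotypes.shape, np.nan)
    out[genotypes == HOM_REF] = scores[0]
    out[genotypes == HET] = scores[1]
    out[genotypes == HOM_ALT] = scores[2]
    return out


def _trend_chi2(x: np.ndarray, y: np.ndarray) -> float:
    """chi2 = N * r^2 for score vector x and 0/1 indicator y."""
    n = len(x)
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return np.nan
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return n * r * r


def catt(genotypes, sexes, scores=(0.0, 1.0, 2.0), permutations: int = 0,
         seed: Optional[int] = None, locus_id: str = "",
         randomized_ties: bool = False) -> TrendTestResult:
    """Cochran–Armitage trend test of genotype dosage against sex.

    The statistic is the classic 1-df trend chi-square; the asymptotic p
    comes from chi2(1).  With ``permutations`` > 0, a permutation p-value is
    estimated by shuffling sex labels (``(b + 1) / (m + 1)`` estimator,
    seeded).  The trend statistic is discrete, so that estimator is valid but
    conservative (it has atoms, the largest at p = 1 when the observed
    statistic is 0); ``randomized_ties=True`` instead returns the randomized
    permutation p-value ``(G + U * (T + 1)) / (m + 1)`` (G strictly greater,
    T ties including the observation, U ~ Uniform(0,1)), which is exactly
    uniform under the null.  Degenerate input (constant genotypes or one sex)
    yields a NaN statistic flagged via ``chi2``.
    """
    genotypes = np.asarray(genotypes)
    sexes = np.asarray(sexes, dtype=object)
    called = (genotypes != MISSING) & np.isin(sexes, (SEX_MALE, SEX_FEMALE))
    x = _dosage_scores(genotypes[called], scores)
    y = (sexes[called] == SEX_MALE).astype(float)
    keep = ~np.isnan(x)
    x, y = x[keep], y[keep]
    n = len(x)
    if n == 0 or (y == y[0]).all():
        raise ValueError("both sexes need at least one called sample")
    chi2 = _trend_chi2(x, y)
    if np.isnan(chi2):
        return TrendTestResult(locus_id, np.nan, np.nan, None, n)
    p_asym = float(stats.chi2.sf(chi2, df=1))
    p_perm = None
    if permutations > 0:
        rng = np.random.default_rng(seed)
        greater = ties = 0
        for _ in range(permutations):
            yp = rng.permutation(y)
            c = _trend_chi2(x, yp)
            if np.isnan(c):
                continue
            if c > chi2 + 1e-12:
                greater += 1
            elif c >= chi2 - 1e-12:
                ties += 1
        if randomized_ties:
            u = rng.random()
            p_perm = (greater + u * (ties + 1)) / (permutations + 1)
        else:
            p_perm = (greater + ties + 1) / (permutations + 1)
    return TrendTestResult(locus_id, float(chi2), p_asym, p_perm, n)


def catt_scan(snp: SnpMatrix, sheet: SampleSheet, locus_subset=None,
              permutations: int = 0, seed: Optional[int] = None,
              randomized_ties: bool = False) -> pd.DataFrame:
    """Per-locus trend tests over a candidate set; one row per locus."""
    m = snp.subset_loci(locus_subset) if locus_subset is not None else snp
    sexes = sheet.sex_of(m.sample_ids)
    rows = []
    ss = np.random.SeedSequence(seed)
    for i, lid in enumerate(m.locus_ids):
        child = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        try:
            r = catt(m.calls[i], sexes, permutations=permutations,
                     seed=child, locus_id=str(lid),
                     randomized_ties=randomized_ties)
        except ValueError:
            r = TrendTestResult(str(lid), np.nan, np.nan, None, 0)
        rows.append(vars(r))
    return pd.DataFrame(rows)


def combined_trend_test(snp: SnpMatrix, sheet: SampleSheet,
                        locus_subset=None) -> TrendTestResult:
    """Joint association of a candidate set with sex via its first principal
    score: dosages are mean-imputed and centred, the leading left singular
    vector gives one score per sample, and the trend chi-square of that score
    against sex is reported.  This is an aggregate convenience, not a
    per-locus test.
    """
    m = snp.subset_loci(locus_subset) if locus_subset is not None else snp
    sexes = sheet.sex_of(m.sample_ids)
    d = m.dosage()  # loci x samples, NaN missing
    mu = np.nanmean(d, axis=1, keepdims=True)
    d = np.where(np.isnan(d), mu, d) - mu
    d = np.nan_to_num(d)  # all-missing loci contribute nothing
    _, _, vt = np.linalg.svd(d, full_matrices=False)
    score = vt[0]
    y = (np.asarray(sexes, dtype=object) == SEX_MALE).astype(float)
    keep = np.isin(sexes, (SEX_MALE, SEX_FEMALE))
    chi2 = _trend_chi2(score[keep], y[keep])
    p = float(stats.chi2.sf(chi2, df=1)) if not np.isnan(chi2) else np.nan
    return TrendTestResult("combined_pc1", float(chi2), p, None, int(keep.sum()))
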