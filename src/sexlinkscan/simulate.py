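"""DArTseq-like dataset simulator with known ground truth.

Generates SNP and presence/absence matrices for one or two genetic clusters
plus a sample sheet and a per-locus truth table, so the whole downstream
pipeline (call-rate filtering, sex-linkage classification, distance and
structure analysis) can be exercised and validated without external data.

Model
-----
Autosomal SNP loci follow the Balding–Nichols divergence model: an ancestral
reference-allele frequency p ~ Uniform(0.05, 0.95) and, for two clusters with
divergence target F, cluster frequencies drawn from
Beta(p(1-F)/F, (1-p)(1-F)/F), whose expected Wright F_ST between clusters is
F.  Genotypes are Hardy–Weinberg draws within cluster.

Sex-linked SNP loci under XY male heterogamety are heterozygous in males and
homozygous (one fixed class per locus) in females; ZW mirrors the pattern
with the sexes swapped.  Sex-linked PA loci are PRESENT in the heterogametic
sex and ABSENT in the homogametic sex (a fragment on the Y or W).  Each
individual violates the expected pattern with probability ``discordance``,
with the per-locus per-sex discordant fraction constrained below 20%, which
is the regime the classifier is designed for (markers discordant in 20% or
more of one sex would not qualify at the 80% concordance threshold anyway).

Missing calls are applied i.i.d. at ``missing_rate`` over every matrix, and
metadata columns (CallRate, FreqHets, RepAvg, ...) are computed from the
realized matrix so the files behave like genuine DArT reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .io import (
    ABSENT, HET, HOM_ALT, HOM_REF, MISSING, PRESENT,
    PaMatrix, SampleSheet, SnpMatrix, SEX_FEMALE, SEX_MALE,
)

SYSTEM_XY = "XY"
SYSTEM_ZW = "ZW"

CATEGORY_AUTOSOMAL = "AUTOSOMAL"
CATEGORY_SEXLINKED = "SEXLINKED"

_BASES = np.array(list("ACGT"))

#: sex-linked loci are generated with per-locus discordance strictly below
#: this bound (the regime of interest for 80%-concordance classification)
DISCORDANCE_BOUND = 0.2


@dataclass
class SimConfig:
    """Study-design parameters for one simulated dataset.

    ``n_males`` / ``n_females`` are per-cluster cohort sizes.  ``fst_target``
    is the Balding–Nichols divergence between the two clusters (ignored when
    ``n_clusters`` is 1).  ``discordance`` is the per-individual probability
    that a sex-linked locus violates its expected pattern; ``missing_rate``
    the i.i.d. null-call probability.  ``seed`` fixes the output bit for bit.
    """

    n_males: int = 19
    n_females: int = 25
    n_clusters: int = 1
    fst_target: float = 0.0
    n_autosomal: int = 5000
    n_sexlinked_snp: int = 0
    n_sexlinked_pa: int = 0
    n_autosomal_pa: int = 0
    system: str = SYSTEM_XY
    discordance: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters not in (1, 2):
            raise ValueError("n_clusters must be 1 or 2")
        if self.system not in (SYSTEM_XY, SYSTEM_ZW):
            raise ValueError("system must be 'XY' or 'ZW'")
        for name in ("fst_target", "discordance", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        for name in ("n_males", "n_females", "n_autosomal",
                     "n_sexlinked_snp", "n_sexlinked_pa", "n_autosomal_pa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_clusters == 2 and self.fst_target == 0.0:
            warnings.warn("two clusters with fst_target 0 are indistinguishable")


@dataclass
class SimDataset:
    snp: SnpMatrix
    pa: PaMatrix
    sheet: SampleSheet
    truth: pd.DataFrame   # locus_id, marker_type, category, system, concordances
    config: SimConfig


def _cluster_frequencies(p_anc: np.ndarray, fst: float, n_clusters: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Per-cluster allele frequencies, shape (n_clusters, n_loci)."""
    if n_clusters == 1 or fst == 0.0:
        return np.tile(p_anc, (n_clusters, 1))
    a = p_anc * (1.0 - fst) / fst
    b = (1.0 - p_anc) * (1.0 - fst) / fst
    freqs = rng.beta(a, b, size=(n_clusters, len(p_anc)))
    return np.clip(freqs, 1e-6, 1.0 - 1e-6)


def _hwe_genotypes(p_ref: np.ndarray, n_ind: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Hardy–Weinberg genotype draws, loci x individuals int8 codes."""
    p = p_ref[:, None]
    u = rng.random((len(p_ref), n_ind))
    g = np.full(u.shape, HET, dtype=np.int8)
    g[u < p**2] = HOM_REF
    g[u >= p**2 + 2 * p * (1 - p)] = HOM_ALT
    return g


def _bounded_discordant_mask(n_loci: int, n_ind: int, discordance: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Per-locus discordance indicators with realized rate < 20% per locus.

    Counts are Binomial(n_ind, discordance), redrawn while the realized
    per-locus fraction reaches the bound (only possible when discordance is
    itself below the bound; larger values are used as-is).
    """
    mask = np.zeros((n_loci, n_ind), dtype=bool)
    if discordance == 0.0 or n_ind == 0:
        return mask
    max_count = n_ind  # no bound when requested discordance >= bound
    if discordance < DISCORDANCE_BOUND:
        max_count = int(np.ceil(DISCORDANCE_BOUND * n_ind)) - 1
        max_count = max(max_count, 0)
    counts = rng.binomial(n_ind, discordance, size=n_loci)
    for _ in range(1000):
        over = counts > max_count
        if not over.any():
            break
        counts[over] = rng.binomial(n_ind, discordance, size=int(over.sum()))
    counts = np.minimum(counts, max_count)
    for i, k in enumerate(counts):
        if k:
            mask[i, rng.choice(n_ind, size=k, replace=False)] = True
    return mask


def _sexlinked_snp(n_loci: int, is_male: np.ndarray, system: str,
                   discordance: float, rng: np.random.Generator) -> np.ndarray:
    """Sex-linked SNP genotypes; heterogametic sex HET, homogametic fixed hom."""
    hetero = is_male if system == SYSTEM_XY else ~is_male
    n_het, n_hom = int(hetero.sum()), int((~hetero).sum())
    hom_class = rng.choice([HOM_REF, HOM_ALT], size=n_loci)
    g = np.empty((n_loci, len(is_male)), dtype=np.int8)
    disc_het = _bounded_discordant_mask(n_loci, n_het, discordance, rng)
    disc_hom = _bounded_discordant_mask(n_loci, n_hom, discordance, rng)
    gh = np.where(disc_het, hom_class[:, None], HET).astype(np.int8)
    gm = np.where(disc_hom, HET, hom_class[:, None]).astype(np.int8)
    g[:, hetero] = gh
    g[:, ~hetero] = gm
    return g


def _sexlinked_pa(n_loci: int, is_male: np.ndarray, system: str,
                  discordance: float, rng: np.random.Generator) -> np.ndarray:
    """Sex-linked PA states; present on the Y (XY) or W (ZW) chromosome."""
    hetero = is_male if system == SYSTEM_XY else ~is_male
    n_het, n_hom = int(hetero.sum()), int((~hetero).sum())
    g = np.empty((n_loci, len(is_male)), dtype=np.int8)
    disc_het = _bounded_discordant_mask(n_loci, n_het, discordance, rng)
    disc_hom = _bounded_discordant_mask(n_loci, n_hom, discordance, rng)
    g[:, hetero] = np.where(disc_het, ABSENT, PRESENT).astype(np.int8)
    g[:, ~hetero] = np.where(disc_hom, PRESENT, ABSENT).astype(np.int8)
    return g


def _random_sequences(n: int, length: int, rng: np.random.Generator):
    idx = rng.integers(0, 4, size=(n, length))
    return ["".join(_BASES[r]) for r in idx]


def _snp_meta(calls: np.ndarray, locus_ids, rng: np.random.Generator) -> pd.DataFrame:
    """DArT-style metadata computed from the realized genotype matrix."""
    n_loci, n_samples = calls.shape
    called = calls != MISSING
    n_called = called.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_ref = (calls == HOM_REF).sum(axis=1) / n_called
        f_alt = (calls == HOM_ALT).sum(axis=1) / n_called
        f_het = (calls == HET).sum(axis=1) / n_called
        one_ref = f_ref + f_het
        one_alt = f_alt + f_het
    seqs = _random_sequences(n_loci, 69, rng)
    pos = rng.integers(5, 64, size=n_loci)
    ref_base = _BASES[rng.integers(0, 4, size=n_loci)]
    alt_base = _BASES[(np.char.find("ACGT", ref_base.astype("U1"))
                       + rng.integers(1, 4, size=n_loci)) % 4]
    pic_ref = 2 * one_ref * (1 - one_ref)
    pic_alt = 2 * one_alt * (1 - one_alt)
    return pd.DataFrame({
        "allele_id": [f"{lid}|F|0-{p}:{r}>{a}"
                      for lid, p, r, a in zip(locus_ids, pos, ref_base, alt_base)],
        "clone_id": [str(lid).split("_")[-1] for lid in locus_ids],
        "allele_sequence": seqs,
        "trimmed_sequence": seqs,
        "snp_base": [f"{r}>{a}" for r, a in zip(ref_base, alt_base)],
        "snp_position": pos,
        "call_rate": n_called / n_samples,
        "one_ratio_ref": one_ref,
        "one_ratio_snp": one_alt,
        "freq_hom_ref": f_ref,
        "freq_hom_snp": f_alt,
        "freq_hets": f_het,
        "pic_ref": pic_ref,
        "pic_snp": pic_alt,
        "avg_pic": (pic_ref + pic_alt) / 2,
        "avg_count_ref": np.round(rng.uniform(8, 40, size=n_loci), 1),
        "avg_count_snp": np.round(rng.uniform(8, 40, size=n_loci), 1),
        "rep_avg": np.ones(n_loci),
    }, index=pd.Index(np.asarray(locus_ids, dtype=object)))


def _pa_meta(calls: np.ndarray, locus_ids) -> pd.DataFrame:
    n_loci, n_samples = calls.shape
    n_called = (calls != MISSING).sum(axis=1)
    return pd.DataFrame({
        "clone_id": np.asarray(locus_ids, dtype=object),
        "call_rate": n_called / n_samples,
        "rep_avg": np.ones(n_loci),
    }, index=pd.Index(np.asarray(locus_ids, dtype=object)))


def _apply_missing(calls: np.ndarray, rate: float, rng: np.random.Generator):
    if rate > 0.0:
        calls[rng.random(calls.shape) < rate] = MISSING
    return calls


def _realized_concordance(calls, is_male, system, marker_type):
    """Fraction of each sex matching the expected sex-linked pattern."""
    hetero = is_male if system == SYSTEM_XY else ~is_male
    if marker_type == "SNP":
        match_het = calls[:, hetero] == HET
        match_hom = np.isin(calls[:, ~hetero], (HOM_REF, HOM_ALT))
    else:
        match_het = calls[:, hetero] == PRESENT
        match_hom = calls[:, ~hetero] == ABSENT
    conc_het = match_het.mean(axis=1) if hetero.any() else np.full(len(calls), np.nan)
    conc_hom = match_hom.mean(axis=1) if (~hetero).any() else np.full(len(calls), np.nan)
    if system == SYSTEM_XY:
        return conc_het, conc_hom   # males, females
    return conc_hom, conc_het


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Generate (SnpMatrix, PaMatrix, SampleSheet, truth) for one config."""
    rng = np.random.default_rng(config.seed)

    # --- samples -----------------------------------------------------------
    ids, sexes, clusters, sites = [], [], [], []
    for cl in range(1, config.n_clusters + 1):
        for i in range(config.n_males):
            ids.append(f"c{cl}M{i + 1:03d}")
            sexes.append(SEX_MALE)
            clusters.append(cl)
        for i in range(config.n_females):
            ids.append(f"c{cl}F{i + 1:03d}")
            sexes.append(SEX_FEMALE)
            clusters.append(cl)
        sites.extend([f"site_{cl}"] * (config.n_males + config.n_females))
    sheet = SampleSheet(pd.DataFrame({
        "sample_id": ids, "sex": sexes, "site": sites,
        "cluster": pd.array(clusters, dtype="Int64"),
    }))
    is_male = np.array([s == SEX_MALE for s in sexes])
    cluster_arr = np.array(clusters)
    n_ind = len(ids)
    per_cluster = config.n_males + config.n_females

    # --- SNP loci ----------------------------------------------------------
    snp_blocks, snp_truth = [], []
    if config.n_autosomal:
        p_anc = rng.uniform(0.05, 0.95, size=config.n_autosomal)
        freqs = _cluster_frequencies(p_anc, config.fst_target, config.n_clusters, rng)
        g = np.empty((config.n_autosomal, n_ind), dtype=np.int8)
        for cl in range(1, config.n_clusters + 1):
            sel = cluster_arr == cl
            g[:, sel] = _hwe_genotypes(freqs[cl - 1], int(sel.sum()), rng)
        snp_blocks.append(("AUT", g, CATEGORY_AUTOSOMAL))
    if config.n_sexlinked_snp:
        g = _sexlinked_snp(config.n_sexlinked_snp, is_male, config.system,
                           config.discordance, rng)
        snp_blocks.append(("SEX", g, CATEGORY_SEXLINKED))

    snp_ids, snp_calls, snp_cat = [], [], []
    for tag, g, cat in snp_blocks:
        start = len(snp_ids)
        snp_ids += [f"SNP_{tag}_{start + i + 1:06d}" for i in range(len(g))]
        snp_calls.append(g)
        snp_cat += [cat] * len(g)
    calls = (np.vstack(snp_calls) if snp_calls
             else np.empty((0, n_ind), dtype=np.int8))
    conc_m = np.full(len(snp_ids), np.nan)
    conc_f = np.full(len(snp_ids), np.nan)
    sex_rows = np.array([c == CATEGORY_SEXLINKED for c in snp_cat])
    if sex_rows.any():
        cm, cf = _realized_concordance(calls[sex_rows], is_male,
                                       config.system, "SNP")
        conc_m[sex_rows], conc_f[sex_rows] = cm, cf
    calls = _apply_missing(calls, config.missing_rate, rng)
    snp = SnpMatrix(
        locus_ids=np.array(snp_ids, dtype=object),
        sample_ids=np.array(ids, dtype=object),
        calls=calls,
        meta=_snp_meta(calls, snp_ids, rng) if snp_ids else None,
    )
    snp_truth = pd.DataFrame({
        "locus_id": snp_ids,
        "marker_type": "SNP",
        "category": snp_cat,
        "system": np.where(sex_rows, config.system, ""),
        "concordance_males": conc_m,
        "concordance_females": conc_f,
    })

    # --- PA loci -----------------------------------------------------------
    pa_ids, pa_calls_l, pa_cat = [], [], []
    if config.n_autosomal_pa:
        q_anc = rng.uniform(0.1, 0.9, size=config.n_autosomal_pa)
        freqs = _cluster_frequencies(q_anc, config.fst_target, config.n_clusters, rng)
        g = np.empty((config.n_autosomal_pa, n_ind), dtype=np.int8)
        for cl in range(1, config.n_clusters + 1):
            sel = cluster_arr == cl
            g[:, sel] = (rng.random((config.n_autosomal_pa, int(sel.sum())))
                         < freqs[cl - 1][:, None]).astype(np.int8)
        pa_ids += [f"PA_AUT_{i + 1:06d}" for i in range(len(g))]
        pa_calls_l.append(g)
        pa_cat += [CATEGORY_AUTOSOMAL] * len(g)
    if config.n_sexlinked_pa:
        g = _sexlinked_pa(config.n_sexlinked_pa, is_male, config.system,
                          config.discordance, rng)
        pa_ids += [f"PA_SEX_{len(pa_ids) + i + 1:06d}" for i in range(len(g))]
        pa_calls_l.append(g)
        pa_cat += [CATEGORY_SEXLINKED] * len(g)
    pa_calls = (np.vstack(pa_calls_l) if pa_calls_l
                else np.empty((0, n_ind), dtype=np.int8))
    conc_m = np.full(len(pa_ids), np.nan)
    conc_f = np.full(len(pa_ids), np.nan)
    sex_rows_pa = np.array([c == CATEGORY_SEXLINKED for c in pa_cat])
    if sex_rows_pa.any():
        cm, cf = _realized_concordance(pa_calls[sex_rows_pa], is_male,
                                       config.system, "PA")
        conc_m[sex_rows_pa], conc_f[sex_rows_pa] = cm, cf
    pa_calls = _apply_missing(pa_calls, config.missing_rate, rng)
    pa = PaMatrix(
        locus_ids=np.array(pa_ids, dtype=object),
        sample_ids=np.array(ids, dtype=object),
        calls=pa_calls,
        meta=_pa_meta(pa_calls, pa_ids) if pa_ids else None,
    )
    pa_truth = pd.DataFrame({
        "locus_id": pa_ids,
        "marker_type": "PA",
        "category": pa_cat,
        "system": np.where(sex_rows_pa, config.system, "") if pa_ids else [],
        "concordance_males": conc_m,
        "concordance_females": conc_f,
    })

    truth = pd.concat([snp_truth, pa_truth], ignore_index=True)
    return SimDataset(snp=snp, pa=pa, sheet=sheet, truth=truth, config=config)


def config_from_dict(d: dict) -> SimConfig:
    return SimConfig(**d)


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)
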