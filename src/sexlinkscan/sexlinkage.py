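"""Sex-linked marker classification for SNP and presence/absence loci.

A SNP locus supports male heterogamety (XX/XY) when at least a threshold
fraction (default 80%) of called males are heterozygous AND at least the same
fraction of called females are homozygous; female heterogamety (ZZ/ZW) is the
mirror image.  PA loci use present-in-the-heterogametic / absent-in-the-
homogametic sex in place of heterozygous/homozygous.  Loci meeting the
criterion in every called individual of both sexes are graded PERFECT, the
rest MODERATE.

Candidate SNP loci additionally pass a false-positive screen: in the
homogametic sex (females under XY, males under ZW) a true sex-linked locus is
homozygous for one consistent allele class, so the fraction of called
homogametic individuals carrying the majority homozygote class must reach the
threshold.  Counting a single class (rather than both homozygote classes, as
the main criterion does) is what gives the screen power beyond the main
criterion.

With small cohorts the 80% criterion admits chance-concordant autosomal loci,
so strict mode (100% concordance) is auto-enabled when either sex has fewer
than 13 individuals; it can be forced on or off explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np
import pandas as pd

from .io import (
    ABSENT, HET, HOM_ALT, HOM_REF, MISSING, PRESENT,
    PaMatrix, SampleSheet, SnpMatrix, SEX_FEMALE, SEX_MALE,
)

SYSTEM_XY = "XY"
SYSTEM_ZW = "ZW"
SYSTEM_NONE = "NONE"
UNEVALUABLE = "UNEVALUABLE"

CLASS_PERFECT = "PERFECT"
CLASS_MODERATE = "MODERATE"
CLASS_NONE = "NONE"


@dataclass(frozen=True)
class SexLinkCriteria:
    """Thresholds for the sex-linkage scan (all compared inclusively).

    ``strict`` forces 100% concordance; when it is left False the scan
    auto-enables it for cohorts below ``auto_strict_threshold`` individuals
    in either sex (small samples make 80%-concordant false positives likely).
    """

    call_rate_min: float = 0.8
    concordance_min: float = 0.8
    strict: bool = False
    auto_strict_threshold: int = 13
    fp_homozygosity_min: float = 0.8
    min_called_per_sex: int = 1

    def __post_init__(self):
        for name in ("call_rate_min",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("concordance_min", "fp_homozygosity_min"):
            v = getattr(self, name)
            if not 0.5 < v <= 1.0:
                raise ValueError(
                    f"{name} must be in (0.5, 1]; values at or below 0.5 "
                    "would allow a locus to support XY and ZW simultaneously"
                )
        if self.min_called_per_sex < 1:
            raise ValueError("min_called_per_sex must be >= 1")

    @property
    def effective_concordance(self) -> float:
        return 1.0 if self.strict else self.concordance_min


@dataclass
class SexLinkResult:
    """Per-locus outcome of the sex-linkage classification."""

    locus_id: str
    marker_type: str                 # "SNP" | "PA"
    system_call: str                 # XY | ZW | NONE | UNEVALUABLE
    het_or_present_frac_males: float
    het_or_present_frac_females: float
    hom_or_absent_frac: float        # in the homogametic sex of the call
    linkage_class: str               # PERFECT | MODERATE | NONE
    fp_pass: Optional[bool]          # None until the FP screen runs (SNP only)
    n_called_males: int
    n_called_females: int


def filter_call_rate(matrix: Union[SnpMatrix, PaMatrix],
                     threshold: float) -> Union[SnpMatrix, PaMatrix]:
    """Retain loci whose recomputed call rate is >= threshold (inclusive)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    keep = matrix.call_rate() >= threshold
    return matrix.subset_loci(matrix.locus_ids[keep])


def _sex_masks(sexes: np.ndarray):
    sexes = np.asarray(sexes, dtype=object)
    return sexes == SEX_MALE, sexes == SEX_FEMALE


def _classify(calls: np.ndarray, sexes: np.ndarray, criteria: SexLinkCriteria,
              het_like, hom_like, locus_id: str, marker_type: str) -> SexLinkResult:
    """Shared classifier; het_like/hom_like are the qualifying code sets."""
    calls = np.asarray(calls)
    males, females = _sex_masks(sexes)
    called = calls != MISSING
    cm, cf = called & males, called & females
    n_m, n_f = int(cm.sum()), int(cf.sum())
    c = criteria.effective_concordance

    if n_m < criteria.min_called_per_sex or n_f < criteria.min_called_per_sex:
        return SexLinkResult(locus_id, marker_type, UNEVALUABLE,
                             np.nan, np.nan, np.nan, CLASS_NONE, None, n_m, n_f)

    het_m = float(np.isin(calls[cm], het_like).mean())
    het_f = float(np.isin(calls[cf], het_like).mean())
    hom_m = float(np.isin(calls[cm], hom_like).mean())
    hom_f = float(np.isin(calls[cf], hom_like).mean())

    if het_m >= c and hom_f >= c:
        system, qual = SYSTEM_XY, (het_m, hom_f)
        hom_frac = hom_f
    elif het_f >= c and hom_m >= c:
        system, qual = SYSTEM_ZW, (het_f, hom_m)
        hom_frac = hom_m
    else:
        return SexLinkResult(locus_id, marker_type, SYSTEM_NONE,
                             het_m, het_f, np.nan, CLASS_NONE, None, n_m, n_f)
    linkage = CLASS_PERFECT if qual[0] == 1.0 and qual[1] == 1.0 else CLASS_MODERATE
    return SexLinkResult(locus_id, marker_type, system,
                         het_m, het_f, hom_frac, linkage, None, n_m, n_f)


def classify_snp_locus(genotypes, sexes, criteria: SexLinkCriteria,
                       locus_id: str = "") -> SexLinkResult:
    """Classify one SNP locus as XY-linked, ZW-linked or neither.

    Fractions are over called individuals of each sex; UNKNOWN-sex samples
    never enter a denominator.  Returns an UNEVALUABLE result when either sex
    has fewer than ``min_called_per_sex`` called individuals.
    """
    return _classify(genotypes, sexes, criteria,
                     het_like=(HET,), hom_like=(HOM_REF, HOM_ALT),
                     locus_id=locus_id, marker_type="SNP")


def classify_pa_locus(states, sexes, criteria: SexLinkCriteria,
                      locus_id: str = "") -> SexLinkResult:
    """Classify one presence/absence locus (present <-> heterogametic sex)."""
    return _classify(states, sexes, criteria,
                     het_like=(PRESENT,), hom_like=(ABSENT,),
                     locus_id=locus_id, marker_type="PA")


def false_positive_test(genotypes, sexes, system_call: str,
                        criteria: SexLinkCriteria) -> bool:
    """Single-class homozygosity screen in the homogametic sex.

    Pass iff the majority homozygote class accounts for at least
    ``fp_homozygosity_min`` of called individuals of the homogametic sex
    (females for an XY call, males for ZW).  Raises on an unevaluable locus
    (no called homogametic individuals).
    """
    if system_call not in (SYSTEM_XY, SYSTEM_ZW):
        raise ValueError("false_positive_test needs an XY or ZW call")
    genotypes = np.asarray(genotypes)
    males, females = _sex_masks(sexes)
    homogametic = females if system_call == SYSTEM_XY else males
    g = genotypes[homogametic & (genotypes != MISSING)]
    if g.size == 0:
        raise ValueError("no called individuals in the homogametic sex "
                         "(locus unevaluable)")
    majority = max(int((g == HOM_REF).sum()), int((g == HOM_ALT).sum()))
    return majority / g.size >= criteria.fp_homozygosity_min


@dataclass
class ScanResult:
    """Full sex-linkage scan output: per-locus table plus summary counts."""

    results: pd.DataFrame
    summary: dict
    criteria: SexLinkCriteria
    strict_used: bool

    def reported(self) -> pd.DataFrame:
        """Loci reported as sex-linked (XY/ZW call; SNPs must pass FP test)."""
        r = self.results
        ok = r["system_call"].isin([SYSTEM_XY, SYSTEM_ZW])
        ok &= (r["marker_type"] == "PA") | (r["fp_pass"] == True)  # noqa: E712
        return r[ok]


def _results_frame(results) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def scan(snp: Optional[SnpMatrix], pa: Optional[PaMatrix], sheet: SampleSheet,
         criteria: SexLinkCriteria = SexLinkCriteria(),
         auto_strict: bool = True) -> ScanResult:
    """Run the full sex-linkage scan on SNP and/or PA matrices.

    Applies the call-rate filter, classifies every surviving locus, runs the
    false-positive screen on SNP candidates, and summarises counts by system
    and linkage class.  Strict (100%-concordance) mode is auto-enabled when
    the smaller sex cohort is below ``criteria.auto_strict_threshold``,
    unless ``auto_strict`` is False or ``criteria.strict`` is already set.
    """
    sexes_all = []
    for m in (snp, pa):
        if m is not None:
            sexes_all = sheet.sex_of(m.sample_ids)
            break
    if len(sexes_all) == 0:
        raise ValueError("scan needs at least one of snp/pa")
    n_m = int((np.asarray(sexes_all, dtype=object) == SEX_MALE).sum())
    n_f = int((np.asarray(sexes_all, dtype=object) == SEX_FEMALE).sum())
    if n_m == 0 or n_f == 0:
        raise ValueError("all samples are one sex; sex-linkage is undefined")

    strict = criteria.strict
    if auto_strict and not strict and min(n_m, n_f) < criteria.auto_strict_threshold:
        strict = True
        warnings.warn(
            f"strict mode auto-enabled: smaller sex cohort ({min(n_m, n_f)}) "
            f"is below {criteria.auto_strict_threshold} individuals"
        )
    crit = replace(criteria, strict=strict)

    results = []
    for matrix, classify in ((snp, classify_snp_locus), (pa, classify_pa_locus)):
        if matrix is None:
            continue
        sexes = sheet.sex_of(matrix.sample_ids)
        kept = filter_call_rate(matrix, crit.call_rate_min)
        for i, lid in enumerate(kept.locus_ids):
            res = classify(kept.calls[i], sexes, crit, locus_id=str(lid))
            if (res.marker_type == "SNP"
                    and res.system_call in (SYSTEM_XY, SYSTEM_ZW)):
                try:
                    res.fp_pass = false_positive_test(
                        kept.calls[i], sexes, res.system_call, crit)
                except ValueError:
                    res.fp_pass = False
                    res.system_call = UNEVALUABLE
            results.append(res)

    table = _results_frame(results) if results else pd.DataFrame(
        columns=list(SexLinkResult.__dataclass_fields__))
    out = ScanResult(results=table, summary={}, criteria=crit, strict_used=strict)
    rep = out.reported()
    summary = {"strict_used": strict, "n_males": n_m, "n_females": n_f}
    for mt in ("SNP", "PA"):
        for sys_ in (SYSTEM_XY, SYSTEM_ZW):
            sel = rep[(rep["marker_type"] == mt) & (rep["system_call"] == sys_)]
            summary[f"{mt.lower()}_{sys_.lower()}"] = int(len(sel))
            for cls in (CLASS_PERFECT, CLASS_MODERATE):
                summary[f"{mt.lower()}_{sys_.lower()}_{cls.lower()}"] = int(
                    (sel["linkage_class"] == cls).sum())
    out.summary = summary
    return out
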