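"""Readers, writers and per-locus summaries for DArTseq-dialect matrices.

DArTseq SNP reports use a one-row-per-locus coded matrix: ``0`` homozygous
reference, ``1`` homozygous alternate ("homozygous SNP"), ``2`` heterozygous,
and ``-`` (or an empty cell) for a failed call.  SilicoDArT presence/absence
(PA) reports use ``1`` present / ``0`` absent with the same null convention.
Both carry per-locus metadata columns (CallRate, RepAvg, ...) ahead of the
per-sample columns; the readers here are header-driven, not positional.

Internally calls are stored as small integers with ``MISSING = -9`` so that
the on-disk codes map onto themselves (0/1/2 for SNPs, 0/1 for PA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import ClassVar

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# genotype codes (match the DArT on-disk coding)
HOM_REF = 0
HOM_ALT = 1
HET = 2
MISSING = -9

# presence/absence codes
ABSENT = 0
PRESENT = 1

#: accepted null-allele tokens; the first is what writers emit
NULL_TOKENS = ("-", "−", "")

#: canonical SNP metadata columns, CSV header -> field name
SNP_META_COLUMNS = {
    "AlleleID": "allele_id",
    "CloneID": "clone_id",
    "AlleleSequence": "allele_sequence",
    "TrimmedSequence": "trimmed_sequence",
    "SNP": "snp_base",
    "SnpPosition": "snp_position",
    "CallRate": "call_rate",
    "OneRatioRef": "one_ratio_ref",
    "OneRatioSnp": "one_ratio_snp",
    "FreqHomRef": "freq_hom_ref",
    "FreqHomSnp": "freq_hom_snp",
    "FreqHets": "freq_hets",
    "PICRef": "pic_ref",
    "PICSnp": "pic_snp",
    "AvgPIC": "avg_pic",
    "AvgCountRef": "avg_count_ref",
    "AvgCountSnp": "avg_count_snp",
    "RepAvg": "rep_avg",
}

PA_META_COLUMNS = {
    "CloneID": "clone_id",
    "AlleleID": "allele_id",
    "CallRate": "call_rate",
    "RepAvg": "rep_avg",
}

_SNP_NUMERIC_META = {
    "snp_position", "call_rate", "one_ratio_ref", "one_ratio_snp",
    "freq_hom_ref", "freq_hom_snp", "freq_hets", "pic_ref", "pic_snp",
    "avg_pic", "avg_count_ref", "avg_count_snp", "rep_avg",
}
_PA_NUMERIC_META = {"call_rate", "rep_avg"}


class GenotypeIOError(ValueError):
    """Raised for malformed matrix files (bad codes, duplicate loci, ...)."""


@dataclass
class _CodedMatrix:
    """Shared behaviour of loci x samples coded matrices."""

    locus_ids: np.ndarray        # (n_loci,) str
    sample_ids: np.ndarray       # (n_samples,) str
    calls: np.ndarray            # (n_loci, n_samples) int8
    meta: pd.DataFrame = field(default=None)  # indexed by locus id

    _alphabet: ClassVar[tuple] = ()

    def __post_init__(self):
        self.locus_ids = np.asarray(self.locus_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.locus_ids), len(self.sample_ids)):
            raise GenotypeIOError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.locus_ids)} loci x {len(self.sample_ids)} samples"
            )
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise GenotypeIOError("duplicate locus ids")
        bad = ~np.isin(self.calls, list(self._alphabet) + [MISSING])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeIOError(
                f"invalid code {self.calls[i, j]} at locus "
                f"{self.locus_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        if self.meta is None:
            self.meta = pd.DataFrame(index=pd.Index(self.locus_ids))

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def called_mask(self) -> np.ndarray:
        return self.calls != MISSING

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per locus (recomputed, not stored)."""
        if self.n_samples == 0:
            return np.zeros(self.n_loci)
        return self.called_mask().mean(axis=1)

    def subset_loci(self, locus_ids) -> "_CodedMatrix":
        idx = pd.Index(self.locus_ids).get_indexer(np.asarray(locus_ids, dtype=object))
        if (idx < 0).any():
            missing = np.asarray(locus_ids, dtype=object)[idx < 0][:3]
            raise KeyError(f"unknown locus ids: {list(missing)}")
        return type(self)(
            locus_ids=self.locus_ids[idx],
            sample_ids=self.sample_ids,
            calls=self.calls[idx],
            meta=self.meta.iloc[idx],
        )

    def subset_samples(self, sample_ids) -> "_CodedMatrix":
        idx = pd.Index(self.sample_ids).get_indexer(np.asarray(sample_ids, dtype=object))
        if (idx < 0).any():
            missing = np.asarray(sample_ids, dtype=object)[idx < 0][:3]
            raise KeyError(f"unknown sample ids: {list(missing)}")
        return type(self)(
            locus_ids=self.locus_ids,
            sample_ids=self.sample_ids[idx],
            calls=self.calls[:, idx],
            meta=self.meta,
        )


@dataclass
class SnpMatrix(_CodedMatrix):
    """Loci x samples SNP genotype matrix with DArT per-locus metadata."""

    _alphabet: ClassVar[tuple] = (HOM_REF, HOM_ALT, HET)

    def dosage(self) -> np.ndarray:
        """Alternate-allele dosage (0/1/2), NaN where missing, loci x samples."""
        d = np.full(self.calls.shape, np.nan)
        d[self.calls == HOM_REF] = 0.0
        d[self.calls == HET] = 1.0
        d[self.calls == HOM_ALT] = 2.0
        return d


@dataclass
class PaMatrix(_CodedMatrix):
    """Loci x samples SilicoDArT presence/absence matrix."""

    _alphabet: ClassVar[tuple] = (ABSENT, PRESENT)


SEX_MALE = "M"
SEX_FEMALE = "F"
SEX_UNKNOWN = "UNKNOWN"


@dataclass
class SampleSheet:
    """Per-sample phenotypic sex, collection site and optional cluster label."""

    table: pd.DataFrame  # columns: sample_id, sex, site, cluster

    def __post_init__(self):
        t = self.table
        if t["sample_id"].duplicated().any():
            dup = t["sample_id"][t["sample_id"].duplicated()].iloc[0]
            raise GenotypeIOError(f"duplicate sample id {dup!r} in sample sheet")
        bad = ~t["sex"].isin([SEX_MALE, SEX_FEMALE, SEX_UNKNOWN])
        if bad.any():
            raise GenotypeIOError(f"invalid sex value {t['sex'][bad].iloc[0]!r}")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.table["sample_id"].to_numpy(dtype=object)

    def sex_of(self, sample_ids) -> np.ndarray:
        s = self.table.set_index("sample_id")["sex"]
        ids = np.asarray(sample_ids, dtype=object)
        unknown = set(ids) - set(s.index)
        if unknown:
            raise KeyError(f"sample ids not in sheet: {sorted(unknown)[:3]}")
        return s.loc[ids].to_numpy(dtype=object)

    def cluster_of(self, sample_ids) -> np.ndarray:
        c = self.table.set_index("sample_id")["cluster"]
        return c.loc[np.asarray(sample_ids, dtype=object)].to_numpy()

    def counts_by_sex(self) -> dict:
        return self.table["sex"].value_counts().to_dict()


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _read_table(path, delimiter: str) -> pd.DataFrame:
    df = pd.read_csv(path, delimiter=delimiter, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    return df


def _parse_calls(df, id_col, meta_cols, token_map, kind):
    """Split a raw table into (ids, sample columns, coded calls, meta)."""
    ids = df[id_col].astype(str).to_numpy(dtype=object)
    if pd.Index(ids).has_duplicates:
        dup = pd.Index(ids)[pd.Index(ids).duplicated()][0]
        counts = pd.Index(ids).value_counts()
        hint = ""
        if (counts == 2).all():
            hint = (" — every locus id appears exactly twice; this looks like "
                    "the two-row allele dialect, which is not supported "
                    "(export the one-row coded matrix instead)")
        raise GenotypeIOError(f"duplicate locus id {dup!r}{hint}")
    sample_cols = [c for c in df.columns if c not in meta_cols and c != id_col]
    if not sample_cols:
        raise GenotypeIOError("no sample columns found")
    if len(df) == 0:
        raise GenotypeIOError("no loci in matrix body")
    calls = np.full((len(df), len(sample_cols)), MISSING, dtype=np.int8)
    for j, col in enumerate(sample_cols):
        vals = df[col].astype(str).str.strip()
        for tok, code in token_map.items():
            calls[(vals == tok).to_numpy(), j] = code
        known = vals.isin(list(token_map) + list(NULL_TOKENS))
        if not known.all():
            i = int(np.argmin(known.to_numpy()))
            raise GenotypeIOError(
                f"unparseable {kind} value {vals.iloc[i]!r} at locus "
                f"{ids[i]!r}, sample {col!r}"
            )
    return ids, np.array(sample_cols, dtype=object), calls


def _parse_meta(df, ids, columns_map, numeric_fields):
    """Collect whatever canonical metadata columns are present.

    Columns absent from the file are simply absent from the returned frame;
    downstream code treats absence as "metadata unavailable".
    """
    meta = {}
    for csv_col, fld in columns_map.items():
        if csv_col in df.columns:
            col = df[csv_col].astype(str).str.strip()
            if fld in numeric_fields:
                meta[fld] = pd.to_numeric(col.replace("", np.nan), errors="coerce")
            else:
                meta[fld] = col
    out = pd.DataFrame(meta)
    out.index = pd.Index(ids)
    return out


def _validate_stored_call_rate(matrix, tol=1e-6):
    if "call_rate" not in matrix.meta.columns:
        return
    stored = matrix.meta["call_rate"].to_numpy(dtype=float)
    recomputed = matrix.call_rate()
    ok = np.isnan(stored) | (np.abs(stored - recomputed) <= tol + 0.005)
    # DArT reports CallRate rounded; allow printed precision, warn beyond it
    if not ok.all():
        i = int(np.argmin(ok))
        warnings.warn(
            f"stored CallRate {stored[i]:.4f} disagrees with recomputed "
            f"{recomputed[i]:.4f} at locus {matrix.locus_ids[i]!r}",
            stacklevel=3,
        )


def read_snp_csv(path, delimiter: str = ",") -> SnpMatrix:
    """Read a one-row coded DArTseq SNP matrix.

    The header must contain ``AlleleID``; every non-metadata column is taken
    as a sample.  Cells must be 0/1/2 or a null token.
    """
    df = _read_table(path, delimiter)
    if "AlleleID" not in df.columns:
        raise GenotypeIOError(f"{path}: header must contain an AlleleID column")
    token_map = {"0": HOM_REF, "1": HOM_ALT, "2": HET}
    ids, samples, calls = _parse_calls(df, "AlleleID", SNP_META_COLUMNS, token_map, "SNP")
    meta = _parse_meta(df, ids, SNP_META_COLUMNS, _SNP_NUMERIC_META)
    m = SnpMatrix(locus_ids=ids, sample_ids=samples, calls=calls, meta=meta)
    _validate_stored_call_rate(m)
    return m


def read_pa_csv(path, delimiter: str = ",") -> PaMatrix:
    """Read a SilicoDArT presence/absence matrix (1 present / 0 absent)."""
    df = _read_table(path, delimiter)
    id_col = "CloneID" if "CloneID" in df.columns else "AlleleID"
    if id_col not in df.columns:
        raise GenotypeIOError(f"{path}: header must contain CloneID or AlleleID")
    token_map = {"0": ABSENT, "1": PRESENT}
    ids, samples, calls = _parse_calls(df, id_col, PA_META_COLUMNS, token_map, "PA")
    meta = _parse_meta(df, ids, PA_META_COLUMNS, _PA_NUMERIC_META)
    m = PaMatrix(locus_ids=ids, sample_ids=samples, calls=calls, meta=meta)
    _validate_stored_call_rate(m)
    return m


_SEX_ALIASES = {
    "m": SEX_MALE, "male": SEX_MALE,
    "f": SEX_FEMALE, "female": SEX_FEMALE,
    "u": SEX_UNKNOWN, "unknown": SEX_UNKNOWN, "na": SEX_UNKNOWN, "": SEX_UNKNOWN,
}


def read_sample_sheet(path, delimiter: str = ",") -> SampleSheet:
    """Read a sample sheet CSV with columns sample_id, sex[, site, cluster]."""
    df = _read_table(path, delimiter)
    cols = {c.lower(): c for c in df.columns}
    id_col = next((cols[k] for k in ("sample_id", "id", "sample") if k in cols), None)
    sex_col = next((cols[k] for k in ("sex", "phenotypic_sex") if k in cols), None)
    if id_col is None or sex_col is None:
        raise GenotypeIOError(f"{path}: need sample id and sex columns")
    sex = df[sex_col].astype(str).str.strip().str.lower().map(_SEX_ALIASES)
    if sex.isna().any():
        bad = df[sex_col][sex.isna()].iloc[0]
        raise GenotypeIOError(f"unrecognised sex value {bad!r}")
    out = pd.DataFrame({
        "sample_id": df[id_col].astype(str).str.strip(),
        "sex": sex,
        "site": df[cols["site"]].astype(str) if "site" in cols else "",
        "cluster": (pd.to_numeric(df[cols["cluster"]].replace("", np.nan),
                                  errors="coerce").astype("Int64")
                    if "cluster" in cols else pd.array([pd.NA] * len(df), dtype="Int64")),
    })
    return SampleSheet(out)


def check_samples_resolvable(matrix: _CodedMatrix, sheet: SampleSheet) -> None:
    """Every matrix sample id must appear in the sheet."""
    missing = set(matrix.sample_ids) - set(sheet.sample_ids)
    if missing:
        raise GenotypeIOError(
            f"matrix samples missing from sample sheet: {sorted(missing)[:5]}"
        )


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

_SNP_FIELD_TO_COL = {v: k for k, v in SNP_META_COLUMNS.items()}
_PA_FIELD_TO_COL = {v: k for k, v in PA_META_COLUMNS.items()}


def _calls_to_tokens(calls, code_map):
    out = np.full(calls.shape, NULL_TOKENS[0], dtype=object)
    for code, tok in code_map.items():
        out[calls == code] = tok
    return out


def _write_matrix(matrix, path, id_col, field_to_col, code_map, delimiter):
    body = pd.DataFrame(
        _calls_to_tokens(matrix.calls, code_map), columns=matrix.sample_ids
    )
    out = pd.DataFrame({id_col: matrix.locus_ids})
    for fld in matrix.meta.columns:
        col = field_to_col.get(fld)
        if col is not None and col != id_col:
            out[col] = matrix.meta[fld].to_numpy()
    out = pd.concat([out, body], axis=1)
    out.to_csv(path, sep=delimiter, index=False)


def write_snp_csv(matrix: SnpMatrix, path, delimiter: str = ",") -> None:
    code_map = {HOM_REF: "0", HOM_ALT: "1", HET: "2"}
    m2 = matrix.meta.copy()
    m2["allele_id"] = matrix.locus_ids  # locus id is the AlleleID on disk
    _write_matrix(
        SnpMatrix(matrix.locus_ids, matrix.sample_ids, matrix.calls, m2),
        path, "AlleleID", _SNP_FIELD_TO_COL, code_map, delimiter,
    )


def write_pa_csv(matrix: PaMatrix, path, delimiter: str = ",") -> None:
    code_map = {ABSENT: "0", PRESENT: "1"}
    m2 = matrix.meta.copy()
    m2["clone_id"] = matrix.locus_ids
    _write_matrix(
        PaMatrix(matrix.locus_ids, matrix.sample_ids, matrix.calls, m2),
        path, "CloneID", _PA_FIELD_TO_COL, code_map, delimiter,
    )


def write_sample_sheet(sheet: SampleSheet, path, delimiter: str = ",") -> None:
    sheet.table.to_csv(path, sep=delimiter, index=False)


def export_fasta(matrix: SnpMatrix, locus_ids, path) -> int:
    """Write trimmed sequences of a locus subset as FASTA (header = locus id).

    Returns the number of records written.  Intended to feed external BLAST
    searches; loci with no trimmed sequence in the metadata are skipped.
    """
    if "trimmed_sequence" not in matrix.meta.columns:
        raise GenotypeIOError("matrix metadata has no trimmed_sequence column")
    sub = matrix.meta.loc[list(locus_ids), "trimmed_sequence"]
    records = [
        SeqRecord(Seq(seq), id=str(lid), description="")
        for lid, seq in sub.items()
        if isinstance(seq, str) and seq
    ]
    return SeqIO.write(records, Path(path), "fasta")


# ---------------------------------------------------------------------------
# per-locus summaries
# ---------------------------------------------------------------------------

def recompute_locus_stats(matrix: _CodedMatrix) -> pd.DataFrame:
    """Recompute per-locus call rate, state frequencies and PIC from calls.

    For SNP matrices the frequencies are over called samples and PIC is the
    expected heterozygosity 1 - sum(p_i^2) of the two allele frequencies.
    All-missing loci get call_rate 0 and NaN frequencies.
    """
    if matrix.n_samples < 1:
        raise GenotypeIOError("matrix has no samples")
    called = matrix.called_mask()
    n_called = called.sum(axis=1).astype(float)
    out = pd.DataFrame(index=pd.Index(matrix.locus_ids))
    out["n_called"] = n_called.astype(int)
    out["call_rate"] = n_called / matrix.n_samples
    with np.errstate(invalid="ignore", divide="ignore"):
        if isinstance(matrix, SnpMatrix):
            f_ref = (matrix.calls == HOM_REF).sum(axis=1) / n_called
            f_alt = (matrix.calls == HOM_ALT).sum(axis=1) / n_called
            f_het = (matrix.calls == HET).sum(axis=1) / n_called
            p_ref = f_ref + f_het / 2.0
            out["freq_hom_ref"] = f_ref
            out["freq_hom_snp"] = f_alt
            out["freq_hets"] = f_het
            out["allele_freq_ref"] = p_ref
            out["pic"] = 1.0 - (p_ref**2 + (1.0 - p_ref) ** 2)
        else:
            out["freq_present"] = (matrix.calls == PRESENT).sum(axis=1) / n_called
    out.loc[n_called == 0, out.columns.difference(["n_called", "call_rate"])] = np.nan
    return out
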