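"""Summary-statistics and LD-matrix containers, I/O and harmonization.

Summary statistics are per-variant association records for one trait
(GWAS, pQTL or eQTL): variant identity and alleles, effect-allele
frequency, beta, SE, p and sample size.  Everything downstream (the
weighted-burden association scan, MR, colocalization, mediation) consumes
these containers, so validation and allele bookkeeping live here, together
with the two elementary transforms ``zscore`` and ``pvalue_from_z``.

Files are plain tab-delimited text.  The default column dialect is
``SNP, CHR, BP, A1 (effect), A2 (other), EAF, BETA, SE, P, N, N_CASES``;
a custom header map can be supplied to ``read_sumstats``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: palindromic (strand-ambiguous) allele pairs
PALINDROMIC_PAIRS = {frozenset("AT"), frozenset("CG")}

#: canonical column order of the in-memory representation
CANONICAL_COLUMNS = [
    "variant_id", "chromosome", "position", "effect_allele", "other_allele",
    "eaf", "beta", "se", "p", "n", "n_cases",
]

#: default file-header -> canonical-field map
DEFAULT_DIALECT = {
    "SNP": "variant_id",
    "CHR": "chromosome",
    "BP": "position",
    "A1": "effect_allele",
    "A2": "other_allele",
    "EAF": "eaf",
    "BETA": "beta",
    "SE": "se",
    "P": "p",
    "N": "n",
    "N_CASES": "n_cases",
}

MANDATORY_FIELDS = [
    "variant_id", "chromosome", "position", "effect_allele", "other_allele",
    "beta", "se",
]


class SumstatsFormatError(ValueError):
    """A summary-statistics file cannot be interpreted."""


@dataclass
class SummaryStats:
    """Per-variant association records for a single trait.

    ``records`` is a DataFrame in canonical columns; ``variant_id`` is
    unique within it.  ``trait_type`` is ``"binary"`` (beta on the
    log-odds scale) or ``"quantitative"`` (beta in SD units).
    """

    trait_name: str
    trait_type: str
    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.records["variant_id"].duplicated().any():
            raise ValueError("duplicate variant_id in summary statistics")

    def __len__(self) -> int:
        return len(self.records)

    def zscores(self) -> pd.Series:
        """Standardized effects beta/se, indexed like ``records``."""
        return self.records["beta"] / self.records["se"]


def zscore(beta, se):
    """Standardized effect z = beta / se (sign preserved).

    Accepts scalars or arrays; every ``se`` must be positive.
    """
    se_arr = np.asarray(se, dtype=float)
    if np.any(se_arr <= 0) or not np.all(np.isfinite(se_arr)):
        raise ValueError("se must be finite and > 0")
    return np.asarray(beta, dtype=float) / se_arr if np.ndim(beta) else float(beta) / float(se)


def pvalue_from_z(z):
    """Two-sided normal p-value, p = 2*Phi(-|z|), tail-accurate.

    Uses the complementary-error-function survival tail, accurate to
    relative error well below 1e-10 down to p ~ 1e-300.  Exact zeros from
    underflow (|z| > ~38.6) are clipped to the smallest positive float so
    downstream log-scale arithmetic stays finite.
    """
    z_arr = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z_arr)):
        raise ValueError("z must be finite")
    p = 2.0 * stats.norm.sf(np.abs(z_arr))
    p = np.maximum(p, np.nextafter(0.0, 1.0))
    p = np.minimum(p, 1.0)
    return float(p) if np.ndim(z) == 0 else p


def is_palindromic(a1, a2) -> bool:
    """True for strand-ambiguous A/T or C/G variants."""
    return frozenset((a1, a2)) in PALINDROMIC_PAIRS


def read_sumstats(path, trait_name: str = "", trait_type: str = "quantitative",
                  dialect: dict | None = None) -> SummaryStats:
    """Read a tab-delimited summary-statistics file.

    Rows failing validation (alleles outside {A,C,G,T} or equal,
    position < 1, se <= 0, eaf outside [0,1], non-finite beta) are dropped
    and counted in the log; alleles are upper-cased before validation.

    Raises
    ------
    SumstatsFormatError
        if a mandatory column is missing or the file is empty.
    """
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    try:
        raw = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    except pd.errors.EmptyDataError:
        raise SumstatsFormatError(f"{path}: empty file") from None
    if raw.empty:
        raise SumstatsFormatError(f"{path}: no data rows")
    df = raw.rename(columns=dialect)
    for fieldname in MANDATORY_FIELDS:
        if fieldname not in df.columns:
            src = {v: k for k, v in dialect.items()}.get(fieldname, fieldname)
            raise SumstatsFormatError(f"{path}: missing mandatory column {src!r}")
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[CANONICAL_COLUMNS].copy()
    df["variant_id"] = df["variant_id"].astype(str)
    df["chromosome"] = df["chromosome"].astype(str)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    for col in ("eaf", "beta", "se", "p", "n", "n_cases"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["position"] = pd.to_numeric(df["position"], errors="coerce")

    ok = (
        df["effect_allele"].isin(NUCLEOTIDES)
        & df["other_allele"].isin(NUCLEOTIDES)
        & (df["effect_allele"] != df["other_allele"])
        & (df["position"] >= 1)
        & df["position"].notna()
        & np.isfinite(df["beta"])
        & (df["se"] > 0)
        & (df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1)))
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("read_sumstats(%s): dropped %d invalid rows", path, n_dropped)
    df = df[ok].reset_index(drop=True)
    df["position"] = df["position"].astype(int)
    ss = SummaryStats(trait_name=trait_name or str(path), trait_type=trait_type,
                      records=df)
    ss.n_dropped = n_dropped
    return ss


def write_sumstats(ss: SummaryStats, path) -> None:
    """Write a SummaryStats in the default TSV dialect (inverse of read)."""
    inv = {v: k for k, v in DEFAULT_DIALECT.items()}
    out = ss.records[CANONICAL_COLUMNS].rename(columns=inv)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# harmonization

_KEEP = ("match", "strand_flip", "palindromic_aligned")
_FLIP = ("swap", "strand_flip_swap", "palindromic_flipped")


def _classify(e1, e2, o1, o2, eaf_exp, eaf_out, lo, hi):
    """Disposition of one shared variant; returns (disposition, flip)."""
    if is_palindromic(e1, e2):
        if {o1, o2} != {e1, e2}:
            return "mismatch", False
        if not np.isfinite(eaf_exp) or not np.isfinite(eaf_out):
            return "palindromic_missing_eaf", False
        if lo <= eaf_exp <= hi or lo <= eaf_out <= hi:
            return "palindromic_ambiguous", False
        # orientation by allele labels, then confirmed/overruled by
        # frequency concordance (a discordant frequency implies the two
        # studies reported opposite strands)
        base_flip = o1 == e2
        aligned_eaf = 1.0 - eaf_out if base_flip else eaf_out
        if (eaf_exp - 0.5) * (aligned_eaf - 0.5) > 0:
            return ("palindromic_flipped" if base_flip else "palindromic_aligned",
                    base_flip)
        return ("palindromic_aligned" if base_flip else "palindromic_flipped",
                not base_flip)
    if o1 == e1 and o2 == e2:
        return "match", False
    if o1 == e2 and o2 == e1:
        return "swap", True
    c1, c2 = COMPLEMENT.get(o1), COMPLEMENT.get(o2)
    if c1 == e1 and c2 == e2:
        return "strand_flip", False
    if c1 == e2 and c2 == e1:
        return "strand_flip_swap", True
    return "mismatch", False


def harmonize(exposure: SummaryStats, outcome: SummaryStats,
              af_ambiguity: tuple[float, float] = (0.42, 0.58)):
    """Express outcome effects per copy of the exposure's effect allele.

    Matching alleles pass through; swapped alleles flip the outcome beta
    and complement its eaf; strand-flipped alleles are re-keyed by
    complement then matched; palindromic variants with either dataset's
    eaf inside the closed ambiguity window (or missing) are removed;
    variants absent from either dataset or with irreconcilable alleles are
    removed.  Returns ``(paired, dispositions)``: the paired instrument
    table (exposure allele orientation) and a per-variant disposition log.
    """
    lo, hi = af_ambiguity
    exp = exposure.records.add_suffix("_exp").rename(
        columns={"variant_id_exp": "variant_id"})
    out = outcome.records.add_suffix("_out").rename(
        columns={"variant_id_out": "variant_id"})
    merged = exp.merge(out, on="variant_id", how="outer", indicator=True)

    disp = np.full(len(merged), "", dtype=object)
    flip = np.zeros(len(merged), dtype=bool)
    both = merged["_merge"] == "both"
    disp[(merged["_merge"] == "left_only").to_numpy()] = "absent_outcome"
    disp[(merged["_merge"] == "right_only").to_numpy()] = "absent_exposure"

    sub = merged[both]
    results = [
        _classify(r.effect_allele_exp, r.other_allele_exp,
                  r.effect_allele_out, r.other_allele_out,
                  r.eaf_exp if r.eaf_exp == r.eaf_exp else np.nan,
                  r.eaf_out if r.eaf_out == r.eaf_out else np.nan,
                  lo, hi)
        for r in sub.itertuples()
    ]
    disp[both.to_numpy()] = [d for d, _ in results]
    flip[both.to_numpy()] = [f for _, f in results]

    dispositions = pd.DataFrame({
        "variant_id": merged["variant_id"],
        "disposition": disp,
    })
    keep = np.isin(disp, _KEEP + _FLIP)
    paired = merged[keep].copy()
    fl = flip[keep]
    paired.loc[fl, "beta_out"] = -paired.loc[fl, "beta_out"]
    paired.loc[fl, "eaf_out"] = 1.0 - paired.loc[fl, "eaf_out"]
    paired = pd.DataFrame({
        "variant_id": paired["variant_id"],
        "chromosome": paired["chromosome_exp"],
        "position": paired["position_exp"],
        "effect_allele": paired["effect_allele_exp"],
        "other_allele": paired["other_allele_exp"],
        "eaf_exposure": paired["eaf_exp"],
        "beta_exposure": paired["beta_exp"],
        "se_exposure": paired["se_exp"],
        "n_exposure": paired["n_exp"],
        "eaf_outcome": paired["eaf_out"],
        "beta_outcome": paired["beta_out"],
        "se_outcome": paired["se_out"],
        "n_outcome": paired["n_out"],
        "disposition": disp[keep],
    }).reset_index(drop=True)
    n_removed = int(len(merged) - keep.sum())
    if n_removed:
        logger.info("harmonize: %d variants removed (%s)", n_removed,
                    pd.Series(disp[~keep]).value_counts().to_dict())
    return paired, dispositions


# ---------------------------------------------------------------------------
# LD matrices

@dataclass
class LDMatrix:
    """Variant-indexed correlation matrix from a reference panel."""

    variant_ids: list
    r: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.variant_ids = list(self.variant_ids)
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.variant_ids)
        if self.r.shape != (n, n):
            raise ValueError("LD matrix shape does not match variant list")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix not symmetric")
        if np.any(np.abs(self.r) > 1 + 1e-8):
            raise ValueError("LD entries must lie in [-1, 1]")

    def index(self, ids) -> np.ndarray:
        pos = {v: i for i, v in enumerate(self.variant_ids)}
        try:
            return np.array([pos[v] for v in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"variant {exc.args[0]!r} absent from LD matrix") from None

    def submatrix(self, ids) -> "LDMatrix":
        idx = self.index(ids)
        return LDMatrix(list(ids), self.r[np.ix_(idx, idx)])

    def regularized(self, lam: float = 0.01) -> "LDMatrix":
        """Ridge-regularize: add ``lam`` to the diagonal, renormalize to
        unit diagonal.  Guarantees positive-definiteness (finite reference
        panels yield rank-deficient sample correlations)."""
        r = self.r + lam * np.eye(len(self.variant_ids))
        d = 1.0 / np.sqrt(np.diag(r))
        return LDMatrix(self.variant_ids, r * np.outer(d, d))


def write_ld(ld: LDMatrix, ids_path, matrix_path) -> None:
    """Two-file LD format: one variant ID per line + whitespace matrix."""
    with open(ids_path, "w") as fh:
        fh.write("\n".join(map(str, ld.variant_ids)) + "\n")
    np.savetxt(matrix_path, ld.r, fmt="%.10g")


def read_ld(ids_path, matrix_path) -> LDMatrix:
    with open(ids_path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    r = np.loadtxt(matrix_path, ndmin=2)
    return LDMatrix(ids, r)


def read_ld_long(path) -> LDMatrix:
    """Long-format LD: tab-delimited ``id1, id2, r`` (symmetric fill,
    unit diagonal for unlisted self-pairs)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id1", "id2", "r"])
    ids = list(pd.unique(df[["id1", "id2"]].to_numpy().ravel()))
    pos = {v: i for i, v in enumerate(ids)}
    r = np.eye(len(ids))
    for row in df.itertuples():
        i, j = pos[row.id1], pos[row.id2]
        r[i, j] = r[j, i] = row.r
    return LDMatrix(ids, r)
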