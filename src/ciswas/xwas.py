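"""FUSION-style weighted-burden association scan (PWAS/TWAS).

For each gene, the association statistic combines GWAS z-scores with the
gene's cis prediction weights under an LD reference:

    z_assoc = (sum_k w_k z_k) / sqrt(w' V w)

where V is the (regularized) LD correlation submatrix of the weighted
variants.  Genes first pass a heritability gate (cross-validated
prediction p-value), then the scan is FDR-adjusted across the surviving
panel with Benjamini-Hochberg.  PWAS and TWAS are the same operation run
on different weight panels; nothing here distinguishes the molecular
layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats_io import (COMPLEMENT, LDMatrix, SummaryStats, is_palindromic,
                          pvalue_from_z)

logger = logging.getLogger(__name__)

WEIGHT_COLUMNS = ["gene_id", "model_tag", "variant_id", "effect_allele",
                  "other_allele", "weight", "chromosome", "position"]
SIDECAR_COLUMNS = ["gene_id", "model_tag", "cv_r2", "gate_p"]


@dataclass
class WeightSet:
    """A gene/protein's cis prediction model.

    ``entries`` holds one row per variant with a nonzero weight
    (columns: variant_id, chromosome, position, effect_allele,
    other_allele, weight).  ``cv_r2`` is the out-of-sample R² of the
    selected model; ``gate_p`` the heritability-gate p-value.
    """

    gene_id: str
    model_tag: str
    entries: pd.DataFrame = field(repr=False)
    cv_r2: float = float("nan")
    gate_p: float = float("nan")

    def __post_init__(self) -> None:
        if self.model_tag == "top1" and (self.entries["weight"] != 0).sum() > 1:
            raise ValueError("top1 model must have exactly one nonzero weight")


@dataclass
class AssocResult:
    """One gene-outcome association from the weighted-burden scan."""

    gene_id: str
    outcome_name: str
    z_assoc: float
    p: float
    q: float = float("nan")
    n_snps_used: int = 0
    note: str = ""


def heritability_gate(weightset: WeightSet, alpha: float = 0.01):
    """Gate on cis heritability: pass iff gate_p < alpha (strict).

    Returns ``(passed, disposition)``; a missing gate_p fails with
    disposition ``"untested"``.
    """
    gp = weightset.gate_p
    if gp is None or not np.isfinite(gp):
        return False, "untested"
    return (gp < alpha), ("pass" if gp < alpha else "gated")


def _orient_weights(entries: pd.DataFrame, gwas: pd.DataFrame):
    """Align weight effect alleles to the GWAS orientation.

    Returns the merged frame with a ``w`` column (sign-flipped where the
    GWAS reports the opposite allele) and a count of irreconcilable
    variants.  Palindromic variants are oriented by allele labels (weight
    panels carry no allele frequency to disambiguate strand).
    """
    m = entries.merge(gwas, on="variant_id", how="inner",
                      suffixes=("_w", "_g"))
    if m.empty:
        return m.assign(w=[]), 0
    e1 = m["effect_allele_w"].to_numpy()
    e2 = m["other_allele_w"].to_numpy()
    o1 = m["effect_allele_g"].to_numpy()
    o2 = m["other_allele_g"].to_numpy()
    c1 = np.array([COMPLEMENT.get(a, "?") for a in o1])
    c2 = np.array([COMPLEMENT.get(a, "?") for a in o2])
    direct = (o1 == e1) & (o2 == e2)
    swap = (o1 == e2) & (o2 == e1)
    cdirect = (c1 == e1) & (c2 == e2) & ~direct & ~swap
    cswap = (c1 == e2) & (c2 == e1) & ~direct & ~swap
    ok = direct | swap | cdirect | cswap
    flip = swap | cswap
    m = m[ok].copy()
    m["w"] = np.where(flip[ok], -m["weight"], m["weight"])
    return m, int((~ok).sum())


def assoc_z(weights: WeightSet, gwas: SummaryStats, ld: LDMatrix) -> AssocResult:
    """The weighted-burden z statistic for one gene.

    GWAS z-scores are recomputed from beta/se (file p-values are
    advisory).  Weighted variants missing from the GWAS are dropped (no
    imputation), noted in the result; the LD submatrix is
    ridge-regularized before the quadratic form.
    """
    entries = weights.entries
    active = entries[entries["weight"] != 0]
    if active.empty:
        return AssocResult(weights.gene_id, gwas.trait_name, np.nan, np.nan,
                           note="no nonzero weights")
    gwas_cols = gwas.records[["variant_id", "effect_allele", "other_allele",
                              "beta", "se"]]
    merged, n_mismatch = _orient_weights(active, gwas_cols)
    merged = merged[np.isfinite(merged["se"]) & (merged["se"] > 0)]
    if merged.empty:
        return AssocResult(weights.gene_id, gwas.trait_name, np.nan, np.nan,
                           note="no overlap")
    notes = []
    n_missing = len(active) - len(merged)
    if n_missing:
        dropped_mass = 1.0 - np.abs(merged["w"]).sum() / np.abs(active["weight"]).sum()
        notes.append(f"dropped {n_missing} weighted variants "
                     f"({dropped_mass:.2f} of weight mass)")
        logger.info("assoc_z(%s): %s", weights.gene_id, notes[-1])
    if n_mismatch:
        notes.append(f"{n_mismatch} allele mismatches")
    ids = list(merged["variant_id"])
    w = merged["w"].to_numpy()
    z = (merged["beta"] / merged["se"]).to_numpy()
    v = ld.submatrix(ids).regularized().r
    denom = float(w @ v @ w)
    if denom <= 0:
        raise FloatingPointError("non-positive quadratic form after "
                                 "LD regularization")
    z_assoc = float(w @ z) / np.sqrt(denom)
    return AssocResult(weights.gene_id, gwas.trait_name, z_assoc,
                       pvalue_from_z(z_assoc), n_snps_used=len(ids),
                       note="; ".join(notes))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def panel_scan(panel, gwas: SummaryStats, ld_store,
               gate_alpha: float = 0.01, fdr_alpha: float = 0.05):
    """Scan a weight panel against one GWAS.

    Applies the heritability gate, computes the burden z per surviving
    gene, then BH-adjusts across the surviving panel for this outcome.
    ``ld_store`` is either a single LDMatrix covering all variants or a
    mapping gene_id -> LDMatrix.  Returns ``(results, log)`` DataFrames;
    ``significant`` flags q < fdr_alpha.
    """
    rows, log = [], []
    for ws in panel:
        passed, disposition = heritability_gate(ws, gate_alpha)
        log.append({"gene_id": ws.gene_id, "stage": "heritability_gate",
                    "disposition": disposition, "gate_p": ws.gate_p})
        if not passed:
            continue
        ld = ld_store[ws.gene_id] if isinstance(ld_store, dict) else ld_store
        res = assoc_z(ws, gwas, ld)
        if not np.isfinite(res.z_assoc):
            log.append({"gene_id": ws.gene_id, "stage": "assoc_z",
                        "disposition": res.note or "failed", "gate_p": np.nan})
            continue
        rows.append(res)
    if not rows:
        logger.warning("panel_scan: no genes survived the heritability gate")
        return (pd.DataFrame(columns=["gene_id", "outcome", "z", "p", "q",
                                      "n_snps_used", "significant", "note"]),
                pd.DataFrame(log))
    out = pd.DataFrame({
        "gene_id": [r.gene_id for r in rows],
        "outcome": [r.outcome_name for r in rows],
        "z": [r.z_assoc for r in rows],
        "p": [r.p for r in rows],
        "n_snps_used": [r.n_snps_used for r in rows],
        "note": [r.note for r in rows],
    })
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q"] < fdr_alpha
    out = out[["gene_id", "outcome", "z", "p", "q", "n_snps_used",
               "significant", "note"]]
    return out, pd.DataFrame(log)


# ---------------------------------------------------------------------------
# weight-file I/O (gene_id, model_tag, variant columns + per-gene sidecar)

def write_weight_panel(panel, weights_path, sidecar_path) -> None:
    rows, side = [], []
    for ws in panel:
        e = ws.entries.copy()
        e.insert(0, "gene_id", ws.gene_id)
        e.insert(1, "model_tag", ws.model_tag)
        rows.append(e[WEIGHT_COLUMNS])
        side.append({"gene_id": ws.gene_id, "model_tag": ws.model_tag,
                     "cv_r2": ws.cv_r2, "gate_p": ws.gate_p})
    pd.concat(rows, ignore_index=True).to_csv(weights_path, sep="\t", index=False)
    pd.DataFrame(side, columns=SIDECAR_COLUMNS).to_csv(sidecar_path, sep="\t",
                                                       index=False)


def read_weight_panel(weights_path, sidecar_path):
    """The sidecar is the panel authority: genes whose selected model has
    no nonzero weights round-trip as empty WeightSets (so the scan can
    log them) rather than vanishing."""
    wdf = pd.read_csv(weights_path, sep="\t",
                      dtype={"chromosome": str, "gene_id": str})
    sdf = pd.read_csv(sidecar_path, sep="\t", dtype={"gene_id": str})
    cols = ["variant_id", "chromosome", "position", "effect_allele",
            "other_allele", "weight"]
    by_gene = dict(tuple(wdf.groupby("gene_id", sort=False)))
    panel = []
    for row in sdf.itertuples():
        grp = by_gene.get(row.gene_id)
        entries = (grp[cols].reset_index(drop=True) if grp is not None
                   else pd.DataFrame(columns=cols))
        panel.append(WeightSet(gene_id=row.gene_id,
                               model_tag=str(row.model_tag),
                               entries=entries,
                               cv_r2=float(row.cv_r2),
                               gate_p=float(row.gate_p)))
    return panel
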