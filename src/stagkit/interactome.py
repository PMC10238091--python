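"""High-confidence interactor filtering and overlap-enrichment statistics.

Differential-abundance tables (one row per protein, with a log2 fold change
for acute cohesin degradation vs untreated, an unadjusted p-value, an IgG
detection flag and a knockdown fold change) are filtered to high-confidence
interactors; overlap of interactor sets with reference interactomes is
tested by the upper-tail hypergeometric distribution with Benjamini-Hochberg
correction across tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

REQUIRED_COLUMNS = ("protein_id", "log2fc", "p_value", "detected_in_igg", "sirna_log2fc")

#: Exclusion reasons in the order they are tested; every excluded record is
#: annotated with the first failing rule so ledgers are reproducible.
EXCLUSION_ORDER = ("igg", "fold_change", "p_value", "sirna")


@dataclass(frozen=True)
class FilterParams:
    """Thresholds for high-confidence interactors: |log2FC| > lfc_min
    (default log2 of 1.5), p < p_max, never detected in IgG controls, and
    knockdown-sensitive (sirna_log2fc <= -lfc_min; records missing the
    knockdown field fail the rule)."""

    lfc_min: float = 0.58
    p_max: float = 0.1
    require_not_igg: bool = True
    sirna_rule: bool = True

    def __post_init__(self):
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be non-negative")


@dataclass(frozen=True)
class EnrichmentResult:
    query_size: int
    reference_size: int
    background_size: int
    overlap: int
    p_value: float
    fdr: float | None = None


def exclusion_reason(row, params: FilterParams) -> str | None:
    """First failing rule for one record, or None if retained."""
    if params.require_not_igg and bool(row["detected_in_igg"]):
        return "igg"
    if not abs(row["log2fc"]) > params.lfc_min:  # strict inequality
        return "fold_change"
    if not row["p_value"] < params.p_max:
        return "p_value"
    if params.sirna_rule:
        sirna = row["sirna_log2fc"]
        if pd.isna(sirna) or not sirna <= -params.lfc_min:
            return "sirna"
    return None


def filter_high_confidence(
    records: pd.DataFrame, params: FilterParams = FilterParams()
) -> tuple[set[str], pd.DataFrame]:
    """Apply the high-confidence filters.

    Returns the retained protein-id set and a per-record table with a
    ``reason`` column (empty string for retained records).
    """
    if records["protein_id"].duplicated().any():
        dups = records.loc[records["protein_id"].duplicated(), "protein_id"].tolist()
        raise ValueError(f"duplicate protein ids: {dups[:5]}")
    reasons = records.apply(lambda row: exclusion_reason(row, params) or "", axis=1)
    ledger = records[["protein_id"]].copy()
    ledger["reason"] = reasons.values if len(records) else []
    retained = set(ledger.loc[ledger["reason"] == "", "protein_id"])
    return retained, ledger


def normalize_id(protein_id: str, strip_isoform: bool = True) -> str:
    pid = protein_id.strip().casefold()
    if strip_isoform and "-" in pid:
        base, _, suffix = pid.rpartition("-")
        if suffix.isdigit():
            pid = base
    return pid


def intersect_interactomes(list_a, list_b, strip_isoform: bool = True) -> set[str]:
    """Exact intersection after id normalisation (case-fold and, optionally,
    stripping numeric isoform suffixes like ``P12345-2``)."""
    a = {normalize_id(x, strip_isoform) for x in list_a}
    b = {normalize_id(x, strip_isoform) for x in list_b}
    return a & b


def hypergeom_enrichment(query, reference, background) -> EnrichmentResult:
    """Upper-tail hypergeometric overlap test.

    With N = |background|, K = |reference ∩ background|, n = |query ∩
    background| and k = |query ∩ reference|, p = P(X >= k) for X ~
    Hypergeom(N, K, n). Query/reference members outside the background are
    clipped with a warning.
    """
    import warnings

    background = set(background)
    if not background:
        raise ValueError("empty background set")
    query, reference = set(query), set(reference)
    n_clip = len(query - background) + len(reference - background)
    if n_clip:
        warnings.warn(
            f"{len(query - background)} query and {len(reference - background)} "
            "reference ids outside the background were clipped",
            stacklevel=2,
        )
        query &= background
        reference &= background
    N, K, n = len(background), len(reference), len(query)
    k = len(query & reference)
    p = float(hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(
        query_size=n, reference_size=K, background_size=N, overlap=k,
        p_value=min(p, 1.0),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_with_fdr(queries: dict[str, set], reference, background) -> pd.DataFrame:
    """Run hypergeom_enrichment for several query sets against one reference
    and BH-adjust across the family of tests."""
    names = list(queries)
    results = [hypergeom_enrichment(queries[n], reference, background) for n in names]
    fdr = bh_adjust([r.p_value for r in results])
    return pd.DataFrame(
        {
            "query": names,
            "n": [r.query_size for r in results],
            "K": [r.reference_size for r in results],
            "N": [r.background_size for r in results],
            "k": [r.overlap for r in results],
            "p_value": [r.p_value for r in results],
            "fdr": fdr,
        }
    )
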