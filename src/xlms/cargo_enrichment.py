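"""DIA cargo-enrichment statistics for flotillin-positive endosomes.

The experiment compares three conditions of three replicates each: GFP
(control transfection), SPIONS (magnetically enriched total early
endosomes), and SPIONS_IP (flotillin-immunopurified endosomes).  Proteins
enriched in SPIONS_IP over SPIONS are candidate cargo of flotillin-dependent
endocytosis.  The statistics follow label-free DIA practice with structured
missingness and no imputation:

1. categorize each protein by its valid-value pattern (background /
   SPIONs-specific / on-off / unclassified);
2. normalize SPIONS and SPIONS_IP replicates on the FLOT1+FLOT2 reference
   intensities (GFP untouched);
3. log2-transform and run an unpaired two-sample t-test (equal variance by
   default) for proteins with >= 2 valid values per side; on/off proteins get
   p = 0 by definition, untestable ones p = 1;
4. Benjamini-Hochberg adjustment;
5. call enrichment at q <= 0.05 and fold change > 1.5 (on/off proteins pass
   by definition on their observed side).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "CONDITIONS",
    "DiaMatrix",
    "EnrichmentRecord",
    "categorize_populations",
    "normalize_flot",
    "test_enrichment",
    "adjust_bh",
    "call_enriched",
    "intersect_sets",
    "run_cargo_pipeline",
]

GFP = "GFP"
SPIONS = "SPIONS"
SPIONS_IP = "SPIONS_IP"
CONDITIONS = (GFP, SPIONS, SPIONS_IP)

BACKGROUND = "background"
SPIONS_SPECIFIC = "spions_specific"
ON_OFF = "on_off"
UNCLASSIFIED = "unclassified"


@dataclass
class DiaMatrix:
    """Protein x sample intensity matrix grouped into the three conditions.

    ``data`` holds positive intensities with NaN for missing (absence is
    information here, never zero); ``groups`` maps each condition name to its
    replicate column names.
    """

    data: pd.DataFrame
    groups: dict[str, list[str]]

    def __post_init__(self) -> None:
        if set(self.groups) != set(CONDITIONS):
            raise ValueError(f"expected condition groups {CONDITIONS}, got {sorted(self.groups)}")
        for cond, cols in self.groups.items():
            missing = [c for c in cols if c not in self.data.columns]
            if missing:
                raise ValueError(f"columns for {cond} not in matrix: {missing}")
        values = self.data[self.columns].to_numpy(dtype=float)
        if values.size and not np.isnan(values).all() and np.nanmin(values) <= 0:
            raise ValueError("intensities must be positive (missing values are NaN)")

    @property
    def columns(self) -> list[str]:
        return [c for cond in CONDITIONS for c in self.groups[cond]]

    def condition(self, name: str) -> pd.DataFrame:
        return self.data[self.groups[name]]

    def valid_counts(self) -> pd.DataFrame:
        return pd.DataFrame({c: self.condition(c).notna().sum(axis=1) for c in CONDITIONS})

    def copy(self) -> "DiaMatrix":
        return DiaMatrix(self.data.copy(), {k: list(v) for k, v in self.groups.items()})


@dataclass
class EnrichmentRecord:
    """Per-protein enrichment verdict."""

    accession: str
    population: str
    log2fc: float | None
    p: float
    q: float
    enriched: bool = False
    depleted: bool = False


def categorize_populations(m: DiaMatrix) -> dict[str, str]:
    """Label each protein by its valid-value pattern across conditions.

    background: all three valid values in all three conditions.
    on_off: >= 2 valid values in exactly one of the SPIONs conditions and no
    valid value anywhere else (checked before SPIONs-specific, which it would
    otherwise always also match).
    spions_specific: no valid GFP value and >= 2 valid values in SPIONS or
    SPIONS_IP.  Anything else is unclassified.
    """
    counts = m.valid_counts()
    sizes = {c: len(m.groups[c]) for c in CONDITIONS}
    labels: dict[str, str] = {}
    for acc, row in counts.iterrows():
        g, s, sip = int(row[GFP]), int(row[SPIONS]), int(row[SPIONS_IP])
        if g == sizes[GFP] and s == sizes[SPIONS] and sip == sizes[SPIONS_IP]:
            labels[acc] = BACKGROUND
        elif g == 0 and ((s >= 2 and sip == 0) or (sip >= 2 and s == 0)):
            labels[acc] = ON_OFF
        elif g == 0 and (s >= 2 or sip >= 2):
            labels[acc] = SPIONS_SPECIFIC
        else:
            labels[acc] = UNCLASSIFIED
    return labels


def normalize_flot(
    m: DiaMatrix, references: Sequence[str] = ("FLOT1", "FLOT2")
) -> DiaMatrix:
    """Scale SPIONS / SPIONS_IP replicates onto the FLOT reference level.

    For each replicate of the two SPIONs conditions the scale factor is
    (condition grand mean of the per-replicate reference means) / (that
    replicate's reference mean); every intensity in the replicate is
    multiplied by it.  GFP columns are untouched.  After normalization each
    replicate's reference mean equals the condition grand mean, which makes
    the transform idempotent.  Both references must be quantified in every
    SPIONS and SPIONS_IP replicate.
    """
    out = m.copy()
    refs = list(references)
    missing = [r for r in refs if r not in out.data.index]
    if missing:
        raise ValueError(f"reference proteins absent from matrix: {missing}")
    for cond in (SPIONS, SPIONS_IP):
        cols = out.groups[cond]
        ref_block = out.data.loc[refs, cols]
        if ref_block.isna().any().any():
            bad = [c for c in cols if ref_block[c].isna().any()]
            raise ValueError(f"references not quantified in every {cond} replicate: {bad}")
        rep_means = ref_block.mean(axis=0)
        grand_mean = float(rep_means.mean())
        for col in cols:
            out.data[col] = out.data[col] * (grand_mean / float(rep_means[col]))
    return out


def test_enrichment(
    m: DiaMatrix,
    populations: Mapping[str, str],
    welch: bool = False,
) -> pd.DataFrame:
    """Per-protein log2 fold change (SPIONS_IP - SPIONS) and t-test p-value.

    Intensities are log2-transformed (the matrix is expected to be
    normalized already).  Proteins with >= 2 valid values on both sides get
    an unpaired two-sided t-test (classic equal-variance by default; Welch
    via ``welch=True``).  On/off proteins are significant by definition
    (p = 0, fold change absent); proteins matching neither rule get p = 1.
    """
    s_log = np.log2(m.condition(SPIONS))
    sip_log = np.log2(m.condition(SPIONS_IP))
    rows = []
    for acc in m.data.index:
        x = sip_log.loc[acc].dropna().to_numpy()
        y = s_log.loc[acc].dropna().to_numpy()
        pop = populations.get(acc, UNCLASSIFIED)
        log2fc: float | None = None
        if len(x) >= 1 and len(y) >= 1:
            log2fc = float(x.mean() - y.mean())
        if pop == ON_OFF:
            p = 0.0
            log2fc = None if (len(x) == 0 or len(y) == 0) else log2fc
        elif len(x) >= 2 and len(y) >= 2:
            sx, sy = x.std(ddof=1), y.std(ddof=1)
            if sx == 0 and sy == 0:
                p = 1.0 if x.mean() == y.mean() else 0.0
            else:
                p = float(stats.ttest_ind(x, y, equal_var=not welch).pvalue)
        else:
            p = 1.0
        rows.append({"accession": acc, "population": pop, "log2fc": log2fc, "p": p})
    return pd.DataFrame(rows).set_index("accession")


def adjust_bh(p_values: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_enriched(
    results: pd.DataFrame,
    m: DiaMatrix,
    q_max: float = 0.05,
    fc_min: float = 1.5,
) -> pd.DataFrame:
    """Apply the q-value and fold-change cut-offs; return the verdict table.

    Enriched: q <= q_max and fold change > fc_min toward SPIONS_IP, or an
    on/off protein observed in SPIONS_IP.  Depleted mirrors the rule toward
    SPIONS.  The fold-change cut-off is applied on the log2 scale as
    |log2fc| > log2(fc_min).
    """
    out = results.copy()
    if "q" not in out.columns:
        out["q"] = adjust_bh(out["p"])
    lfc_min = np.log2(fc_min)
    counts = m.valid_counts()
    enriched, depleted = [], []
    for acc, row in out.iterrows():
        if row["population"] == ON_OFF:
            side_ip = counts.loc[acc, SPIONS_IP] >= 2 and counts.loc[acc, SPIONS] == 0
            enriched.append(bool(side_ip))
            depleted.append(not side_ip)
            continue
        sig = row["q"] <= q_max and row["log2fc"] is not None and not pd.isna(row["log2fc"])
        enriched.append(bool(sig and row["log2fc"] > lfc_min))
        depleted.append(bool(sig and row["log2fc"] < -lfc_min))
    out["enriched"] = enriched
    out["depleted"] = depleted
    return out


def intersect_sets(set_a: Iterable[str], set_b: Iterable[str]) -> tuple[int, list[str]]:
    """Exact accession-set intersection: (count, sorted members)."""
    common = sorted(set(set_a) & set(set_b))
    return len(common), common


def run_cargo_pipeline(
    m: DiaMatrix,
    references: Sequence[str] = ("FLOT1", "FLOT2"),
    q_max: float = 0.05,
    fc_min: float = 1.5,
    welch: bool = False,
) -> pd.DataFrame:
    """Full cargo statistics: categorize, normalize, test, adjust, call.

    Returns a per-protein DataFrame with population, log2fc, p, q, and the
    enriched/depleted verdicts.
    """
    populations = categorize_populations(m)
    normalized = normalize_flot(m, references)
    results = test_enrichment(normalized, populations, welch=welch)
    results["q"] = adjust_bh(results["p"])
    return call_enriched(results, normalized, q_max=q_max, fc_min=fc_min)


def records_from_frame(results: pd.DataFrame) -> list[EnrichmentRecord]:
    return [
        EnrichmentRecord(
            accession=acc,
            population=row["population"],
            log2fc=None if pd.isna(row["log2fc"]) else float(row["log2fc"]),
            p=float(row["p"]),
            q=float(row["q"]),
            enriched=bool(row["enriched"]),
            depleted=bool(row["depleted"]),
        )
        for acc, row in results.iterrows()
    ]


__all__.append("records_from_frame")
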