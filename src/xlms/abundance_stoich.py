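"""iBAQ-based complex stoichiometry and abundance/cross-link summaries.

iBAQ values are proportional to molar protein amounts, so within one complex
the ratio of subunit iBAQ values estimates subunit copy numbers (e.g. the
V-ATPase V1 sector's A3 B3 E3 G3 D1 F1 C1 H1 pattern).  This module turns an
abundance table into integer copy-number estimates against a single-copy
reference subunit, correlates cross-link yield with protein abundance, and
summarizes how CSMs of different protein classes split between disrupted
(DR) and intact (IT) cross-linking conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .xl_tables import CsmRecord, DR, IT, NA

logger = logging.getLogger(__name__)

__all__ = [
    "StoichiometryEstimate",
    "estimate_stoichiometry",
    "abundance_link_summary",
    "condition_class_distribution",
    "read_abundance_table",
]


@dataclass
class StoichiometryEstimate:
    subunit: str
    relative_abundance: float
    copies: int
    reference: str


def read_abundance_table(path, sample_prefix: str | None = "iBAQ ", index_col: str = "accession"):
    """Read a CSV/TSV abundance table into a proteins x samples DataFrame.

    MaxQuant-style exports keep per-sample values in columns named
    ``"iBAQ <sample>"``; pass ``sample_prefix`` to select and strip them, or
    ``None`` to take every non-index column as a sample.
    """
    path = str(path)
    sep = "\t" if path.endswith((".tsv", ".txt", ".tab")) else ","
    frame = pd.read_csv(path, sep=sep).set_index(index_col)
    if sample_prefix is not None:
        cols = [c for c in frame.columns if c.startswith(sample_prefix)]
        if cols:
            frame = frame[cols].rename(columns={c: c[len(sample_prefix):] for c in cols})
    frame = frame.apply(pd.to_numeric, errors="coerce")
    if (frame.to_numpy(dtype=float) < 0).any():
        raise ValueError("abundance table contains negative values")
    return frame


def _auto_reference(abundances: "pd.Series") -> str:
    """Pick the assumed single-copy reference: split the subunits into a low
    and a high abundance cluster at the largest log-scale gap and take the
    median member of the low cluster."""
    s = abundances.sort_values()
    if len(s) < 2:
        return s.index[0]
    logs = np.log(s.to_numpy())
    gaps = np.diff(logs)
    split = int(np.argmax(gaps)) + 1
    low = s.iloc[:split]
    if split == len(s):  # no gap: everything is one cluster
        low = s
    return low.index[len(low) // 2]


def estimate_stoichiometry(
    table: pd.DataFrame,
    subunits: Sequence[str],
    reference: str = "auto",
) -> list[StoichiometryEstimate]:
    """Estimate subunit copy numbers from an abundance table.

    Per-subunit abundance is the median across samples (robust to
    single-replicate dropouts).  ``reference`` names the assumed single-copy
    subunit, or ``"auto"`` to pick one from the lower abundance cluster.
    Copies = round(abundance / reference abundance), with a floor of 1.
    Estimates are scale-invariant: rescaling the whole table changes nothing.
    """
    missing = [s for s in subunits if s not in table.index]
    if missing:
        raise ValueError(f"subunits missing from abundance table: {missing}")
    med = table.loc[list(subunits)].median(axis=1, skipna=True)
    if med.isna().any():
        bad = list(med.index[med.isna()])
        raise ValueError(f"subunits without any abundance value: {bad}")
    ref = _auto_reference(med) if reference == "auto" else reference
    if ref not in med.index:
        raise ValueError(f"reference {ref!r} is not among the subunits")
    ref_abundance = float(med[ref])
    if ref_abundance == 0:
        raise ValueError(f"reference {ref!r} has zero abundance")
    out = []
    for sub in subunits:
        rel = float(med[sub]) / ref_abundance
        copies = max(1, int(np.floor(rel + 0.5)))
        out.append(StoichiometryEstimate(sub, rel, copies, ref))
    return out


def abundance_link_summary(
    link_counts: Mapping[str, int],
    abundances: Mapping[str, float] | pd.Series,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, float, float]:
    """Join per-protein cross-link counts with abundances; Spearman correlation.

    Returns the joined table, Spearman's rho, and a permutation p-value
    (two-sided, ``n_permutations`` label shuffles, seeded).  At least three
    proteins must carry both a count and an abundance.
    """
    ab = pd.Series(abundances, dtype=float).dropna()
    common = sorted(set(link_counts) & set(ab.index))
    if len(common) < 3:
        raise ValueError(f"only {len(common)} proteins have both values; need >= 3")
    joined = pd.DataFrame(
        {
            "accession": common,
            "link_count": [link_counts[a] for a in common],
            "abundance": [float(ab[a]) for a in common],
        }
    )
    rho = float(stats.spearmanr(joined["link_count"], joined["abundance"]).statistic)

    # permutation p: Pearson correlation of rank vectors under label shuffles
    rng = np.random.default_rng(seed)
    rx = stats.rankdata(joined["link_count"])
    ry = stats.rankdata(joined["abundance"])
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    n = len(rx)
    perms = np.stack([rng.permutation(ry) for _ in range(n_permutations)])
    rho_perm = perms @ rx / n
    p = float((1 + np.sum(np.abs(rho_perm) >= abs(rho) - 1e-12)) / (n_permutations + 1))
    return joined, rho, p


def condition_class_distribution(
    records: Iterable[CsmRecord],
    class_annotation: Mapping[str, str],
) -> dict[str, dict[str, float]]:
    """Percent of each protein class's CSMs found under DR vs IT conditions.

    A CSM counts toward a class when either of its proteins carries that
    annotation (once per class).  Records with condition NA are excluded from
    the percentages but reported per class as ``n_na``.  For every class with
    at least one DR/IT record, ``percent_dr + percent_it == 100``.
    """
    tallies: dict[str, dict[str, int]] = {}
    for rec in records:
        classes = {
            class_annotation[acc]
            for acc in (rec.protein_a, rec.protein_b)
            if acc in class_annotation
        }
        for cls in classes:
            t = tallies.setdefault(cls, {DR: 0, IT: 0, NA: 0})
            t[rec.condition] += 1
    out: dict[str, dict[str, float]] = {}
    for cls, t in tallies.items():
        n = t[DR] + t[IT]
        if n == 0 and t[NA] == 0:
            continue
        out[cls] = {
            "percent_dr": (100.0 * t[DR] / n) if n else 0.0,
            "percent_it": (100.0 * t[IT] / n) if n else 0.0,
            "n": n,
            "n_na": t[NA],
        }
    return out
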