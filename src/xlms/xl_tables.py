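"""Cross-link identification tables: reading, filtering, deduplication, classification.

A cross-linking MS search engine (e.g. XlinkX) emits one row per cross-link
spectral match (CSM).  Many CSMs can support the same unique residue-to-residue
cross-link, so counting interactions or mapping links onto structures first
requires collapsing CSMs to unique unordered (accession, residue) pairs.  This
module holds the CSM record model, the score/FDR filter, the deduplication to
unique links, and simple condition (disrupted vs intact organelle) summaries.

Residue indices are 1-based UniProt coordinates throughout the pipeline; any
export using other numbering must be adapted through the column dialect.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Condition",
    "CsmRecord",
    "CrossLinkPair",
    "FilterConfig",
    "GENERIC_DIALECT",
    "XLINKX_DIALECT",
    "read_csm_table",
    "filter_csms",
    "deduplicate_links",
    "condition_overlap",
    "subset_links",
    "write_links_tsv",
    "read_links_tsv",
]

#: Cross-linking condition of the sample a CSM came from.  DR = disrupted
#: organelles (reagent reaches the lumen), IT = intact organelles (surface
#: only), NA = condition not recorded.
DR = "DR"
IT = "IT"
NA = "NA"
Condition = str

_CONDITIONS = {DR, IT, NA}


@dataclass(frozen=True)
class CsmRecord:
    """One cross-link spectral match (one spectrum, one cross-linked peptide pair).

    ``site_a``/``site_b`` are 1-based UniProt residue indices.  A record with
    ``protein_a == protein_b`` and ``site_a == site_b`` is legal: it is a
    self-link, which in a homo-oligomer necessarily spans two protein copies.
    """

    protein_a: str
    site_a: int
    protein_b: str
    site_b: int
    score: float
    fdr_level: float
    condition: Condition = NA
    replicate: int = 1
    peptide_pair_id: str = ""

    def __post_init__(self) -> None:
        if self.site_a < 1 or self.site_b < 1:
            raise ValueError(f"residue indices are 1-based, got {self.site_a}, {self.site_b}")
        if self.score < 0:
            raise ValueError(f"negative search-engine score {self.score}")
        if self.condition not in _CONDITIONS:
            raise ValueError(f"condition must be one of {sorted(_CONDITIONS)}, got {self.condition!r}")


@dataclass(frozen=True)
class CrossLinkPair:
    """One unique unordered residue-to-residue cross-link.

    ``site_u``/``site_v`` are (accession, residue) tuples stored in canonical
    order (lexicographic by accession, then residue) so the pair is unordered.
    ``link_class`` is ``"intra"`` for two different residues of one protein,
    ``"self"`` for the same residue of one protein, ``"inter"`` for two
    different proteins.
    """

    site_u: tuple[str, int]
    site_v: tuple[str, int]
    link_class: str
    csm_count: int = 1
    conditions_seen: frozenset[str] = field(default_factory=frozenset)

    @staticmethod
    def canonical_sites(a: tuple[str, int], b: tuple[str, int]) -> tuple[tuple[str, int], tuple[str, int]]:
        return (a, b) if a <= b else (b, a)

    @staticmethod
    def classify(a: tuple[str, int], b: tuple[str, int]) -> str:
        if a[0] != b[0]:
            return "inter"
        return "self" if a[1] == b[1] else "intra"

    @classmethod
    def from_sites(
        cls,
        a: tuple[str, int],
        b: tuple[str, int],
        csm_count: int = 1,
        conditions_seen: Iterable[str] = (),
    ) -> "CrossLinkPair":
        u, v = cls.canonical_sites(a, b)
        return cls(u, v, cls.classify(u, v), csm_count, frozenset(conditions_seen))

    @property
    def accessions(self) -> tuple[str, str]:
        return (self.site_u[0], self.site_v[0])

    @property
    def key(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return (self.site_u, self.site_v)


@dataclass(frozen=True)
class FilterConfig:
    """CSM acceptance filter: minimum search-engine score and maximum FDR.

    Defaults mirror common XlinkX practice (score >= 40, 5% CSM-level FDR).
    The FDR is the search engine's per-record value; it is not recomputed here.
    """

    min_score: float = 40.0
    max_fdr: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.max_fdr <= 1):
            raise ValueError(f"max_fdr must be in (0, 1], got {self.max_fdr}")


# ---------------------------------------------------------------------------
# Table reading

#: Column dialect for the package's own generic TSV/CSV layout.
GENERIC_DIALECT: dict[str, str] = {
    "protein_a": "protein_a",
    "site_a": "site_a",
    "protein_b": "protein_b",
    "site_b": "site_b",
    "score": "score",
    "fdr": "fdr",
    "condition": "condition",
    "replicate": "replicate",
}

#: Column dialect for XlinkX-style exports.  Site columns carry the leading
#: residue letter ("K189"), which is stripped.
XLINKX_DIALECT: dict[str, str] = {
    "protein_a": "Protein Accession A",
    "site_a": "Leading Protein Position A",
    "protein_b": "Protein Accession B",
    "site_b": "Leading Protein Position B",
    "score": "Max. XlinkX Score",
    "fdr": "fdr",
    "condition": "condition",
    "replicate": "replicate",
    "strip_site_prefix": True,
}

_REQUIRED = ("protein_a", "site_a", "protein_b", "site_b", "score", "fdr")
_SITE_RE = re.compile(r"^\s*[A-Za-z]?(\d+)\s*$")


def _parse_site(value, strip_prefix: bool) -> int:
    if isinstance(value, (int,)) and not isinstance(value, bool):
        return int(value)
    if isinstance(value, float):
        if math.isnan(value) or value != int(value):
            raise ValueError(f"non-integer residue index {value!r}")
        return int(value)
    text = str(value)
    if strip_prefix:
        m = _SITE_RE.match(text)
        if not m:
            raise ValueError(f"non-integer residue index {value!r}")
        return int(m.group(1))
    try:
        return int(text)
    except ValueError as exc:
        raise ValueError(f"non-integer residue index {value!r}") from exc


def read_csm_table(
    path: str | Path,
    dialect: Mapping[str, object] | None = None,
    strict: bool = False,
) -> list[CsmRecord]:
    """Read a CSM-level cross-link identification table (CSV or TSV).

    ``dialect`` maps required field names to column names of the file
    (see :data:`GENERIC_DIALECT` and :data:`XLINKX_DIALECT`); it may carry the
    boolean entry ``strip_site_prefix`` for exports whose site columns carry a
    leading residue letter ("K12" -> 12).  Rows missing a required field are
    rejected and reported (with their row numbers) via logging, or raise if
    ``strict`` is true.  Missing file or unmapped required columns raise.
    """
    dialect = dict(GENERIC_DIALECT if dialect is None else dialect)
    strip_prefix = bool(dialect.pop("strip_site_prefix", False))

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    frame = pd.read_csv(path, sep=sep, dtype=str)

    missing_cols = [dialect[f] for f in _REQUIRED if dialect[f] not in frame.columns]
    if missing_cols:
        raise ValueError(f"{path}: required columns not found: {missing_cols}")

    records: list[CsmRecord] = []
    rejected: list[tuple[int, str]] = []
    for idx, row in frame.iterrows():
        rownum = int(idx) + 2  # 1-based, counting the header row
        try:
            values = {f: row[dialect[f]] for f in _REQUIRED}
            if any(pd.isna(v) for v in values.values()):
                raise ValueError("missing required field")
            cond_col = dialect.get("condition")
            condition = NA
            if cond_col in frame.columns and not pd.isna(row[cond_col]):
                condition = str(row[cond_col]).strip().upper()
            rep_col = dialect.get("replicate")
            replicate = 1
            if rep_col in frame.columns and not pd.isna(row[rep_col]):
                replicate = int(float(row[rep_col]))
            records.append(
                CsmRecord(
                    protein_a=str(values["protein_a"]).strip(),
                    site_a=_parse_site(values["site_a"], strip_prefix),
                    protein_b=str(values["protein_b"]).strip(),
                    site_b=_parse_site(values["site_b"], strip_prefix),
                    score=float(values["score"]),
                    fdr_level=float(values["fdr"]),
                    condition=condition,
                    replicate=replicate,
                    peptide_pair_id=str(row.get("peptide_pair_id", "") or ""),
                )
            )
        except (ValueError, KeyError) as exc:
            rejected.append((rownum, str(exc)))
    if rejected:
        msg = f"{path}: rejected {len(rejected)} rows: " + "; ".join(
            f"row {n} ({why})" for n, why in rejected[:20]
        )
        if strict:
            raise ValueError(msg)
        logger.warning(msg)
    return records


# ---------------------------------------------------------------------------
# Filtering and deduplication


def filter_csms(records: Iterable[CsmRecord], cfg: FilterConfig = FilterConfig()) -> list[CsmRecord]:
    """Keep CSMs with score >= min_score and FDR <= max_fdr, preserving order."""
    return [r for r in records if r.score >= cfg.min_score and r.fdr_level <= cfg.max_fdr]


def deduplicate_links(records: Iterable[CsmRecord]) -> list[CrossLinkPair]:
    """Collapse CSMs to unique unordered residue-to-residue cross-links.

    Records are expected to be pre-filtered.  For each unique unordered
    (accession, residue) x (accession, residue) combination one
    :class:`CrossLinkPair` is returned with the number of contributing CSMs
    and the union of conditions seen.  Output is sorted by canonical site key.
    """
    counts: dict[tuple, int] = {}
    conds: dict[tuple, set[str]] = {}
    for rec in records:
        key = CrossLinkPair.canonical_sites(
            (rec.protein_a, rec.site_a), (rec.protein_b, rec.site_b)
        )
        counts[key] = counts.get(key, 0) + 1
        conds.setdefault(key, set())
        if rec.condition != NA:
            conds[key].add(rec.condition)
    return [
        CrossLinkPair.from_sites(u, v, csm_count=counts[(u, v)], conditions_seen=conds[(u, v)])
        for (u, v) in sorted(counts)
    ]


def condition_overlap(pairs: Sequence[CrossLinkPair]) -> dict[str, float]:
    """Tally unique links seen in DR only, IT only, or both conditions.

    Returns ``{"dr_only", "it_only", "both", "total", "percent_both"}``;
    the three counts are disjoint and sum to the total.  A pair with empty
    ``conditions_seen`` is an error (its provenance is unknown).
    """
    dr_only = it_only = both = 0
    for pair in pairs:
        seen = pair.conditions_seen
        if not seen:
            raise ValueError(f"pair {pair.key} has empty conditions_seen")
        if seen == {DR}:
            dr_only += 1
        elif seen == {IT}:
            it_only += 1
        else:
            both += 1
    total = dr_only + it_only + both
    return {
        "dr_only": dr_only,
        "it_only": it_only,
        "both": both,
        "total": total,
        "percent_both": (100.0 * both / total) if total else 0.0,
    }


def subset_links(
    pairs: Iterable[CrossLinkPair], accessions: set[str]
) -> tuple[list[CrossLinkPair], int]:
    """Keep pairs with at least one side in ``accessions``.

    Returns the kept pairs and the number of distinct accessions from the set
    that actually contribute a link (e.g. how many annotated lysosomal
    proteins carry at least one cross-link).
    """
    kept: list[CrossLinkPair] = []
    contributing: set[str] = set()
    for pair in pairs:
        hit = set(pair.accessions) & accessions
        if hit:
            kept.append(pair)
            contributing |= hit
    return kept, len(contributing)


# ---------------------------------------------------------------------------
# Canonical unique-link table I/O

_LINK_COLUMNS = [
    "protein_a", "site_a", "protein_b", "site_b", "link_class", "csm_count", "conditions",
]


def write_links_tsv(pairs: Iterable[CrossLinkPair], path: str | Path) -> None:
    """Write unique links as a canonical TSV (one pair per row, canonical order)."""
    rows = [
        {
            "protein_a": p.site_u[0],
            "site_a": p.site_u[1],
            "protein_b": p.site_v[0],
            "site_b": p.site_v[1],
            "link_class": p.link_class,
            "csm_count": p.csm_count,
            "conditions": ",".join(sorted(p.conditions_seen)),
        }
        for p in pairs
    ]
    pd.DataFrame(rows, columns=_LINK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_links_tsv(path: str | Path) -> list[CrossLinkPair]:
    frame = pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str})
    pairs = []
    for _, row in frame.iterrows():
        conds = [] if pd.isna(row["conditions"]) or row["conditions"] == "" else str(row["conditions"]).split(",")
        pairs.append(
            CrossLinkPair.from_sites(
                (row["protein_a"], int(row["site_a"])),
                (row["protein_b"], int(row["site_b"])),
                csm_count=int(row["csm_count"]),
                conditions_seen=conds,
            )
        )
    return pairs


def class_tally(pairs: Iterable[CrossLinkPair]) -> dict[str, int]:
    """Three-way intra / inter / self tally of unique links.

    Self-links are reported separately: an intra-link is defined as joining
    *different* residues of one protein, so the two-way intra/inter split does
    not absorb them.
    """
    tally = {"intra": 0, "inter": 0, "self": 0}
    for pair in pairs:
        tally[pair.link_class] += 1
    return tally


__all__.append("class_tally")
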