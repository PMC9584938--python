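"""Mapping cross-links onto protein structures and checking the DSSO constraint.

DSSO bridges lysine side chains up to roughly 35 A between site atoms, so a
confidently identified cross-link whose minimal site-atom distance on a
structure exceeds that bound points at either a wrong identification or a
structure that does not represent the in-situ state (e.g. an alternative
oligomer).  This module loads PDB/mmCIF models, reconciles author residue
numbering with UniProt coordinates by pairwise alignment, evaluates every
chain assignment compatible with a link's accessions (essential for
homo-oligomers), and classifies links as satisfied / violated / unmapped.

Distances are plain Euclidean between site atoms: C-beta, falling back to
C-alpha for glycine or when C-beta is missing.  Surface-path (topological)
distances are not computed; the 35 A default is configurable to absorb the
CA-vs-CB difference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
from Bio import Align

from .xl_tables import CrossLinkPair

logger = logging.getLogger(__name__)

__all__ = [
    "ChainModel",
    "Residue",
    "StructureModel",
    "SeqMap",
    "EvalConfig",
    "MappedLink",
    "load_structure",
    "align_numbering",
    "map_link",
    "map_links",
    "summarize_violations",
    "export_link_file",
    "read_link_file",
    "identity_seqmap",
]

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M", "SEC": "U", "PYL": "O",
}


@dataclass
class Residue:
    """One amino-acid residue: author number, 3-letter name, atom coordinates (A)."""

    number: int
    name: str
    atoms: dict[str, np.ndarray]

    @property
    def one_letter(self) -> str:
        return _THREE_TO_ONE.get(self.name.upper(), "X")

    def site_atom(self) -> np.ndarray | None:
        """Site atom under the CB rule: C-beta, or C-alpha for Gly/missing CB."""
        if self.name.upper() != "GLY" and "CB" in self.atoms:
            return self.atoms["CB"]
        return self.atoms.get("CA")


@dataclass
class ChainModel:
    chain_id: str
    accession: str | None
    residues: list[Residue]

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def residue(self, number: int) -> Residue | None:
        return self._index().get(number)

    def _index(self) -> dict[int, Residue]:
        if not hasattr(self, "_res_index"):
            self._res_index = {r.number: r for r in self.residues}
        return self._res_index


@dataclass
class StructureModel:
    chains: list[ChainModel]
    model_id: str = "model"

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chain identifiers in model {self.model_id}: {ids}")

    def chain(self, chain_id: str) -> ChainModel:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    def chains_for(self, accession: str) -> list[ChainModel]:
        return [c for c in self.chains if c.accession == accession]


@dataclass
class SeqMap:
    """Author residue numbering -> UniProt index for one chain.

    ``mapping`` covers aligned identical-or-substituted positions; ``identity``
    is the fraction of identical aligned columns.
    """

    chain_id: str
    mapping: dict[int, int]
    identity: float

    def __post_init__(self) -> None:
        values = list(self.mapping.values())
        if len(set(values)) != len(values):
            raise ValueError("seq map is not injective")
        self._inverse = {v: k for k, v in self.mapping.items()}

    def author_number(self, uniprot_index: int) -> int | None:
        return self._inverse.get(uniprot_index)


@dataclass(frozen=True)
class EvalConfig:
    """Distance-evaluation settings.

    ``d_max`` is the cross-linker span between site atoms (DSSO: ~35 A).
    ``treat_homomer`` enables evaluation of every chain-pair assignment when
    several chains carry the same accession.
    """

    d_max: float = 35.0
    treat_homomer: bool = True

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")


@dataclass
class MappedLink:
    """A cross-link placed on a structure.

    ``status`` is ``satisfied`` (distance <= d_max), ``violated`` (> d_max) or
    ``unmapped`` (no placement; ``reason`` says why).  ``requires_interchain``
    marks links whose only satisfied placement spans two chains (self-links
    always do): direct evidence for an oligomeric contact.
    """

    pair: CrossLinkPair
    distance: float | None
    best_assignment: tuple[str, str] | None
    status: str
    requires_interchain: bool = False
    reason: str = ""


# ---------------------------------------------------------------------------
# Structure loading


def load_structure(
    path: str | Path,
    chain_map: Mapping[str, str] | None = None,
    model_id: str | None = None,
) -> StructureModel:
    """Load a PDB or mmCIF file into a :class:`StructureModel`.

    The first model of a multi-model file is used; waters and heteroatoms are
    dropped; alternate locations resolve to the highest-occupancy atom.
    ``chain_map`` assigns UniProt accessions to chain ids; for mmCIF input,
    accessions present in the entity annotation are used as a fallback.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()

    entity_acc: dict[str, str] = {}
    for ent in st.entities:
        for dbref in getattr(ent, "dbrefs", []):
            if dbref.accession_code:
                for sub in ent.subchains:
                    entity_acc[sub] = dbref.accession_code

    chains: list[ChainModel] = []
    model = st[0]
    for chain in model:
        residues: list[Residue] = []
        seen_numbers: set[int] = set()
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue
            num = res.seqid.num
            if num in seen_numbers:
                continue  # first conformation of duplicated seqids wins
            atoms: dict[str, np.ndarray] = {}
            occ: dict[str, float] = {}
            for atom in res:
                if atom.name not in atoms or atom.occ > occ[atom.name]:
                    atoms[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    occ[atom.name] = atom.occ
            if not atoms:
                continue
            seen_numbers.add(num)
            residues.append(Residue(num, res.name, atoms))
        if not residues:
            continue
        acc = None
        if chain_map and chain.name in chain_map:
            acc = chain_map[chain.name]
        elif len(chain) and chain[0].subchain in entity_acc:
            acc = entity_acc[chain[0].subchain]
        chains.append(ChainModel(chain.name, acc, residues))
    if not chains:
        raise ValueError(f"{path}: no protein chains")
    return StructureModel(chains, model_id or path.stem)


# ---------------------------------------------------------------------------
# Numbering reconciliation

_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-5,
    extend_gap_score=-1,
)


def align_numbering(
    chain: ChainModel, uniprot_seq: str, min_identity: float = 0.30
) -> SeqMap:
    """Globally align a chain's sequence to its UniProt sequence.

    Scoring: match +1, mismatch -1, gap open -5, gap extend -1.  The returned
    map sends author residue numbers to 1-based UniProt indices for all
    aligned (identical or substituted) columns.  Chains aligning below
    ``min_identity`` (fraction of identical aligned columns) are refused:
    such a mapping would silently mis-number every downstream distance.
    """
    if not uniprot_seq:
        raise ValueError("empty UniProt sequence")
    chain_seq = chain.sequence()
    aln = _aligner.align(chain_seq, uniprot_seq)[0]
    mapping: dict[int, int] = {}
    matches = 0
    aligned_cols = 0
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        for offset in range(a_end - a_start):
            i, j = a_start + offset, b_start + offset
            aligned_cols += 1
            if chain_seq[i] == uniprot_seq[j]:
                matches += 1
            mapping[chain.residues[i].number] = j + 1
    identity = matches / aligned_cols if aligned_cols else 0.0
    if identity < min_identity:
        raise ValueError(
            f"chain {chain.chain_id}: alignment identity {identity:.2f} below "
            f"minimum {min_identity:.2f}; refusing numbering map"
        )
    return SeqMap(chain.chain_id, mapping, identity)


def identity_seqmap(chain: ChainModel) -> SeqMap:
    """Identity mapping for chains already numbered in UniProt coordinates."""
    return SeqMap(chain.chain_id, {r.number: r.number for r in chain.residues}, 1.0)


# ---------------------------------------------------------------------------
# Link mapping


def _site_candidates(
    structure: StructureModel,
    seqmaps: Mapping[str, SeqMap],
    accession: str,
    uniprot_residue: int,
) -> list[tuple[str, np.ndarray]]:
    """All (chain_id, site-atom coordinate) placements of one cross-linked site."""
    out: list[tuple[str, np.ndarray]] = []
    for chain in structure.chains_for(accession):
        seqmap = seqmaps.get(chain.chain_id)
        if seqmap is None:
            continue
        author = seqmap.author_number(uniprot_residue)
        if author is None:
            continue
        res = chain.residue(author)
        if res is None:
            continue
        coord = res.site_atom()
        if coord is not None:
            out.append((chain.chain_id, coord))
    return out


def map_link(
    pair: CrossLinkPair,
    structure: StructureModel,
    seqmaps: Mapping[str, SeqMap],
    cfg: EvalConfig = EvalConfig(),
) -> MappedLink:
    """Place one cross-link on a structure at its minimal site-atom distance.

    The distance is the minimum over all chain assignments consistent with the
    pair's accessions.  For homo-oligomers this includes intra-chain placement
    unless the link is a self-link, which only two distinct protein copies can
    produce.  Unmappable residues yield status ``unmapped`` with a reason.
    """
    acc_u, res_u = pair.site_u
    acc_v, res_v = pair.site_v
    for acc in {acc_u, acc_v}:
        if not structure.chains_for(acc):
            return MappedLink(pair, None, None, "unmapped", reason=f"accession {acc} absent from model")
    cand_u = _site_candidates(structure, seqmaps, acc_u, res_u)
    cand_v = _site_candidates(structure, seqmaps, acc_v, res_v)
    if not cand_u or not cand_v:
        missing = f"{acc_u}:{res_u}" if not cand_u else f"{acc_v}:{res_v}"
        return MappedLink(pair, None, None, "unmapped", reason=f"residue {missing} absent from model")

    is_self = pair.link_class == "self"
    best: tuple[float, tuple[str, str]] | None = None
    best_intra: float | None = None
    best_inter: tuple[float, tuple[str, str]] | None = None
    for cu, xu in cand_u:
        for cv, xv in cand_v:
            same_chain = cu == cv
            if is_self and same_chain:
                continue  # a self-link cannot form within one chain
            if not same_chain and not cfg.treat_homomer and acc_u == acc_v and not is_self:
                continue  # homomer ambiguity disabled: intra links stay intra-chain
            d = float(np.linalg.norm(xu - xv))
            if best is None or d < best[0]:
                best = (d, (cu, cv))
            if same_chain:
                if best_intra is None or d < best_intra:
                    best_intra = d
            elif best_inter is None or d < best_inter[0]:
                best_inter = (d, (cu, cv))
    if best is None:
        return MappedLink(
            pair, None, None, "unmapped",
            reason="self-link with no second chain available",
        )
    distance, assignment = best
    status = "satisfied" if distance <= cfg.d_max else "violated"
    requires_interchain = False
    if best_inter is not None and best_inter[0] <= cfg.d_max:
        if is_self or best_intra is None or best_intra > cfg.d_max:
            requires_interchain = True
    return MappedLink(pair, distance, assignment, status, requires_interchain)


def map_links(
    pairs: Iterable[CrossLinkPair],
    structure: StructureModel,
    seqmaps: Mapping[str, SeqMap],
    cfg: EvalConfig = EvalConfig(),
) -> list[MappedLink]:
    return [map_link(p, structure, seqmaps, cfg) for p in pairs]


def summarize_violations(mapped: Sequence[MappedLink]) -> dict:
    """Global and per-protein satisfied/violated/unmapped counts.

    A violated inter-link is attributed to both of its proteins.  The
    violation list is sorted by distance, largest overshoot first.
    """
    global_counts = {"satisfied": 0, "violated": 0, "unmapped": 0}
    per_protein: dict[str, dict[str, int]] = {}
    violations: list[MappedLink] = []
    for link in mapped:
        global_counts[link.status] += 1
        for acc in set(link.pair.accessions):
            per_protein.setdefault(acc, {"satisfied": 0, "violated": 0, "unmapped": 0})
            per_protein[acc][link.status] += 1
        if link.status == "violated":
            violations.append(link)
    violations.sort(key=lambda m: -(m.distance if m.distance is not None else -math.inf))
    return {"global": global_counts, "per_protein": per_protein, "violations": violations}


# ---------------------------------------------------------------------------
# Pseudobond-style export


def export_link_file(mapped: Sequence[MappedLink], path: str | Path) -> int:
    """Write mapped links as a pseudobond-style text file.

    One line per mapped link: chain/residue/atom specs of both sites, distance
    and status.  Unmapped links are omitted; their count is returned.
    """
    if not mapped:
        raise ValueError("no mapped links to export")
    omitted = 0
    lines = ["# chain_a\tresidue_a\tatom_a\tchain_b\tresidue_b\tatom_b\tdistance_A\tstatus"]
    for link in mapped:
        if link.status == "unmapped" or link.distance is None or link.best_assignment is None:
            omitted += 1
            continue
        (acc_u, res_u), (acc_v, res_v) = link.pair.site_u, link.pair.site_v
        ca, cb = link.best_assignment
        lines.append(
            f"{ca}\t{res_u}\tCB\t{cb}\t{res_v}\tCB\t{link.distance:.2f}\t{link.status}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
    return omitted


def read_link_file(path: str | Path) -> list[dict]:
    """Parse a pseudobond-style link file written by :func:`export_link_file`."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        ca, ra, aa, cb, rb, ab, dist, status = line.split("\t")
        out.append(
            {
                "chain_a": ca, "residue_a": int(ra), "atom_a": aa,
                "chain_b": cb, "residue_b": int(rb), "atom_b": ab,
                "distance": float(dist), "status": status,
            }
        )
    return out
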