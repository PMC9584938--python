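"""Synthetic fixtures with known ground truth for every pipeline stage.

Real inputs to this pipeline are large downloads (search-engine exports,
PDB entries, DIA matrices).  The generators here produce small stand-ins
with *planted, serializable truth* so that filtering, deduplication,
distance mapping, docking recovery, stoichiometry, and enrichment statistics
can all be tested end to end: toy protein folds with ideal backbone
geometry, symmetric assemblies with a controlled inter-subunit contact,
CSM tables mixing true links (within the cross-linker span) with decoys
(beyond it), iBAQ tables with known copy numbers, and three-condition DIA
matrices with planted enrichment, reference-protein distortions, and
left-censored plus condition-structured missingness.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .cargo_enrichment import CONDITIONS, DiaMatrix, GFP, SPIONS, SPIONS_IP
from .restraint_dock import Pose, Restraint
from .structure_map import ChainModel, Residue, StructureModel

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticTruth",
    "gen_structure",
    "gen_assembly",
    "gen_crosslink_table",
    "gen_dia",
    "gen_ibaq",
    "restraints_from_assembly",
    "write_pdb",
    "write_fasta",
]


@dataclass
class SyntheticTruth:
    """Ground truth planted by a generator, serializable next to the fixture."""

    seed: int
    params: dict = field(default_factory=dict)
    poses: dict[str, dict] = field(default_factory=dict)  # copy id -> {quaternion, translation}
    true_links: list = field(default_factory=list)  # [site_a, res_a, site_b, res_b, distance]
    decoy_links: list = field(default_factory=list)
    enriched: list[str] = field(default_factory=list)
    copies: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Structures

_NON_LYS = "ADEVLITNQSG"
_ONE_TO_THREE = {
    "A": "ALA", "D": "ASP", "E": "GLU", "V": "VAL", "L": "LEU", "I": "ILE",
    "T": "THR", "N": "ASN", "Q": "GLN", "S": "SER", "G": "GLY", "K": "LYS",
}

_CA_CB = 1.53  # A, standard C-alpha -> C-beta bond length


def _sequence(n_res: int, lys_fraction: float, rng: np.random.Generator) -> str:
    is_lys = rng.random(n_res) < lys_fraction
    others = rng.choice(list(_NON_LYS), size=n_res)
    return "".join("K" if k else o for k, o in zip(is_lys, others))


def _helix_backbone(
    n_res: int, supercoil_radius: float = 0.0, supercoil_pitch: float = 140.0
) -> tuple[np.ndarray, np.ndarray]:
    """Ideal alpha-helix CA trace (rise 1.5 A, 100 deg/residue) with radial CB.

    A nonzero ``supercoil_radius`` winds the helix axis around the z axis with
    the given pitch (coiled-coil-like left-handed supercoil).  Long natural
    helices are rarely mathematically straight; a straight ideal helix has a
    lattice pseudo-symmetry (180 deg flip about its own axis combined with a
    sub-turn screw shift nearly maps the side-chain lattice onto itself) that
    no residue-pair distance restraint set can break, so pose-recovery
    fixtures use a supercoiled helix.
    """
    i = np.arange(n_res)
    theta = np.deg2rad(100.0) * i
    radius = 2.3
    ca = np.stack([radius * np.cos(theta), radius * np.sin(theta), 1.5 * i], axis=1)
    radial = np.stack([np.cos(theta), np.sin(theta), np.zeros(n_res)], axis=1)
    cb = ca + _CA_CB * radial
    if supercoil_radius > 0:
        phi = 2 * np.pi * ca[:, 2] / supercoil_pitch
        offset = np.stack(
            [supercoil_radius * (np.cos(phi) - 1.0), supercoil_radius * np.sin(phi), np.zeros(n_res)],
            axis=1,
        )
        ca = ca + offset
        cb = cb + offset
    return ca, cb

def _hairpin_backbone(n_res: int) -> tuple[np.ndarray, np.ndarray]:
    """Two antiparallel extended strands 5.5 A apart (toy beta-hairpin)."""
    half = n_res // 2
    ca = np.zeros((n_res, 3))
    for i in range(n_res):
        if i < half:
            ca[i] = (0.0, 0.0, 3.8 * i)
        else:
            ca[i] = (5.5, 0.0, 3.8 * (n_res - 1 - i))
    side = np.where(np.arange(n_res) < half, -1.0, 1.0)
    cb = ca + np.stack([side * _CA_CB, np.zeros(n_res), np.zeros(n_res)], axis=1)
    return ca, cb


def _coil_backbone(n_res: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Self-avoiding CA walk: 3.8 A steps, non-adjacent separation >= 4.5 A."""
    for _ in range(60):  # bounded restarts
        ca = [np.zeros(3)]
        ok = True
        for _i in range(1, n_res):
            placed = False
            for _try in range(200):
                step = rng.normal(size=3)
                step *= 3.8 / np.linalg.norm(step)
                cand = ca[-1] + step
                if len(ca) < 2 or np.min(np.linalg.norm(np.array(ca[:-1]) - cand, axis=1)) >= 4.5:
                    ca.append(cand)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            ca = np.array(ca)
            # CB roughly perpendicular to the local chain direction
            cb = np.empty_like(ca)
            for i in range(n_res):
                prev_i, next_i = max(i - 1, 0), min(i + 1, n_res - 1)
                tangent = ca[next_i] - ca[prev_i]
                ref = np.array([0.0, 0.0, 1.0])
                if abs(np.dot(tangent / np.linalg.norm(tangent), ref)) > 0.9:
                    ref = np.array([1.0, 0.0, 0.0])
                perp = np.cross(tangent, ref)
                cb[i] = ca[i] + _CA_CB * perp / np.linalg.norm(perp)
            return ca, cb
    raise RuntimeError("self-avoiding walk failed after bounded retries")


def gen_structure(
    n_res: int,
    fold: str = "helix",
    lys_fraction: float = 0.2,
    seed: int = 0,
    chain_id: str = "A",
    accession: str = "SYNP1",
    supercoil_radius: float = 0.0,
    supercoil_pitch: float = 140.0,
) -> tuple[StructureModel, str]:
    """Generate a toy single-chain structure with site atoms and its sequence.

    ``fold`` is ``helix`` (ideal alpha-helix geometry), ``hairpin`` (two
    antiparallel strands) or ``random_coil`` (self-avoiding walk).  Lysines
    are placed Bernoulli(``lys_fraction``) per residue, deterministically for
    a given seed.  Residues are numbered 1..n_res (UniProt == author
    numbering).  Only CA and CB atoms are generated: the distance logic under
    test never looks at side chains beyond the site atom.
    """
    if n_res < 10:
        raise ValueError("n_res must be >= 10")
    if not (0 < lys_fraction < 1):
        raise ValueError("lys_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    seq = _sequence(n_res, lys_fraction, rng)
    if fold == "helix":
        ca, cb = _helix_backbone(n_res, supercoil_radius, supercoil_pitch)
    elif fold == "hairpin":
        ca, cb = _hairpin_backbone(n_res)
    elif fold == "random_coil":
        ca, cb = _coil_backbone(n_res, rng)
    else:
        raise ValueError(f"unknown fold {fold!r}")
    residues = []
    for i, letter in enumerate(seq):
        name = _ONE_TO_THREE[letter]
        atoms = {"CA": ca[i].copy()}
        if name != "GLY":
            atoms["CB"] = cb[i].copy()
        residues.append(Residue(i + 1, name, atoms))
    chain = ChainModel(chain_id, accession, residues)
    return StructureModel([chain], f"syn_{fold}_{n_res}"), seq


# ---------------------------------------------------------------------------
# Assemblies


def _site_coords(chain: ChainModel) -> np.ndarray:
    return np.array([r.site_atom() for r in chain.residues])


def _transform_chain(chain: ChainModel, chain_id: str, R: np.ndarray, t: np.ndarray) -> ChainModel:
    residues = [
        Residue(r.number, r.name, {a: R @ xyz + t for a, xyz in r.atoms.items()})
        for r in chain.residues
    ]
    return ChainModel(chain_id, chain.accession, residues)


def _min_inter_distance(chains: Sequence[np.ndarray]) -> float:
    best = np.inf
    for a in range(len(chains)):
        for b in range(a + 1, len(chains)):
            best = min(best, float(cdist(chains[a], chains[b]).min()))
    return best


def gen_assembly(
    monomer: StructureModel | ChainModel,
    n_copies: int = 2,
    symmetry: str = "C2",
    contact: float = 8.0,
    seed: int = 0,
    orientation: str = "random",
) -> tuple[StructureModel, SyntheticTruth]:
    """Place symmetry copies of a monomer with a controlled subunit contact.

    Copies are related by exact symmetry operators (one 2-fold for C2, two
    perpendicular 2-folds for D2); the monomer's offset from the symmetry
    element is tuned by bisection until the nearest inter-subunit site-atom
    distance lies within [contact - 1, contact + 1] A, with no pair closer
    than 3 A.  The true per-copy poses are recorded in the returned truth.

    ``orientation="random"`` rotates the monomer randomly before placement
    (subunits typically meet in a point-like crossed contact);
    ``orientation="aligned"`` keeps the monomer's long axis parallel to the
    symmetry axis, producing extended side-by-side interfaces (coiled-coil
    or helix-bundle-like), the geometry used for pose-recovery benchmarks
    because restraints distributed along an extended interface determine the
    subunit placement.
    """
    chain = monomer.chains[0] if isinstance(monomer, StructureModel) else monomer
    if n_copies not in (2, 4):
        raise ValueError("n_copies must be 2 or 4")
    if (symmetry == "C2" and n_copies != 2) or (symmetry == "D2" and n_copies != 4):
        raise ValueError(f"symmetry {symmetry} incompatible with n_copies {n_copies}")
    if orientation not in ("random", "aligned"):
        raise ValueError(f"unknown orientation {orientation!r}")
    rng = np.random.default_rng(seed)
    sites0 = _site_coords(chain)
    center = sites0.mean(axis=0)

    if orientation == "aligned":
        R0 = np.eye(3)
    else:
        R0 = Rotation.from_quat(_rand_quat(rng)).as_matrix()  # random monomer orientation

    def ops_for(shift: float, direction: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        # base placement: centered, randomly oriented, displaced off the symmetry element
        t_base = -R0 @ center + direction * shift
        base = [(R0, t_base)]
        if symmetry == "C2":
            axes = [np.array([0.0, 0.0, 1.0])]
        else:
            axes = [np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]),
                    np.array([0.0, 0.0, 1.0])]
        ops = list(base)
        for axis in axes[: n_copies - 1]:
            S = Rotation.from_rotvec(axis * np.pi).as_matrix()
            ops.append((S @ R0, S @ t_base))
        return ops

    direction = rng.normal(size=3)
    if symmetry == "C2" or orientation == "aligned":
        direction[2] = 0.0  # displacement along the C2/long axis never separates copies
    direction /= np.linalg.norm(direction)

    def min_dist(shift: float) -> float:
        coords = [sites0 @ R.T + t for R, t in ops_for(shift, direction)]
        return _min_inter_distance(coords)

    radius = float(np.linalg.norm(sites0 - center, axis=1).max())
    lo, hi = 0.0, 2 * radius + contact + 5
    for _ in range(200):
        if min_dist(hi) > contact:
            break
        hi *= 1.5
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if min_dist(mid) < contact:
            lo = mid
        else:
            hi = mid
    shift = 0.5 * (lo + hi)
    d = min_dist(shift)
    if not (contact - 1 <= d <= contact + 1) or d < 3.0:
        raise RuntimeError(f"assembly placement failed: nearest contact {d:.2f} A")

    ops = ops_for(shift, direction)
    copy_ids = "ABCD"[:n_copies]
    chains = [_transform_chain(chain, cid, R, t) for cid, (R, t) in zip(copy_ids, ops)]
    truth = SyntheticTruth(
        seed=seed,
        params={"n_copies": n_copies, "symmetry": symmetry, "contact": contact},
        poses={
            cid: {
                "quaternion": list(map(float, Rotation.from_matrix(R).as_quat())),
                "translation": list(map(float, t)),
            }
            for cid, (R, t) in zip(copy_ids, ops)
        },
    )
    return StructureModel(chains, f"syn_{symmetry}_{n_copies}mer"), truth


def gen_coiled_coil_dimer(
    n_res: int = 60,
    contact: float = 5.0,
    lys_fraction: float = 0.25,
    seed: int = 0,
    supercoil_pitch: float = 140.0,
) -> tuple[StructureModel, SyntheticTruth]:
    """Parallel C2 coiled-coil dimer with an extended constant-gap interface.

    Both strands are supercoiled helices wound around the C2 (z) axis, phase
    shifted by 180 degrees; the supercoil radius is tuned by bisection until
    the nearest inter-strand site-atom distance equals ``contact`` (within
    1 A).  This is the planted-dimer fixture for docking-recovery benchmarks:
    the interface runs the full length of the strands, so cross-link
    restraints sampled from it determine the mobile strand's placement (a
    straight-helix dimer leaves flip and screw-slide pseudo-symmetries that
    no distance restraint set can resolve).
    """
    seq = _sequence(n_res, lys_fraction, np.random.default_rng(seed))

    def build(r0: float) -> tuple[np.ndarray, np.ndarray]:
        ca, cb = _helix_backbone(n_res, supercoil_radius=r0, supercoil_pitch=supercoil_pitch)
        shift = np.array([r0, 0.0, 0.0])  # supercoil axis -> z
        return ca + shift, cb + shift

    def min_gap(r0: float) -> float:
        ca, cb = build(r0)
        sites = np.where((np.array(list(seq)) == "G")[:, None], ca, cb)
        flip = np.diag([-1.0, -1.0, 1.0])
        return float(cdist(sites, sites @ flip.T).min())

    lo, hi = 2.0, 40.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if min_gap(mid) < contact:
            lo = mid
        else:
            hi = mid
    r0 = 0.5 * (lo + hi)
    gap = min_gap(r0)
    if not (contact - 1 <= gap <= contact + 1):
        raise RuntimeError(f"coiled-coil placement failed: nearest contact {gap:.2f} A")

    ca, cb = build(r0)
    flip = np.diag([-1.0, -1.0, 1.0])
    chains = []
    for cid, R in (("A", np.eye(3)), ("B", flip)):
        residues = []
        for i, letter in enumerate(seq):
            name = _ONE_TO_THREE[letter]
            atoms = {"CA": R @ ca[i]}
            if name != "GLY":
                atoms["CB"] = R @ cb[i]
            residues.append(Residue(i + 1, name, atoms))
        chains.append(ChainModel(cid, "SYNP1", residues))
    truth = SyntheticTruth(
        seed=seed,
        params={"n_res": n_res, "contact": contact, "supercoil_radius": r0,
                "supercoil_pitch": supercoil_pitch},
        poses={
            "A": {"quaternion": [0.0, 0.0, 0.0, 1.0], "translation": [0.0, 0.0, 0.0]},
            "B": {"quaternion": [0.0, 0.0, 1.0, 0.0], "translation": [0.0, 0.0, 0.0]},
        },
    )
    return StructureModel(chains, "syn_coiled_coil"), truth


__all__.append("gen_coiled_coil_dimer")


def _rand_quat(rng: np.random.Generator) -> np.ndarray:
    u1, u2, u3 = rng.random(3)
    return np.array(
        [
            np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
            np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
            np.sqrt(u1) * np.sin(2 * np.pi * u3),
            np.sqrt(u1) * np.cos(2 * np.pi * u3),
        ]
    )


def truth_poses(truth: SyntheticTruth) -> dict[str, Pose]:
    """Rehydrate the planted per-copy poses from a truth record."""
    return {
        cid: Pose(cid, tuple(np.array(p["quaternion"]) / np.linalg.norm(p["quaternion"])),
                  tuple(p["translation"]))
        for cid, p in truth.poses.items()
    }


__all__.append("truth_poses")


def restraints_from_assembly(
    assembly: StructureModel,
    n_restraints: int,
    seed: int = 0,
    width: float = 20.0,
    max_distance: float = 30.0,
    subunit_ids: tuple[str, str] | None = None,
    spread: bool = False,
) -> list[Restraint]:
    """Sample inter-subunit restraints with the true distance at the bound midpoint.

    Picks residue pairs from two distinct chains whose site-atom distance is
    at most ``max_distance`` and builds flat-bottom restraints
    [d - width/2, d + width/2] (clamped at zero), so the generating assembly
    has exactly zero restraint energy.  ``subunit_ids`` renames the two sides
    (e.g. to the receptor/mobile ids used in a docking run); by default the
    chain ids of the assembly are used.  With ``spread`` the second chain's
    sequence is split into ``n_restraints`` segments and one restraint drawn
    per segment, emulating cross-links distributed along an extended
    interface; a purely random draw can cluster in one segment and leave the
    rest of the subunit rotationally unconstrained.
    """
    rng = np.random.default_rng(seed)
    ca, cb = assembly.chains[0], assembly.chains[1]
    xa, xb = _site_coords(ca), _site_coords(cb)
    d = cdist(xa, xb)
    ii, jj = np.where(d <= max_distance)
    if len(ii) < n_restraints:
        raise ValueError(f"only {len(ii)} candidate pairs within {max_distance} A")
    if spread:
        edges = np.linspace(0, len(cb.residues), n_restraints + 1)
        pick = []
        for k in range(n_restraints):
            in_seg = np.where((jj >= edges[k]) & (jj < edges[k + 1]))[0]
            pool = in_seg if len(in_seg) else np.arange(len(ii))
            pool = np.setdiff1d(pool, np.array(pick, dtype=int))
            if not len(pool):
                pool = np.setdiff1d(np.arange(len(ii)), np.array(pick, dtype=int))
            pick.append(int(pool[rng.integers(len(pool))]))
        pick = np.array(pick)
    else:
        pick = rng.choice(len(ii), size=n_restraints, replace=False)
    sid_a, sid_b = subunit_ids or (ca.chain_id, cb.chain_id)
    out = []
    for k in pick:
        i, j = int(ii[k]), int(jj[k])
        dist = float(d[i, j])
        out.append(
            Restraint(
                (sid_a, ca.residues[i].number),
                (sid_b, cb.residues[j].number),
                lower=max(0.0, dist - width / 2),
                upper=dist + width / 2,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Cross-link tables


def gen_crosslink_table(
    assembly: StructureModel,
    n_true: int = 40,
    n_decoy: int = 10,
    d_max: float = 35.0,
    seed: int = 0,
    true_score: tuple[float, float] = (55.0, 8.0),
    decoy_score: tuple[float, float] = (25.0, 8.0),
    dr_probability: float = 0.55,
    n_replicates: int = 3,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Emit a CSM table of true links (mappable within ``d_max``) plus decoys.

    True links are sampled uniformly from lysine pairs whose minimal
    site-atom distance over all chain assignments is <= ``d_max`` (inter- and
    intra-chain); decoys from lysine pairs beyond ``d_max`` + 5 A, emulating
    identifications that violate the cross-linker span.  Scores are drawn
    Normal(mean, sd) per class (true links score higher on average; the
    separation is configurable), FDR values lie within the accept band, and
    each unique link is emitted as 1-5 CSMs spread over DR/IT conditions and
    replicates.  The returned table uses the package's generic column
    dialect.
    """
    chains = assembly.chains
    accession = chains[0].accession or "SYNP1"
    coords = [_site_coords(c) for c in chains]
    resnums = [r.number for r in chains[0].residues]
    is_lys = np.array([r.name == "LYS" for r in chains[0].residues])

    d_intra = cdist(coords[0], coords[0])
    d_min = d_intra.copy()
    d_inter = np.full_like(d_intra, np.inf)
    for a in range(len(chains)):
        for b in range(len(chains)):
            if a != b:
                d_inter = np.minimum(d_inter, cdist(coords[a], coords[b]))
    np.fill_diagonal(d_min, np.inf)  # a self-link needs two copies
    d_min = np.minimum(d_min, d_inter)

    lys_pairs = [
        (i, j)
        for i in range(len(resnums))
        for j in range(i, len(resnums))
        if is_lys[i] and is_lys[j]
    ]
    true_cand = [(i, j) for i, j in lys_pairs if d_min[i, j] <= d_max]
    decoy_cand = [(i, j) for i, j in lys_pairs if d_min[i, j] > d_max + 5]
    if len(true_cand) < n_true:
        raise ValueError(f"only {len(true_cand)} lysine pairs within {d_max} A; need {n_true}")
    if len(decoy_cand) < n_decoy:
        raise ValueError(f"only {len(decoy_cand)} decoy candidates; need {n_decoy}")

    rng = np.random.default_rng(seed)
    true_pick = [true_cand[k] for k in rng.choice(len(true_cand), n_true, replace=False)]
    decoy_pick = [decoy_cand[k] for k in rng.choice(len(decoy_cand), n_decoy, replace=False)]

    rows = []
    truth = SyntheticTruth(seed=seed, params={"n_true": n_true, "n_decoy": n_decoy, "d_max": d_max})
    for pick, (mean, sd), bucket in (
        (true_pick, true_score, truth.true_links),
        (decoy_pick, decoy_score, truth.decoy_links),
    ):
        for i, j in pick:
            bucket.append([accession, resnums[i], accession, resnums[j], float(d_min[i, j])])
            n_csm = int(rng.integers(1, 6))
            for _ in range(n_csm):
                rows.append(
                    {
                        "protein_a": accession,
                        "site_a": resnums[i],
                        "protein_b": accession,
                        "site_b": resnums[j],
                        "score": max(0.0, float(rng.normal(mean, sd))),
                        "fdr": float(rng.uniform(0.0, 0.05)),
                        "condition": "DR" if rng.random() < dr_probability else "IT",
                        "replicate": int(rng.integers(1, n_replicates + 1)),
                    }
                )
    frame = pd.DataFrame(rows).sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    return frame, truth


# ---------------------------------------------------------------------------
# DIA matrices


def gen_dia(
    n_null: int = 300,
    n_enriched: int = 30,
    fold_change: float = 2.0,
    sigma_log2: float = 0.3,
    seed: int = 0,
    n_replicates: int = 3,
    censor_quantile: float = 0.15,
    censor_prob: float = 0.6,
    n_spions_specific: int = 20,
    n_on_off: int = 8,
    replicate_distortion_sd: float = 0.15,
    reference_sigma: float = 0.05,
) -> tuple[DiaMatrix, SyntheticTruth]:
    """Three-condition DIA intensity matrix with planted enrichment.

    Log2 intensities are Normal(mu_p, sigma_log2) around a per-protein
    baseline; planted rows are shifted by log2(fold_change) in SPIONS_IP
    (with ``fold_change`` 1 nothing is planted and the truth set is empty).
    FLOT1/FLOT2 reference rows are present in all SPIONs columns with the
    low measurement noise of very abundant proteins (``reference_sigma``;
    DIA noise is intensity-dependent, and normalizing on imprecisely
    measured references would inject their noise into every value), and
    every SPIONS/SPIONS_IP replicate carries a multiplicative distortion
    (what reference normalization must undo).  Missingness is left-censored
    (values below the ``censor_quantile`` of the log2 distribution are
    dropped with probability ``censor_prob``) plus condition-structured
    dropout creating SPIONs-specific and on/off rows.
    """
    if fold_change < 1:
        raise ValueError("fold_change must be >= 1")
    rng = np.random.default_rng(seed)
    shift = np.log2(fold_change)

    names: list[str] = []
    mus: list[float] = []
    kinds: list[str] = []

    for i in range(n_null):
        names.append(f"NULL{i+1:04d}")
        mus.append(float(rng.uniform(19, 27)))
        kinds.append("null")
    for i in range(n_enriched):
        names.append(f"ENR{i+1:04d}")
        mus.append(float(rng.uniform(24, 27)))
        kinds.append("enriched" if shift > 0 else "null")
    for i in range(n_spions_specific):
        names.append(f"SPEC{i+1:04d}")
        mus.append(float(rng.uniform(21, 26)))
        kinds.append("spions_specific")
    for i in range(n_on_off):
        names.append(f"ONOFF{i+1:04d}")
        mus.append(float(rng.uniform(21, 26)))
        kinds.append("on_off_ip" if i % 2 == 0 else "on_off_s")
    for ref in ("FLOT1", "FLOT2"):
        names.append(ref)
        mus.append(28.0)
        kinds.append("reference")

    groups = {c: [f"{c}_{r+1}" for r in range(n_replicates)] for c in CONDITIONS}
    cols = [c for cond in CONDITIONS for c in groups[cond]]
    log2 = np.empty((len(names), len(cols)))
    for row, mu in enumerate(mus):
        sigma = reference_sigma if kinds[row] == "reference" else sigma_log2
        log2[row] = mu + rng.normal(0.0, sigma, size=len(cols))
    ip_cols = [cols.index(c) for c in groups[SPIONS_IP]]
    for row, kind in enumerate(kinds):
        if kind == "enriched":
            log2[row, ip_cols] += shift

    # left-censored missingness on the undistorted log2 scale
    threshold = float(np.quantile(log2, censor_quantile))
    drop = (log2 < threshold) & (rng.random(log2.shape) < censor_prob)
    for row, kind in enumerate(kinds):
        if kind == "reference":
            drop[row, :] = False  # references must be quantified everywhere

    values = np.power(2.0, log2)
    # replicate-specific distortions on the SPIONs conditions (GFP untouched)
    distortions: dict[str, float] = {}
    for cond in (SPIONS, SPIONS_IP):
        for col in groups[cond]:
            f = float(np.exp(rng.normal(0.0, replicate_distortion_sd)))
            distortions[col] = f
            values[:, cols.index(col)] *= f
    values[drop] = np.nan

    frame = pd.DataFrame(values, index=names, columns=cols)
    # condition-structured dropout
    for row, kind in enumerate(kinds):
        name = names[row]
        if kind == "spions_specific":
            frame.loc[name, groups[GFP]] = np.nan
        elif kind == "on_off_ip":
            frame.loc[name, groups[GFP] + groups[SPIONS]] = np.nan
        elif kind == "on_off_s":
            frame.loc[name, groups[GFP] + groups[SPIONS_IP]] = np.nan

    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_null": n_null, "n_enriched": n_enriched, "fold_change": fold_change,
            "sigma_log2": sigma_log2, "censor_quantile": censor_quantile,
            "censor_prob": censor_prob, "n_spions_specific": n_spions_specific,
            "n_on_off": n_on_off, "distortions": distortions,
        },
        enriched=[n for n, k in zip(names, kinds) if k == "enriched"],
    )
    return DiaMatrix(frame, groups), truth


# ---------------------------------------------------------------------------
# iBAQ tables


def gen_ibaq(
    copies: Mapping[str, int],
    base_abundance: float = 1e6,
    cv: float = 0.15,
    n_samples: int = 6,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """iBAQ-style abundance table with known subunit copy numbers.

    Each value is copies x base x lognormal(0, cv) per sample, emulating
    replicate scatter around the molar amount.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    cols = [f"sample_{i+1}" for i in range(n_samples)]
    rows = {
        acc: c * base_abundance * np.exp(rng.normal(0.0, cv, size=n_samples))
        for acc, c in copies.items()
    }
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    truth = SyntheticTruth(
        seed=seed,
        params={"base_abundance": base_abundance, "cv": cv, "n_samples": n_samples},
        copies=dict(copies),
    )
    return frame, truth


# ---------------------------------------------------------------------------
# File output helpers

_ELEMENTS = {"CA": "C", "CB": "C", "N": "N", "C": "C", "O": "O"}


def write_pdb(structure: StructureModel, path: str | Path) -> None:
    """Write a StructureModel as PDB via gemmi (mmCIF if the suffix is .cif)."""
    st = gemmi.Structure()
    st.name = structure.model_id
    model = gemmi.Model("1")
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, " ")
            for atom_name, xyz in res.atoms.items():
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.element = gemmi.Element(_ELEMENTS.get(atom_name, atom_name[0]))
                atom.pos = gemmi.Position(*map(float, xyz))
                atom.occ = 1.0
                gres.add_atom(atom)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    if path.suffix.lower() == ".cif":
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=acc, description="") for acc, s in sequences.items()]
    seqio_write(records, str(path), "fasta")
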