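"""Restraint-guided rigid-body docking of protein subunits.

Cross-links measured on a complex translate into flat-bottom distance
restraints between residue pairs (DSSO: 20 +/- 10 A between site atoms).
This module searches rigid-body placements of a mobile subunit (or of the
copies of a symmetric homo-oligomer) that satisfy those restraints while
avoiding steric clashes, mirroring the classic restraint-docking protocol:
many random starting poses, local rigid-body minimization, scoring, RMSD
clustering, and reporting of cluster representatives.

The score is a documented surrogate, not a physical force field:

    total = w_r * E_restraint + w_x * n_clash - w_c * n_contact

where E_restraint is the flat-bottom quadratic penalty summed over
restraints, n_clash counts site-atom pairs across subunits closer than the
clash cutoff, and n_contact counts pairs in the contact band.  Rankings are
therefore not comparable to physics-based energies; restraint satisfaction
of the resulting models is the meaningful output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .structure_map import ChainModel, EvalConfig, MappedLink, Residue, StructureModel, identity_seqmap, map_links
from .xl_tables import CrossLinkPair

logger = logging.getLogger(__name__)

__all__ = [
    "Restraint",
    "Pose",
    "ScoredPose",
    "PoseCluster",
    "DockConfig",
    "Subunit",
    "restraint_energy",
    "score_pose",
    "sample_and_minimize",
    "cluster_poses",
    "ligand_rmsd",
    "assemble_symmetric",
    "evaluate_assembly",
    "assembly_to_structure",
    "read_restraints_tsv",
    "write_restraints_tsv",
    "write_scores_tsv",
]


@dataclass(frozen=True)
class Restraint:
    """Flat-bottom distance restraint between two (subunit, residue) sites.

    Zero penalty for lower <= d <= upper, quadratic in the overshoot outside.
    Defaults encode the DSSO band 20 +/- 10 A on C-beta site atoms.
    """

    site_u: tuple[str, int]
    site_v: tuple[str, int]
    lower: float = 10.0
    upper: float = 30.0

    def __post_init__(self) -> None:
        if not (0 <= self.lower < self.upper):
            raise ValueError(f"need 0 <= lower < upper, got [{self.lower}, {self.upper}]")

    def penalty(self, d: float) -> float:
        if d < self.lower:
            return (self.lower - d) ** 2
        if d > self.upper:
            return (d - self.upper) ** 2
        return 0.0


@dataclass(frozen=True)
class Pose:
    """Rigid-body placement of one subunit: x -> R(q) x + t."""

    subunit_id: str
    quaternion: tuple[float, float, float, float]  # (x, y, z, w), unit norm
    translation: tuple[float, float, float]

    def __post_init__(self) -> None:
        norm = float(np.linalg.norm(self.quaternion))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"quaternion norm {norm} != 1")

    @classmethod
    def identity(cls, subunit_id: str) -> "Pose":
        return cls(subunit_id, (0.0, 0.0, 0.0, 1.0), (0.0, 0.0, 0.0))

    @classmethod
    def from_matrix(cls, subunit_id: str, R: np.ndarray, t: np.ndarray) -> "Pose":
        q = Rotation.from_matrix(R).as_quat()
        q = q / np.linalg.norm(q)
        return cls(subunit_id, tuple(float(x) for x in q), tuple(float(x) for x in t))

    @property
    def matrix(self) -> np.ndarray:
        return Rotation.from_quat(self.quaternion).as_matrix()

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.matrix.T + np.asarray(self.translation)


@dataclass
class ScoredPose:
    """A set of rigid-body poses with its surrogate score components."""

    poses: dict[str, Pose]
    e_restraint: float
    n_clash: int
    n_contact: int
    total: float


@dataclass
class PoseCluster:
    representative: ScoredPose
    members: list[int]  # indices into the scored list handed to cluster_poses

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class DockConfig:
    """Search and scoring settings for restraint docking.

    Defaults follow the standard restraint-docking protocol: 500 random
    starting poses, the best 100 retained after rigid-body minimization,
    clustering at 5 A pairwise RMSD, ten models reported.
    """

    n_init: int = 500
    n_refine: int = 100
    cluster_rmsd: float = 5.0
    n_report: int = 10
    w_restraint: float = 1.0
    w_clash: float = 0.5
    w_contact: float = 0.05
    clash_cutoff: float = 3.0
    contact_cutoff: float = 8.0
    max_evals: int = 500
    min_cluster_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_refine > self.n_init:
            raise ValueError("n_refine must not exceed n_init")
        if self.cluster_rmsd <= 0:
            raise ValueError("cluster_rmsd must be positive")


@dataclass
class Subunit:
    """Site-atom representation of one rigid subunit.

    ``coords`` holds one site atom (CB, or CA for glycine/missing CB) per
    residue in ``resnums`` (UniProt numbering).  ``chain`` optionally keeps
    the full-atom chain for assembly export.
    """

    subunit_id: str
    resnums: np.ndarray
    coords: np.ndarray
    chain: ChainModel | None = None

    def __post_init__(self) -> None:
        self.resnums = np.asarray(self.resnums, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        self._index = {int(n): i for i, n in enumerate(self.resnums)}

    @classmethod
    def from_chain(cls, chain: ChainModel, subunit_id: str | None = None) -> "Subunit":
        nums, coords = [], []
        for res in chain.residues:
            site = res.site_atom()
            if site is not None:
                nums.append(res.number)
                coords.append(site)
        return cls(subunit_id or chain.chain_id, np.array(nums), np.array(coords), chain)

    def index_of(self, resnum: int) -> int:
        if resnum not in self._index:
            raise KeyError(resnum)
        return self._index[resnum]

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    @property
    def radius(self) -> float:
        return float(np.linalg.norm(self.coords - self.centroid, axis=1).max())


# ---------------------------------------------------------------------------
# Energies and scoring


def _resolve(restraint_site: tuple[str, int], subunits: Mapping[str, Subunit], restraint: Restraint) -> tuple[str, int]:
    sid, resnum = restraint_site
    if sid not in subunits:
        raise ValueError(f"restraint {restraint} names unknown subunit {sid!r}")
    try:
        return sid, subunits[sid].index_of(resnum)
    except KeyError:
        raise ValueError(f"restraint {restraint} names residue {resnum} absent from subunit {sid!r}")


def restraint_energy(
    coords: Mapping[str, np.ndarray],
    restraints: Iterable[Restraint],
    subunits: Mapping[str, Subunit] | None = None,
) -> float:
    """Flat-bottom quadratic restraint energy over placed subunit coordinates.

    ``coords`` maps subunit id to an (n, 3) site-atom array congruent with
    the subunit's residue order; ``subunits`` supplies the residue-number
    index (defaults to interpreting restraint residue numbers as residues of
    identically shaped subunits built beforehand).
    """
    total = 0.0
    for r in restraints:
        if subunits is not None:
            su, iu = _resolve(r.site_u, subunits, r)
            sv, iv = _resolve(r.site_v, subunits, r)
        else:
            su, iu = r.site_u
            sv, iv = r.site_v
        d = float(np.linalg.norm(coords[su][iu] - coords[sv][iv]))
        total += r.penalty(d)
    return total


def _flat_bottom(d: np.ndarray, lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    low = np.clip(lower - d, 0.0, None)
    high = np.clip(d - upper, 0.0, None)
    return low**2 + high**2


def _count_contacts(a: np.ndarray, b: np.ndarray, cfg: DockConfig) -> tuple[int, int]:
    d = cdist(a, b)
    n_clash = int((d < cfg.clash_cutoff).sum())
    n_contact = int(((d >= cfg.clash_cutoff) & (d <= cfg.contact_cutoff)).sum())
    return n_clash, n_contact


def score_pose(
    receptor: Subunit,
    mobile: Subunit,
    restraints: Sequence[Restraint],
    cfg: DockConfig = DockConfig(),
    pose: Pose | None = None,
) -> ScoredPose:
    """Score one placement of ``mobile`` against ``receptor``.

    ``pose`` transforms the mobile subunit (identity if omitted).  Clash and
    contact counts consider cross-subunit site-atom pairs only.
    """
    pose = pose or Pose.identity(mobile.subunit_id)
    mob = pose.apply(mobile.coords)
    subunits = {receptor.subunit_id: receptor, mobile.subunit_id: mobile}
    coords = {receptor.subunit_id: receptor.coords, mobile.subunit_id: mob}
    e = restraint_energy(coords, restraints, subunits)
    n_clash, n_contact = _count_contacts(receptor.coords, mob, cfg)
    total = cfg.w_restraint * e + cfg.w_clash * n_clash - cfg.w_contact * n_contact
    return ScoredPose({mobile.subunit_id: pose}, e, n_clash, n_contact, total)


# ---------------------------------------------------------------------------
# Sampling and minimization


def _random_quaternion(rng: np.random.Generator) -> np.ndarray:
    # Subgroup algorithm: uniform on SO(3).
    u1, u2, u3 = rng.random(3)
    return np.array(
        [
            np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
            np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
            np.sqrt(u1) * np.sin(2 * np.pi * u3),
            np.sqrt(u1) * np.cos(2 * np.pi * u3),
        ]
    )


def _rotvec_matrix(v: np.ndarray) -> np.ndarray:
    """Rodrigues rotation matrix for a rotation vector (fast path for the objective)."""
    theta = np.linalg.norm(v)
    if theta < 1e-12:
        return np.eye(3)
    k = v / theta
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def _cross_restraint_arrays(
    receptor: Subunit, mobile: Subunit, restraints: Sequence[Restraint]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float]:
    """Split restraints into receptor<->mobile index arrays plus the constant
    intra-subunit penalty (rigid transforms leave intra distances unchanged)."""
    subunits = {receptor.subunit_id: receptor, mobile.subunit_id: mobile}
    ir, im, lo, up = [], [], [], []
    const = 0.0
    for r in restraints:
        su, iu = _resolve(r.site_u, subunits, r)
        sv, iv = _resolve(r.site_v, subunits, r)
        if su == sv:
            xs = receptor.coords if su == receptor.subunit_id else mobile.coords
            const += r.penalty(float(np.linalg.norm(xs[iu] - xs[iv])))
        elif su == receptor.subunit_id:
            ir.append(iu), im.append(iv), lo.append(r.lower), up.append(r.upper)
        else:
            ir.append(iv), im.append(iu), lo.append(r.lower), up.append(r.upper)
    return (np.array(ir, int), np.array(im, int), np.array(lo), np.array(up), const)


def sample_and_minimize(
    receptor: Subunit,
    mobile: Subunit,
    restraints: Sequence[Restraint],
    cfg: DockConfig = DockConfig(),
) -> list[ScoredPose]:
    """Random-restart rigid-body docking of ``mobile`` onto ``receptor``.

    Draws ``n_init`` starting poses (uniform random orientation; centroid in
    the union of spheres of radius upper + mobile radius around restrained
    receptor sites), locally minimizes each over the 6 rigid-body degrees of
    freedom with derivative-free descent (<= ``max_evals`` evaluations), and
    returns the best ``n_refine`` poses sorted by total score.  Fully
    reproducible for a given ``cfg.seed``.
    """
    ir, im, lo, up, const = _cross_restraint_arrays(receptor, mobile, restraints)
    if len(ir) == 0:
        raise ValueError("no restraint spans receptor and mobile subunits")
    rng = np.random.default_rng(cfg.seed)
    rec = receptor.coords
    mob0 = mobile.coords
    mob_centroid = mobile.centroid
    mob_radius = mobile.radius
    rec_sites = rec[np.unique(ir)]
    reach = up.max() + mob_radius

    # Rigid-body minimization descends the energy terms (restraints + clash);
    # the contact reward enters only the ranking score, as in restraint-docking
    # protocols where minimization and model scoring are separate stages.
    def objective(params: np.ndarray) -> float:
        R = _rotvec_matrix(params[:3])
        mob = mob0 @ R.T + params[3:]
        d = np.linalg.norm(rec[ir] - mob[im], axis=1)
        e = const + float(_flat_bottom(d, lo, up).sum())
        n_clash = int((cdist(rec, mob) < cfg.clash_cutoff).sum())
        return cfg.w_restraint * e + cfg.w_clash * n_clash

    results: list[tuple[float, np.ndarray]] = []
    for _ in range(cfg.n_init):
        q = _random_quaternion(rng)
        R0 = Rotation.from_quat(q).as_matrix()
        site = rec_sites[rng.integers(len(rec_sites))]
        # random point in the reach sphere around a restrained receptor site
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        target = site + direction * reach * rng.random() ** (1 / 3)
        t0 = target - R0 @ mob_centroid
        x0 = np.concatenate([Rotation.from_matrix(R0).as_rotvec(), t0])
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"maxfev": cfg.max_evals, "xatol": 1e-2, "fatol": 1e-3},
        )
        f0 = objective(x0)
        if res.fun <= f0:
            results.append(res.x)
        else:  # descent guarantee: never return a pose worse than its start
            results.append(x0)

    scored: list[ScoredPose] = []
    for params in results:
        R = _rotvec_matrix(params[:3])
        pose = Pose.from_matrix(mobile.subunit_id, R, params[3:])
        scored.append(score_pose(receptor, mobile, restraints, cfg, pose))
    scored.sort(key=lambda s: s.total)
    return scored[: cfg.n_refine]


# ---------------------------------------------------------------------------
# Clustering


def ligand_rmsd(pose_a: Pose, pose_b: Pose, mobile_coords: np.ndarray) -> float:
    """RMSD of the mobile subunit's site atoms between two poses.

    The receptor is rigid and common to both poses, so the receptor
    superposition is the identity and the ligand RMSD is a direct coordinate
    RMSD of the transformed mobile atoms.
    """
    diff = pose_a.apply(mobile_coords) - pose_b.apply(mobile_coords)
    return float(np.sqrt((diff**2).sum(axis=1).mean()))


def _pose_coords(scored: ScoredPose, mobiles: Mapping[str, Subunit]) -> np.ndarray:
    parts = [scored.poses[sid].apply(mobiles[sid].coords) for sid in sorted(scored.poses)]
    return np.vstack(parts)


def cluster_poses(
    scored: Sequence[ScoredPose],
    mobile: Subunit | Mapping[str, Subunit],
    cfg: DockConfig = DockConfig(),
) -> tuple[list[PoseCluster], list[ScoredPose]]:
    """Single-linkage clustering of poses at ``cfg.cluster_rmsd`` A ligand RMSD.

    Two poses join a cluster whenever a chain of pairwise RMSDs below the
    cutoff connects them (connected components of the thresholded RMSD
    graph).  Returns clusters ordered by their lowest-total representative,
    plus the overall ``n_report`` best poses.
    """
    if not scored:
        raise ValueError("no poses to cluster")
    mobiles = {mobile.subunit_id: mobile} if isinstance(mobile, Subunit) else dict(mobile)
    coords = np.stack([_pose_coords(s, mobiles) for s in scored])
    n = len(scored)
    flat = coords.reshape(n, -1)
    sq = ((flat[:, None, :] - flat[None, :, :]) ** 2).reshape(n, n, -1).sum(axis=2)
    rmsd = np.sqrt(sq / coords.shape[1])
    adj = csr_matrix(rmsd <= cfg.cluster_rmsd)
    n_comp, labels = connected_components(adj, directed=False)
    clusters = []
    for comp in range(n_comp):
        members = [i for i in range(n) if labels[i] == comp]
        if len(members) < cfg.min_cluster_size:
            continue
        rep = min(members, key=lambda i: scored[i].total)
        clusters.append(PoseCluster(scored[rep], members))
    clusters.sort(key=lambda c: c.representative.total)
    top = sorted(scored, key=lambda s: s.total)[: cfg.n_report]
    return clusters, top


# ---------------------------------------------------------------------------
# Symmetric assembly search

_COPY_IDS = "ABCD"


def _symmetry_ops_c2(params: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Identity plus a 2-fold rotation about an axis (direction from two
    angles, passing through a point)."""
    theta, phi = params[0], params[1]
    u = np.array([np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)])
    p = params[2:5]
    R = _rotvec_matrix(u * np.pi)
    return [(np.eye(3), np.zeros(3)), (R, p - R @ p)]


def _symmetry_ops_d2(params: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Identity plus three 2-folds about perpendicular axes of an oriented
    frame (rotvec) through an origin."""
    F = _rotvec_matrix(params[:3])
    o = params[3:6]
    ops = [(np.eye(3), np.zeros(3))]
    for axis in np.eye(3):
        R = F @ _rotvec_matrix(axis * np.pi) @ F.T
        ops.append((R, o - R @ o))
    return ops


def _ambiguous_energy(
    copies: Sequence[np.ndarray],
    pairs_idx: np.ndarray,
    lo: np.ndarray,
    up: np.ndarray,
    same_res: np.ndarray,
) -> float:
    """Restraint energy with each restraint taking the minimum penalty over
    all chain assignments (intra-chain excluded for self-residue restraints)."""
    n_copies = len(copies)
    best = np.full(len(pairs_idx), np.inf)
    for a in range(n_copies):
        for b in range(n_copies):
            if a == b:
                d = np.linalg.norm(copies[a][pairs_idx[:, 0]] - copies[a][pairs_idx[:, 1]], axis=1)
                pen = _flat_bottom(d, lo, up)
                pen = np.where(same_res, np.inf, pen)
            else:
                d = np.linalg.norm(copies[a][pairs_idx[:, 0]] - copies[b][pairs_idx[:, 1]], axis=1)
                pen = _flat_bottom(d, lo, up)
            best = np.minimum(best, pen)
    return float(best.sum())


def _assembly_score(
    copies: Sequence[np.ndarray],
    pairs_idx: np.ndarray,
    lo: np.ndarray,
    up: np.ndarray,
    same_res: np.ndarray,
    cfg: DockConfig,
) -> tuple[float, float, int, int]:
    e = _ambiguous_energy(copies, pairs_idx, lo, up, same_res)
    n_clash = n_contact = 0
    for a in range(len(copies)):
        for b in range(a + 1, len(copies)):
            c, k = _count_contacts(copies[a], copies[b], cfg)
            n_clash += c
            n_contact += k
    total = cfg.w_restraint * e + cfg.w_clash * n_clash - cfg.w_contact * n_contact
    return total, e, n_clash, n_contact


def _monomer_restraint_arrays(
    monomer: Subunit, restraints: Sequence[Restraint]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    idx, lo, up = [], [], []
    for r in restraints:
        iu = monomer.index_of(r.site_u[1])
        iv = monomer.index_of(r.site_v[1])
        idx.append((iu, iv))
        lo.append(r.lower)
        up.append(r.upper)
    idx = np.array(idx, int).reshape(-1, 2)
    return idx, np.array(lo), np.array(up), idx[:, 0] == idx[:, 1]


def _scored_from_ops(
    monomer: Subunit,
    ops: Sequence[tuple[np.ndarray, np.ndarray]],
    pairs_idx, lo, up, same_res,
    cfg: DockConfig,
) -> ScoredPose:
    copies = [monomer.coords @ R.T + t for R, t in ops]
    total, e, n_clash, n_contact = _assembly_score(copies, pairs_idx, lo, up, same_res, cfg)
    poses = {
        _COPY_IDS[i]: Pose.from_matrix(_COPY_IDS[i], R, t) for i, (R, t) in enumerate(ops)
    }
    return ScoredPose(poses, e, n_clash, n_contact, total)


def assemble_symmetric(
    monomer: Subunit,
    restraints: Sequence[Restraint],
    n_copies: int,
    symmetry: str = "none",
    cfg: DockConfig = DockConfig(),
) -> list[ScoredPose]:
    """Search homo-oligomeric assemblies of ``monomer`` under cross-link restraints.

    For C2/D2 the search space is reduced to the symmetry generators (one
    2-fold axis for C2, an oriented frame of two perpendicular 2-folds for
    D2) applied to a single subunit pose; restraint residue pairs are
    evaluated under the minimum over symmetry-equivalent chain assignments.
    ``symmetry="none"`` docks copies sequentially (B onto A, C onto AB, D
    onto ABC).  Returns the best ``n_refine`` assemblies sorted by total.
    """
    if n_copies not in (2, 4):
        raise ValueError("n_copies must be 2 or 4")
    if symmetry == "D2" and n_copies != 4:
        raise ValueError("D2 symmetry requires n_copies = 4")
    if symmetry == "C2" and n_copies != 2:
        raise ValueError("C2 symmetry requires n_copies = 2")
    if not restraints:
        raise ValueError("at least one restraint is required")

    if symmetry == "none":
        return _assemble_sequential(monomer, restraints, n_copies, cfg)

    pairs_idx, lo, up, same_res = _monomer_restraint_arrays(monomer, restraints)
    make_ops = _symmetry_ops_c2 if symmetry == "C2" else _symmetry_ops_d2
    n_params = 5 if symmetry == "C2" else 6
    rng = np.random.default_rng(cfg.seed)
    centroid = monomer.centroid
    reach = monomer.radius + up.max()

    def objective(params: np.ndarray) -> float:
        # minimization target: restraint energy + clash penalty (no contact reward)
        ops = make_ops(params)
        copies = [monomer.coords @ R.T + t for R, t in ops]
        e = _ambiguous_energy(copies, pairs_idx, lo, up, same_res)
        n_clash = 0
        for a in range(len(copies)):
            for b in range(a + 1, len(copies)):
                n_clash += int((cdist(copies[a], copies[b]) < cfg.clash_cutoff).sum())
        return cfg.w_restraint * e + cfg.w_clash * n_clash

    results: list[np.ndarray] = []
    for _ in range(cfg.n_init):
        if symmetry == "C2":
            theta = np.arccos(2 * rng.random() - 1)
            phi = 2 * np.pi * rng.random()
            point = centroid + rng.normal(size=3) * reach / 2
            x0 = np.concatenate([[theta, phi], point])
        else:
            rotvec = Rotation.from_quat(_random_quaternion(rng)).as_rotvec()
            origin = centroid + rng.normal(size=3) * reach / 2
            x0 = np.concatenate([rotvec, origin])
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"maxfev": cfg.max_evals, "xatol": 1e-2, "fatol": 1e-3},
        )
        results.append(res.x if res.fun <= objective(x0) else x0)
    out = [
        _scored_from_ops(monomer, make_ops(params), pairs_idx, lo, up, same_res, cfg)
        for params in results
    ]
    out.sort(key=lambda s: s.total)
    return out[: cfg.n_refine]


def _assemble_sequential(
    monomer: Subunit, restraints: Sequence[Restraint], n_copies: int, cfg: DockConfig
) -> list[ScoredPose]:
    """Dock copies one at a time, each stage a full random-restart search.

    Every stage places the next copy against all previously placed copies,
    with restraints interpreted ambiguously (minimum over chain assignments).
    """
    pairs_idx, lo, up, same_res = _monomer_restraint_arrays(monomer, restraints)
    rng = np.random.default_rng(cfg.seed)
    placed: list[np.ndarray] = [monomer.coords.copy()]
    poses: dict[str, Pose] = {_COPY_IDS[0]: Pose.identity(_COPY_IDS[0])}
    mob0 = monomer.coords
    centroid = monomer.centroid
    reach = up.max() + monomer.radius

    for copy_i in range(1, n_copies):
        def objective(params: np.ndarray) -> float:
            R = _rotvec_matrix(params[:3])
            mob = mob0 @ R.T + params[3:]
            copies = placed + [mob]
            e = _ambiguous_energy(copies, pairs_idx, lo, up, same_res)
            n_clash = sum(
                int((cdist(copies[a], mob) < cfg.clash_cutoff).sum())
                for a in range(len(placed))
            )
            return cfg.w_restraint * e + cfg.w_clash * n_clash

        best: tuple[float, np.ndarray] | None = None
        anchor_pool = np.vstack(placed)
        for _ in range(cfg.n_init):
            q = _random_quaternion(rng)
            R0 = Rotation.from_quat(q).as_matrix()
            site = anchor_pool[rng.integers(len(anchor_pool))]
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            target = site + direction * reach * rng.random() ** (1 / 3)
            x0 = np.concatenate([Rotation.from_matrix(R0).as_rotvec(), target - R0 @ centroid])
            res = minimize(
                objective, x0, method="Nelder-Mead",
                options={"maxfev": cfg.max_evals, "xatol": 1e-2, "fatol": 1e-3},
            )
            params = res.x if res.fun <= objective(x0) else x0
            R = _rotvec_matrix(params[:3])
            total = _assembly_score(
                placed + [mob0 @ R.T + params[3:]], pairs_idx, lo, up, same_res, cfg
            )[0]
            if best is None or total < best[0]:
                best = (total, params)
        R = _rotvec_matrix(best[1][:3])
        placed.append(mob0 @ R.T + best[1][3:])
        poses[_COPY_IDS[copy_i]] = Pose.from_matrix(_COPY_IDS[copy_i], R, best[1][3:])

    total, e, n_clash, n_contact = _assembly_score(placed, pairs_idx, lo, up, same_res, cfg)
    return [ScoredPose(poses, e, n_clash, n_contact, total)]


# ---------------------------------------------------------------------------
# Assembly evaluation against cross-links


def assembly_to_structure(
    monomer_chain: ChainModel,
    poses: Mapping[str, Pose],
    accession: str | None = None,
    model_id: str = "assembly",
) -> StructureModel:
    """Apply per-copy poses to a full-atom monomer chain, one chain per copy."""
    accession = accession or monomer_chain.accession
    chains = []
    for copy_id in sorted(poses):
        pose = poses[copy_id]
        R, t = pose.matrix, np.asarray(pose.translation)
        residues = [
            Residue(r.number, r.name, {a: R @ xyz + t for a, xyz in r.atoms.items()})
            for r in monomer_chain.residues
        ]
        chains.append(ChainModel(copy_id, accession, residues))
    return StructureModel(chains, model_id)


def evaluate_assembly(
    assembly: StructureModel,
    pairs: Sequence[CrossLinkPair],
    cfg: EvalConfig = EvalConfig(),
) -> list[MappedLink]:
    """Check cross-links against an assembled model (delegates to structure_map).

    Assembly chains are assumed to be numbered in UniProt coordinates (true
    for models built by :func:`assembly_to_structure`).
    """
    seqmaps = {c.chain_id: identity_seqmap(c) for c in assembly.chains}
    return map_links(pairs, assembly, seqmaps, cfg)


# ---------------------------------------------------------------------------
# Restraint and score table I/O


def read_restraints_tsv(path: str | Path) -> list[Restraint]:
    frame = pd.read_csv(path, sep="\t")
    return [
        Restraint(
            (str(row["subunit_a"]), int(row["residue_a"])),
            (str(row["subunit_b"]), int(row["residue_b"])),
            float(row.get("lower", 10.0)),
            float(row.get("upper", 30.0)),
        )
        for _, row in frame.iterrows()
    ]


def write_restraints_tsv(restraints: Iterable[Restraint], path: str | Path) -> None:
    rows = [
        {
            "subunit_a": r.site_u[0], "residue_a": r.site_u[1],
            "subunit_b": r.site_v[0], "residue_b": r.site_v[1],
            "lower": r.lower, "upper": r.upper,
        }
        for r in restraints
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_scores_tsv(scored: Sequence[ScoredPose], path: str | Path) -> None:
    rows = [
        {
            "rank": i + 1,
            "e_restraint": s.e_restraint,
            "n_clash": s.n_clash,
            "n_contact": s.n_contact,
            "total": s.total,
        }
        for i, s in enumerate(scored)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
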