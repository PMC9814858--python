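"""Boresch orientational restraint selection and its standard-state free energy.

A Boresch restraint ties a ligand to its receptor through six atoms (three
ligand, three protein) via one distance, two angles and three dihedrals, each
harmonically restrained.  The selection procedure mirrors the practice of
restraint-generation tools for absolute binding free energy calculations:

1. rank ligand heavy atoms by mobility (RMSF over an equilibration
   trajectory already superposed on the protein backbone) and keep the least
   mobile ones as anchor candidates;
2. pair each ligand anchor with every protein alpha-carbon within an 8 A
   cut-off (majority occupancy over the trajectory), completing the sextet
   with the nearest bonded ligand heavy atoms and the residue's backbone C
   and N;
3. extract bond/angle/dihedral time series for every candidate and pick the
   one with the lowest combined standard deviation (dihedral statistics are
   circular);
4. export the trajectory frame closest to the candidate's mean geometry as
   the simulation starting structure.

Because the restrained, non-interacting ligand is confined harmonically, the
free energy of imposing the restraint at standard concentration has a closed
form (:func:`analytic_restraint_dG`), which enters the thermodynamic cycle
as the c->d arrow.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ._constants import DEFAULT_TEMPERATURE, V_STANDARD, kcal_to_kj, kt_kcal

logger = logging.getLogger(__name__)

#: Guard band (rad) around the sin(theta) singularity at 0 and pi; the
#: stiff-spring closed form is invalid for near-collinear equilibrium angles.
THETA_GUARD = 0.1

COORD_NAMES = ("r", "theta_a", "theta_b", "phi_a", "phi_b", "phi_c")
_COORD_CLASS = {
    "r": "bond",
    "theta_a": "angle",
    "theta_b": "angle",
    "phi_a": "dihedral",
    "phi_b": "dihedral",
    "phi_c": "dihedral",
}


# ---------------------------------------------------------------------------
# Circular statistics (dihedrals live on the circle)
# ---------------------------------------------------------------------------


def circular_mean(angles) -> float:
    """Mean direction of angles in radians (atan2 of averaged sin/cos)."""
    a = np.asarray(angles, dtype=float)
    return float(np.arctan2(np.sin(a).mean(), np.cos(a).mean()))


def circular_std(angles) -> float:
    """Circular standard deviation sqrt(-2 ln R) in radians."""
    a = np.asarray(angles, dtype=float)
    r = math.hypot(float(np.sin(a).mean()), float(np.cos(a).mean()))
    r = min(r, 1.0)
    if r <= 0:
        return float("inf")
    return math.sqrt(-2.0 * math.log(r))


def wrap_angle(a):
    """Wrap angle(s) to (-pi, pi]."""
    return -((-np.asarray(a) + np.pi) % (2 * np.pi) - np.pi)


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoreschRestraint:
    """Six-atom orientational restraint with equilibrium geometry and force
    constants.

    Atom indices are 0-based into the topology.  Distances in Angstrom,
    angles in radians; force constants in kcal/mol/A^2 (bond) and
    kcal/mol/rad^2 (angles, dihedrals).
    """

    l1: int
    l2: int
    l3: int
    p1: int
    p2: int
    p3: int
    r0: float
    theta_a0: float
    theta_b0: float
    phi_a0: float
    phi_b0: float
    phi_c0: float
    k_r: float = 10.0
    k_theta_a: float = 10.0
    k_theta_b: float = 10.0
    k_phi_a: float = 10.0
    k_phi_b: float = 10.0
    k_phi_c: float = 10.0

    def __post_init__(self):
        atoms = (self.l1, self.l2, self.l3, self.p1, self.p2, self.p3)
        if len(set(atoms)) != 6:
            raise ValueError(f"restraint atoms must be six distinct atoms, got {atoms}")
        if not self.r0 > 0:
            raise ValueError(f"r0 must be positive, got {self.r0}")
        for name, theta in (("theta_a0", self.theta_a0), ("theta_b0", self.theta_b0)):
            if not (THETA_GUARD < theta < math.pi - THETA_GUARD):
                raise ValueError(
                    f"{name}={theta:.3f} rad is within {THETA_GUARD} rad of the "
                    "sin(theta) singularity; the harmonic closed form is invalid there"
                )
        for name in ("k_r", "k_theta_a", "k_theta_b", "k_phi_a", "k_phi_b", "k_phi_c"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def force_constants(self) -> tuple[float, ...]:
        return (self.k_r, self.k_theta_a, self.k_theta_b, self.k_phi_a, self.k_phi_b, self.k_phi_c)


@dataclass
class RestraintCandidate:
    """A candidate restraint sextet with its coordinate time series.

    ``series`` maps coordinate name (r, theta_a, theta_b, phi_a, phi_b,
    phi_c) to a per-frame array; ``stds`` are linear for bond/angles and
    circular for dihedrals.
    """

    atoms: tuple[int, int, int, int, int, int]  # (l1, l2, l3, p1, p2, p3)
    series: dict[str, np.ndarray]
    means: dict[str, float] = field(default_factory=dict)
    stds: dict[str, float] = field(default_factory=dict)
    score: float | None = None

    def __post_init__(self):
        lengths = {len(v) for v in self.series.values()}
        if len(lengths) != 1:
            raise ValueError("coordinate series must all have the same length")
        if not self.means or not self.stds:
            self.means = {}
            self.stds = {}
            for name in COORD_NAMES:
                v = self.series[name]
                if _COORD_CLASS[name] == "dihedral":
                    self.means[name] = circular_mean(v)
                    self.stds[name] = circular_std(v)
                else:
                    self.means[name] = float(np.mean(v))
                    self.stds[name] = float(np.std(v))

    def to_restraint(
        self,
        k_r: float = 10.0,
        k_theta: float = 10.0,
        k_phi: float = 10.0,
    ) -> BoreschRestraint:
        """Freeze into a :class:`BoreschRestraint` with equilibrium values at
        the per-coordinate (circular) means and the given force constants."""
        l1, l2, l3, p1, p2, p3 = self.atoms
        return BoreschRestraint(
            l1=l1, l2=l2, l3=l3, p1=p1, p2=p2, p3=p3,
            r0=self.means["r"],
            theta_a0=self.means["theta_a"],
            theta_b0=self.means["theta_b"],
            phi_a0=self.means["phi_a"],
            phi_b0=self.means["phi_b"],
            phi_c0=self.means["phi_c"],
            k_r=k_r,
            k_theta_a=k_theta, k_theta_b=k_theta,
            k_phi_a=k_phi, k_phi_b=k_phi, k_phi_c=k_phi,
        )


# ---------------------------------------------------------------------------
# Geometry extraction
# ---------------------------------------------------------------------------


def _trajectory_positions(universe, indices: np.ndarray) -> np.ndarray:
    """Positions of the selected atoms over all frames, shape (F, len(indices), 3)."""
    group = universe.atoms[np.asarray(indices, dtype=int)]
    return np.array([group.positions.copy() for _ in universe.trajectory], dtype=float)


def boresch_series(universe, atoms: tuple[int, ...]) -> dict[str, np.ndarray]:
    """Bond, angle and dihedral time series for one candidate sextet.

    ``atoms`` is (l1, l2, l3, p1, p2, p3); the six coordinates are
    r(L1-P1), theta_a(L2-L1-P1), theta_b(L1-P1-P2), phi_a(L3-L2-L1-P1),
    phi_b(L2-L1-P1-P2), phi_c(L1-P1-P2-P3).
    """
    pos = _trajectory_positions(universe, np.array(atoms))
    return _series_from_positions(pos)


def _series_from_positions(pos: np.ndarray) -> dict[str, np.ndarray]:
    l1, l2, l3, p1, p2, p3 = (pos[:, i, :] for i in range(6))

    def norm(v):
        return np.linalg.norm(v, axis=-1)

    def angle(a, b, c):
        ba = a - b
        bc = c - b
        cosang = np.einsum("ij,ij->i", ba, bc) / (norm(ba) * norm(bc))
        return np.arccos(np.clip(cosang, -1.0, 1.0))

    def dihedral(a, b, c, d):
        b0 = b - a
        b1 = c - b
        b2 = d - c
        n1 = np.cross(b0, b1)
        n2 = np.cross(b1, b2)
        m1 = np.cross(n1, b1 / norm(b1)[:, None])
        x = np.einsum("ij,ij->i", n1, n2)
        y = np.einsum("ij,ij->i", m1, n2)
        return np.arctan2(y, x)

    return {
        "r": norm(l1 - p1),
        "theta_a": angle(l2, l1, p1),
        "theta_b": angle(l1, p1, p2),
        "phi_a": dihedral(l3, l2, l1, p1),
        "phi_b": dihedral(l2, l1, p1, p2),
        "phi_c": dihedral(l1, p1, p2, p3),
    }


# ---------------------------------------------------------------------------
# Selection pipeline
# ---------------------------------------------------------------------------


def ligand_anchor_candidates(universe, ligand_selection: str = "resname LIG", n_top: int = 3):
    """Rank ligand heavy atoms by RMSF and return the *n_top* least mobile.

    The trajectory is assumed already superposed on the protein backbone, so
    per-atom RMSF measures mobility within the binding site.  Ties are broken
    deterministically by atom index.  Returns (indices, rmsf_values), both
    ordered least-mobile first.
    """
    ligand = universe.select_atoms(ligand_selection)
    heavy = ligand.select_atoms("not name H*")
    if len(heavy) < 3:
        raise ValueError(
            f"ligand selection {ligand_selection!r} has {len(heavy)} heavy atoms; need >= 3"
        )
    pos = _trajectory_positions(universe, heavy.indices)
    mean = pos.mean(axis=0)
    rmsf = np.sqrt(((pos - mean[None]) ** 2).sum(axis=2).mean(axis=0))
    order = np.argsort(rmsf, kind="stable")[:n_top]
    return heavy.indices[order], rmsf[order]


def _bonded_heavy_neighbours(universe, index: int, exclude: set[int]) -> list[int]:
    """Heavy neighbours of an atom, bonded if bond information exists,
    nearest-by-first-frame-distance otherwise; sorted nearest first."""
    atom = universe.atoms[index]
    residue_heavy = atom.residue.atoms.select_atoms("not name H*")
    try:
        neighbours = [
            b.partner(atom).index
            for b in atom.bonds
            if not b.partner(atom).name.startswith("H")
        ]
    except Exception:
        neighbours = []
    if not neighbours:
        others = [i for i in residue_heavy.indices if i != index and i not in exclude]
        d = np.linalg.norm(
            universe.atoms[others].positions - atom.position[None, :], axis=1
        )
        return [others[i] for i in np.argsort(d, kind="stable")]
    neighbours = [i for i in neighbours if i not in exclude]
    d = np.linalg.norm(
        universe.atoms[neighbours].positions - atom.position[None, :], axis=1
    )
    return [neighbours[i] for i in np.argsort(d, kind="stable")]


def enumerate_restraints(
    universe,
    ligand_anchors,
    cutoff: float = 8.0,
    min_occupancy: float = 0.5,
    protein_selection: str = "protein",
) -> list[RestraintCandidate]:
    """Enumerate candidate Boresch sextets around the given ligand anchors.

    For each anchor L1, every protein alpha carbon within *cutoff* Angstrom
    of L1 in at least *min_occupancy* of the frames becomes P1, completed by
    the residue's backbone C and N (P2, P3) and the nearest bonded heavy
    ligand atoms (L2, L3).  Candidates whose mean angles fall inside the
    collinearity guard band are excluded.  Returns an empty list (with a
    warning) when no alpha carbon is in range.
    """
    calphas = universe.select_atoms(f"({protein_selection}) and name CA")
    candidates: list[RestraintCandidate] = []
    anchors = np.atleast_1d(np.asarray(ligand_anchors, dtype=int))
    if len(calphas) == 0:
        logger.warning("no alpha carbons in protein selection")
        return []
    ca_pos = _trajectory_positions(universe, calphas.indices)  # (F, C, 3)
    for l1 in anchors:
        l1_pos = _trajectory_positions(universe, np.array([l1]))[:, 0, :]
        dist = np.linalg.norm(ca_pos - l1_pos[:, None, :], axis=2)  # (F, C)
        occupancy = (dist <= cutoff).mean(axis=0)
        near = np.nonzero(occupancy >= min_occupancy)[0]
        l2_list = _bonded_heavy_neighbours(universe, int(l1), exclude=set())
        if not l2_list:
            continue
        l2 = l2_list[0]
        l3_list = _bonded_heavy_neighbours(universe, int(l2), exclude={int(l1)})
        if not l3_list:
            continue
        l3 = l3_list[0]
        for ci in near:
            p1_atom = calphas[int(ci)]
            residue = p1_atom.residue
            p2 = residue.atoms.select_atoms("name C")
            p3 = residue.atoms.select_atoms("name N")
            if len(p2) != 1 or len(p3) != 1:
                continue
            atoms = (int(l1), int(l2), int(l3), int(p1_atom.index), int(p2.indices[0]), int(p3.indices[0]))
            if len(set(atoms)) != 6:
                continue
            series = boresch_series(universe, atoms)
            cand = RestraintCandidate(atoms=atoms, series=series)
            collinear = any(
                not (THETA_GUARD < cand.means[name] < math.pi - THETA_GUARD)
                for name in ("theta_a", "theta_b")
            )
            if collinear:
                logger.debug("candidate %s excluded: near-collinear mean angle", atoms)
                continue
            candidates.append(cand)
    if not candidates:
        logger.warning("no restraint candidates found within %.1f A cut-off", cutoff)
    return candidates


def score_candidates(candidates: list[RestraintCandidate]) -> None:
    """Score candidates in place by median-normalised combined variability.

    Each candidate's score is the sum over its six coordinates of
    sigma / median(sigma of that coordinate class across candidates), a
    dimensionless combination of the mixed-unit standard deviations
    (classes: bond, angle, dihedral).  Lower is better.
    """
    medians: dict[str, float] = {}
    for cls in ("bond", "angle", "dihedral"):
        values = [
            c.stds[name]
            for c in candidates
            for name in COORD_NAMES
            if _COORD_CLASS[name] == cls
        ]
        med = float(np.median(values)) if values else 0.0
        medians[cls] = med if med > 0 else 1.0
    for c in candidates:
        c.score = float(
            sum(c.stds[name] / medians[_COORD_CLASS[name]] for name in COORD_NAMES)
        )


def select_restraint(candidates: list[RestraintCandidate]) -> RestraintCandidate:
    """Pick the candidate with the lowest combined standard deviation.

    Ties are broken by smallest bond standard deviation, then by lowest atom
    indices.  Raises ``ValueError`` on an empty candidate list.
    """
    if not candidates:
        raise ValueError("no restraint candidates to select from")
    score_candidates(candidates)
    return min(candidates, key=lambda c: (c.score, c.stds["r"], c.atoms))


def pick_reference_frame(candidate: RestraintCandidate) -> int:
    """Frame whose geometry is closest to the candidate's mean geometry.

    Minimises the sum over the six coordinates of ((value - mean)/sigma)^2,
    with dihedral deviations wrapped to (-pi, pi].  Coordinates with zero
    sigma are omitted from the metric (logged).  Ties resolve to the
    earliest frame.
    """
    n_frames = len(next(iter(candidate.series.values())))
    metric = np.zeros(n_frames)
    used = 0
    for name in COORD_NAMES:
        sigma = candidate.stds[name]
        if sigma <= 0 or not np.isfinite(sigma):
            logger.info("coordinate %s has zero variance; omitted from frame metric", name)
            continue
        dev = candidate.series[name] - candidate.means[name]
        if _COORD_CLASS[name] == "dihedral":
            dev = wrap_angle(dev)
        metric += (dev / sigma) ** 2
        used += 1
    if used == 0:
        return 0
    return int(np.argmin(metric))


def select_boresch_restraint(
    universe,
    ligand_selection: str = "resname LIG",
    n_anchors: int = 3,
    cutoff: float = 8.0,
    k_r: float = 10.0,
    k_theta: float = 10.0,
    k_phi: float = 10.0,
):
    """Full selection pipeline: anchors -> candidates -> best restraint.

    Returns ``(BoreschRestraint, RestraintCandidate, reference_frame)``.
    """
    anchors, _ = ligand_anchor_candidates(universe, ligand_selection, n_top=n_anchors)
    candidates = enumerate_restraints(universe, anchors, cutoff=cutoff)
    best = select_restraint(candidates)
    frame = pick_reference_frame(best)
    return best.to_restraint(k_r=k_r, k_theta=k_theta, k_phi=k_phi), best, frame


# ---------------------------------------------------------------------------
# Analytic standard-state free energy
# ---------------------------------------------------------------------------


def analytic_restraint_dG(
    restraint: BoreschRestraint,
    temperature: float = DEFAULT_TEMPERATURE,
    v_standard: float = V_STANDARD,
) -> float:
    """Free energy (kcal/mol) of imposing the six harmonic restraints on a
    non-interacting ligand at standard concentration (the c->d arrow of the
    cycle).

    DG = -kT ln[ 8 pi^2 V0 sqrt(prod K) / (r0^2 sin(thA0) sin(thB0) (2 pi kT)^3) ]

    valid in the stiff-spring regime away from the sin(theta) singularities
    (enforced by the restraint's guard band).
    """
    kt = kt_kcal(temperature)
    prod_k = math.prod(restraint.force_constants)
    numerator = 8.0 * math.pi**2 * v_standard * math.sqrt(prod_k)
    denominator = (
        restraint.r0**2
        * math.sin(restraint.theta_a0)
        * math.sin(restraint.theta_b0)
        * (2.0 * math.pi * kt) ** 3
    )
    return -kt * math.log(numerator / denominator)


# ---------------------------------------------------------------------------
# GROMACS topology export
# ---------------------------------------------------------------------------


def to_gromacs_topology(restraint: BoreschRestraint) -> str:
    """GROMACS ``[ intermolecular_interactions ]`` fragment for the restraint.

    Bond as type 6 (harmonic, no exclusions), angles type 1, dihedrals type
    2, each with lambda-coupled force constants switching 0 -> K.  Atom
    indices are written 1-based; units follow ``.top`` conventions (nm,
    degrees, kJ/mol).
    """
    l1, l2, l3 = restraint.l1 + 1, restraint.l2 + 1, restraint.l3 + 1
    p1, p2, p3 = restraint.p1 + 1, restraint.p2 + 1, restraint.p3 + 1
    r0_nm = restraint.r0 / 10.0
    k_r_kj = kcal_to_kj(restraint.k_r) * 100.0  # kcal/mol/A^2 -> kJ/mol/nm^2
    deg = math.degrees
    lines = [
        "[ intermolecular_interactions ]",
        "[ bonds ]",
        "; ai     aj     type   bA         kA         bB         kB",
        f"  {l1:<6d} {p1:<6d} 6      {r0_nm:<10.5f} 0.0        {r0_nm:<10.5f} {k_r_kj:.2f}",
        "",
        "[ angles ]",
        "; ai     aj     ak     type   thA        kA         thB        kB",
        f"  {l2:<6d} {l1:<6d} {p1:<6d} 1      {deg(restraint.theta_a0):<10.3f} 0.0        "
        f"{deg(restraint.theta_a0):<10.3f} {kcal_to_kj(restraint.k_theta_a):.2f}",
        f"  {l1:<6d} {p1:<6d} {p2:<6d} 1      {deg(restraint.theta_b0):<10.3f} 0.0        "
        f"{deg(restraint.theta_b0):<10.3f} {kcal_to_kj(restraint.k_theta_b):.2f}",
        "",
        "[ dihedrals ]",
        "; ai     aj     ak     al     type   phiA       kA         phiB       kB",
        f"  {l3:<6d} {l2:<6d} {l1:<6d} {p1:<6d} 2      {deg(restraint.phi_a0):<10.3f} 0.0        "
        f"{deg(restraint.phi_a0):<10.3f} {kcal_to_kj(restraint.k_phi_a):.2f}",
        f"  {l2:<6d} {l1:<6d} {p1:<6d} {p2:<6d} 2      {deg(restraint.phi_b0):<10.3f} 0.0        "
        f"{deg(restraint.phi_b0):<10.3f} {kcal_to_kj(restraint.k_phi_b):.2f}",
        f"  {l1:<6d} {p1:<6d} {p2:<6d} {p3:<6d} 2      {deg(restraint.phi_c0):<10.3f} 0.0        "
        f"{deg(restraint.phi_c0):<10.3f} {kcal_to_kj(restraint.k_phi_c):.2f}",
        "",
    ]
    return "\n".join(lines)
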