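"""Synthetic inputs with known ground truth for every pipeline stage.

Four generator families:

* harmonic alchemical ensembles — 1-D harmonic windows ``u_k(x) = K_k x^2/2
  + c_k`` whose reduced free energies are known exactly
  (``f_k = -1/2 ln(2pi/K_k) + c_k``), the canonical validation standard for
  free-energy estimators;
* AR(1) time series with closed-form statistical inefficiency
  ``g = (1+rho)/(1-rho)``, for validating decorrelation;
* toy protein-ligand trajectories with prescribed per-atom fluctuation
  amplitudes, for validating restraint selection against the construction
  ground truth;
* benchmark sets emulating a multi-system fragment-optimisation campaign
  (59 ligands over 4 systems by default) with configurable population
  correlation, systematic offsets and censoring.

All generators are bit-reproducible from a master seed; per-component
streams are derived from it so pipeline-level regression tests stay stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._constants import DEFAULT_TEMPERATURE, KB_KCAL, kt_kcal
from .benchmark import LigandRecord
from .io import LambdaSchedule, LegEnsemble, WindowSamples

#: Experimental free energy at a Ki of 1 mM (a typical reporting bound for
#: weak binders) at 298.15 K; used as the default censoring bound.
DEFAULT_CENSOR_BOUND = KB_KCAL * DEFAULT_TEMPERATURE * math.log(1e-3)


def _rng(seed, stream: int) -> np.random.Generator:
    """Derived per-component stream from a master seed."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng([int(seed), int(stream)])


# ---------------------------------------------------------------------------
# Harmonic alchemical ensembles
# ---------------------------------------------------------------------------


@dataclass
class HarmonicSpec:
    """Per-window harmonic potentials for one alchemical stage.

    ``k`` are spring constants in kT/A^2 and ``c`` energy offsets in kT, one
    per window.  ``dk_dlam``/``dc_dlam`` are the exact path derivatives used
    to emit dH/dlambda series (filled by the :meth:`linear` constructor;
    finite-differenced from the window values otherwise).
    """

    k: np.ndarray
    c: np.ndarray
    n_samples: int = 1000
    seed: int = 0
    temperature: float = DEFAULT_TEMPERATURE
    dk_dlam: np.ndarray | None = None
    dc_dlam: np.ndarray | None = None

    def __post_init__(self):
        self.k = np.asarray(self.k, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if np.any(self.k <= 0):
            raise ValueError("spring constants must be positive")
        if self.k.shape != self.c.shape:
            raise ValueError("k and c must have the same length")

    @classmethod
    def linear(
        cls,
        k_start: float,
        k_end: float,
        lambdas,
        c_start: float = 0.0,
        c_end: float = 0.0,
        n_samples: int = 1000,
        seed: int = 0,
        temperature: float = DEFAULT_TEMPERATURE,
    ) -> "HarmonicSpec":
        """Windows on the linear path K(lam) = K0 + lam (K1 - K0) (same for c)."""
        lam = np.asarray(lambdas, dtype=float)
        return cls(
            k=k_start + lam * (k_end - k_start),
            c=c_start + lam * (c_end - c_start),
            n_samples=n_samples,
            seed=seed,
            temperature=temperature,
            dk_dlam=np.full_like(lam, k_end - k_start),
            dc_dlam=np.full_like(lam, c_end - c_start),
        )

    @property
    def n_windows(self) -> int:
        return len(self.k)

    @property
    def analytic_f(self) -> np.ndarray:
        """Exact reduced free energy per window (kT), up to a common constant."""
        return -0.5 * np.log(2.0 * np.pi / self.k) + self.c

    @property
    def analytic_delta_a(self) -> float:
        """Exact reduced free-energy change over the stage (kT)."""
        f = self.analytic_f
        return float(f[-1] - f[0])


def _stage_windows(
    spec: HarmonicSpec, lambdas, rng: np.random.Generator, dt_ps: float = 10.0
) -> list[WindowSamples]:
    lam = np.asarray(lambdas, dtype=float)
    if len(lam) != spec.n_windows:
        raise ValueError(
            f"schedule stage has {len(lam)} windows but spec defines {spec.n_windows}"
        )
    kt = kt_kcal(spec.temperature)
    if spec.dk_dlam is not None:
        dk, dc = spec.dk_dlam, spec.dc_dlam
    else:
        dk = np.gradient(spec.k, lam)
        dc = np.gradient(spec.c, lam)
    windows = []
    times = np.arange(spec.n_samples) * dt_ps
    for j in range(spec.n_windows):
        x = rng.normal(0.0, 1.0 / math.sqrt(spec.k[j]), size=spec.n_samples)
        x2 = x**2
        # u_i(x) - u_j(x) in kT, converted to kcal/mol for storage
        energies = (
            0.5 * (spec.k[None, :] - spec.k[j]) * x2[:, None]
            + (spec.c[None, :] - spec.c[j])
        ) * kt
        dhdl = ((0.5 * dk[j] * x2 + dc[j]) * kt)[:, None]
        windows.append(
            WindowSamples(
                window_index=j,
                own_lambda=(lam[j],),
                times=times,
                energies=energies,
                dhdl=dhdl,
                temperature=spec.temperature,
                foreign_lambdas=tuple((v,) for v in lam),
            )
        )
    return windows


def gen_harmonic_ensemble(
    spec: "HarmonicSpec | dict[str, HarmonicSpec]",
    schedule: LambdaSchedule,
    replica_id: str = "r1",
    ligand_id: str = "harmonic",
) -> tuple[LegEnsemble, dict[str, float]]:
    """Draw a full leg of harmonic windows with exact analytic stage DAs.

    *spec* is one :class:`HarmonicSpec` (single-stage schedule) or a mapping
    stage name -> spec.  Samples are iid (already decorrelated); the
    cross-evaluation matrix is exact by construction.  Returns the ensemble
    and the analytic reduced free-energy change per stage (kT).
    """
    if isinstance(spec, HarmonicSpec):
        if len(schedule.stages) != 1:
            raise ValueError("a single HarmonicSpec needs a single-stage schedule")
        spec = {schedule.stages[0][0]: spec}
    windows: list[WindowSamples] = []
    analytic: dict[str, float] = {}
    for stream, (stage_name, lams) in enumerate(schedule.stages):
        stage_spec = spec[stage_name]
        rng = _rng(stage_spec.seed, stream)
        windows.extend(_stage_windows(stage_spec, lams, rng))
        analytic[stage_name] = stage_spec.analytic_delta_a
    leg = LegEnsemble(
        schedule=schedule,
        windows=windows,
        replica_id=replica_id,
        ligand_id=ligand_id,
    )
    return leg, analytic


# ---------------------------------------------------------------------------
# AR(1) series
# ---------------------------------------------------------------------------


def gen_ar1_series(rho: float, n: int, seed=0) -> np.ndarray:
    """Stationary AR(1) series with unit marginal variance.

    x_t = rho x_{t-1} + sqrt(1-rho^2) eps_t; the statistical inefficiency is
    (1+rho)/(1-rho).  Requires |rho| < 1.
    """
    if abs(rho) >= 1:
        raise ValueError(f"AR(1) requires |rho| < 1, got {rho}")
    from scipy.signal import lfilter

    rng = _rng(seed, 1)
    eps = rng.normal(size=n)
    driven = math.sqrt(1.0 - rho**2) * eps
    driven[0] = eps[0]  # stationary start: x_0 ~ N(0, 1)
    return lfilter([1.0], [1.0, -rho], driven)


def ar1_inefficiency(rho: float) -> float:
    """Closed-form statistical inefficiency of an AR(1) process."""
    return (1.0 + rho) / (1.0 - rho)


# ---------------------------------------------------------------------------
# Toy binding-site trajectories
# ---------------------------------------------------------------------------


@dataclass
class ToyComplex:
    """A toy protein-ligand complex with construction ground truth.

    ``universe`` is an in-memory MDAnalysis Universe; ``anchor_truth`` is
    the global index of the least-mobile ligand heavy atom and
    ``ca_within_cutoff`` the alpha-carbon indices within the contact cut-off
    of it (both from the noise-free base geometry).
    """

    universe: object
    ligand_heavy_indices: np.ndarray
    amplitudes: np.ndarray
    anchor_truth: int
    ca_within_cutoff: tuple[int, ...]
    cutoff: float

    def write(self, pdb_path, traj_path=None):
        """Write topology (PDB) and optionally the trajectory (XTC/DCD)."""
        import MDAnalysis as mda

        self.universe.atoms.write(str(pdb_path))
        if traj_path is not None:
            with mda.Writer(str(traj_path), self.universe.atoms.n_atoms) as w:
                for _ in self.universe.trajectory:
                    w.write(self.universe.atoms)


def gen_binding_site_traj(
    seed=0,
    n_frames: int = 100,
    ligand_amplitudes=(0.1, 0.3, 0.4, 0.5, 0.5),
    protein_amplitude: float = 0.05,
    n_residues: int = 12,
    protein_radius: float = 6.5,
    cutoff: float = 8.0,
) -> ToyComplex:
    """Build a toy complex trajectory with known least-mobile ligand atom.

    The protein is a ring of glycine residues (N, CA, C backbone atoms) of
    radius *protein_radius* around the ligand, a short carbon chain at the
    centre whose atoms fluctuate isotropically with the given Gaussian
    *ligand_amplitudes* (Angstrom).  Two hydrogens ride on the first ligand
    atom.  Ground truth (least-mobile heavy atom; alpha carbons within
    *cutoff* of it in the base geometry) is recorded on the result.
    """
    import MDAnalysis as mda

    rng = _rng(seed, 2)
    amplitudes = np.asarray(ligand_amplitudes, dtype=float)
    n_lig = len(amplitudes)
    if n_lig < 3:
        raise ValueError("need at least 3 ligand heavy atoms")

    # base geometry: ligand chain along x at the origin, protein ring around it
    lig_base = np.zeros((n_lig, 3))
    lig_base[:, 0] = np.arange(n_lig) * 1.5
    lig_base[:, 1] = 0.3 * (np.arange(n_lig) % 2)  # slight zig-zag, avoids collinearity
    lig_base -= lig_base.mean(axis=0)
    h_base = lig_base[0] + np.array([[0.6, 0.8, 0.0], [0.6, -0.8, 0.0]])

    prot_base = []
    for i in range(n_residues):
        ang = 2.0 * math.pi * i / n_residues
        ca = np.array(
            [protein_radius * math.cos(ang), protein_radius * math.sin(ang), 1.0 - 2.0 * (i % 2)]
        )
        n_at = ca + np.array([-0.8, -0.9, 0.4])
        c_at = ca + np.array([0.8, 0.9, -0.4])
        prot_base.extend([n_at, ca, c_at])
    prot_base = np.array(prot_base)

    n_prot = len(prot_base)
    n_atoms = n_prot + n_lig + 2
    atom_resindex = np.concatenate(
        [np.repeat(np.arange(n_residues), 3), np.full(n_lig + 2, n_residues)]
    )
    u = mda.Universe.empty(
        n_atoms,
        n_residues=n_residues + 1,
        atom_resindex=atom_resindex,
        residue_segindex=np.zeros(n_residues + 1, dtype=int),
        trajectory=True,
    )
    names = ["N", "CA", "C"] * n_residues + [f"C{i + 1}" for i in range(n_lig)] + ["H1", "H2"]
    elements = ["N", "C", "C"] * n_residues + ["C"] * n_lig + ["H", "H"]
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("elements", elements)
    u.add_TopologyAttr("resnames", ["GLY"] * n_residues + ["LIG"])
    u.add_TopologyAttr("resids", list(range(1, n_residues + 2)))
    lig_offset = n_prot
    bonds = [(lig_offset + i, lig_offset + i + 1) for i in range(n_lig - 1)]
    bonds += [(lig_offset, n_prot + n_lig), (lig_offset, n_prot + n_lig + 1)]  # hydrogens on C1
    u.add_bonds(bonds)

    base = np.concatenate([prot_base, lig_base, h_base])
    sigmas = np.concatenate(
        [np.full(n_prot, protein_amplitude), amplitudes, np.full(2, amplitudes[0])]
    )
    coords = base[None, :, :] + rng.normal(size=(n_frames, n_atoms, 3)) * sigmas[None, :, None]
    u.load_new(coords.astype(np.float32), order="fac")

    heavy_indices = np.arange(lig_offset, lig_offset + n_lig)
    anchor_local = int(np.argmin(amplitudes))  # first minimum wins, matching tie-break
    anchor_truth = int(heavy_indices[anchor_local])
    ca_indices = np.array([3 * i + 1 for i in range(n_residues)])
    d = np.linalg.norm(prot_base[ca_indices] - lig_base[anchor_local][None, :], axis=1)
    ca_within = tuple(int(i) for i in ca_indices[d <= cutoff])
    return ToyComplex(
        universe=u,
        ligand_heavy_indices=heavy_indices,
        amplitudes=amplitudes,
        anchor_truth=anchor_truth,
        ca_within_cutoff=ca_within,
        cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# Benchmark sets
# ---------------------------------------------------------------------------

#: Default per-system systematic shifts (kcal/mol, added to the calculated
#: values): one well-matched system and three with the 1-2.5 kcal/mol
#: overbinding shifts typical of absolute alchemical benchmarks.
DEFAULT_SYSTEM_OFFSETS = (0.0, -1.0, -2.0, -2.5)


def gen_benchmark_set(
    n_ligands: int = 59,
    seed=0,
    dg_range: tuple[float, float] = (-13.0, -4.0),
    slope: float = 1.0,
    noise_sd: float | None = None,
    target_rho: float | None = 0.89,
    system_offsets=DEFAULT_SYSTEM_OFFSETS,
    replica_std_mean: float = 0.79,
    replica_std_sd: float = 0.38,
    censor_bound: float | None = DEFAULT_CENSOR_BOUND,
) -> tuple[list[LigandRecord], dict]:
    """Draw a synthetic multi-system benchmark set with known population
    structure.

    Experimental free energies are uniform over *dg_range* (a
    millimolar-to-nanomolar activity window); calculated values are
    ``offset + slope * dg_exp + noise``.  The Gaussian noise is either given
    directly (*noise_sd*) or derived from a target within-system population
    Pearson correlation *target_rho*.  Replica standard deviations are drawn
    from a clipped normal around *replica_std_mean* so downstream decision
    tests see realistic uncertainty.  Records weaker than *censor_bound*
    are censored at the bound (upper-affinity bounds).  Requires
    ``n_ligands >= 3``.

    Returns ``(records, info)`` where *info* carries the population
    parameters actually used.
    """
    if n_ligands < 3:
        raise ValueError(f"need at least 3 ligands, got {n_ligands}")
    rng = _rng(seed, 3)
    lo, hi = min(dg_range), max(dg_range)
    sigma_x = (hi - lo) / math.sqrt(12.0)
    if noise_sd is None:
        if target_rho is None:
            raise ValueError("give either noise_sd or target_rho")
        if not 0 < target_rho <= 1:
            raise ValueError("target_rho must be in (0, 1]")
        noise_sd = abs(slope) * sigma_x * math.sqrt(1.0 / target_rho**2 - 1.0)
    rho_pop = abs(slope) * sigma_x / math.hypot(slope * sigma_x, noise_sd) if noise_sd >= 0 else 1.0

    offsets = tuple(system_offsets) if system_offsets else (0.0,)
    n_systems = len(offsets)
    records = []
    for i in range(n_ligands):
        system = i % n_systems
        dg_exp = rng.uniform(lo, hi)
        dg_calc = offsets[system] + slope * dg_exp + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
        rep_std = float(np.clip(rng.normal(replica_std_mean, replica_std_sd), 0.05, None))
        censored = censor_bound is not None and dg_exp > censor_bound
        records.append(
            LigandRecord(
                ligand_id=f"lig{i + 1}",
                dg_calc=float(dg_calc),
                replica_std=rep_std,
                dg_exp=float(censor_bound) if censored else float(dg_exp),
                censored=censored,
                bound_direction="upper" if censored else "none",
                system_id=f"system{system + 1}",
            )
        )
    info = {
        "population_rho": rho_pop,
        "noise_sd": noise_sd,
        "slope": slope,
        "system_offsets": offsets,
        "sigma_x": sigma_x,
        "n_censored": sum(r.censored for r in records),
    }
    return records, info
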