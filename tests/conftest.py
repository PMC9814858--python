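import numpy as np
import pytest

from abfekit import LambdaSchedule, WindowSamples


def make_window(
    n_frames: int = 10,
    n_stage_windows: int = 2,
    window_index: int = 0,
    dt_ps: float = 10.0,
    dhdl=None,
    energies=None,
    temperature: float = 298.15,
):
    """Small well-formed WindowSamples for structural tests."""
    times = np.arange(n_frames) * dt_ps
    if energies is None:
        energies = np.zeros((n_frames, n_stage_windows))
        for j in range(n_stage_windows):
            energies[:, j] = j * 0.1 * (1 + np.arange(n_frames))
    return WindowSamples(
        window_index=window_index,
        own_lambda=(0.0,),
        times=times,
        energies=energies,
        dhdl=dhdl,
        temperature=temperature,
    )


@pytest.fixture(scope="session")
def toy_complex():
    from abfekit import gen_binding_site_traj

    return gen_binding_site_traj(seed=0)


def tiny_universe(lig_coords, prot_residues, n_frames: int = 2, jitter: float = 0.0, seed: int = 0):
    """Hand-built complex: one LIG residue of carbon atoms plus GLY residues.

    *lig_coords* is (n_lig, 3); *prot_residues* is a list of dicts with keys
    "N", "CA", "C" mapping to 3-vectors.  The trajectory repeats the base
    geometry *n_frames* times (optionally with Gaussian jitter).
    """
    import MDAnalysis as mda

    lig_coords = np.asarray(lig_coords, dtype=float)
    n_lig = len(lig_coords)
    n_res = len(prot_residues)
    n_atoms = 3 * n_res + n_lig
    atom_resindex = np.concatenate(
        [np.repeat(np.arange(n_res), 3), np.full(n_lig, n_res)]
    )
    u = mda.Universe.empty(
        n_atoms,
        n_residues=n_res + 1,
        atom_resindex=atom_resindex,
        residue_segindex=np.zeros(n_res + 1, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", ["N", "CA", "C"] * n_res + [f"C{i+1}" for i in range(n_lig)])
    u.add_TopologyAttr("elements", ["N", "C", "C"] * n_res + ["C"] * n_lig)
    u.add_TopologyAttr("resnames", ["GLY"] * n_res + ["LIG"])
    u.add_TopologyAttr("resids", list(range(1, n_res + 2)))
    lig_offset = 3 * n_res
    u.add_bonds([(lig_offset + i, lig_offset + i + 1) for i in range(n_lig - 1)])
    base = np.concatenate(
        [np.concatenate([[r["N"], r["CA"], r["C"]] for r in prot_residues]), lig_coords]
    )
    coords = np.repeat(base[None, :, :], n_frames, axis=0)
    if jitter:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(scale=jitter, size=coords.shape)
    u.load_new(coords.astype(np.float32), order="fac")
    return u


def two_state_schedule():
    return LambdaSchedule.single_stage("coul", (0.0, 1.0))
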