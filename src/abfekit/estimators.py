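"""Free-energy estimators and thermodynamic-cycle assembly.

The workhorse is :class:`MBAR`, a model object holding the reduced-potential
matrix ``u_kn`` and per-window sample counts ``N_k``; ``fit()`` solves the
multistate Bennett acceptance ratio self-consistency equations

    f_i = -ln sum_n exp(-u_i(x_n)) / sum_k N_k exp(f_k - u_k(x_n))

anchored at ``f_0 = 0``, by self-consistent iteration with Newton-Raphson
acceleration, initialised from chained pairwise BAR estimates.  The returned
:class:`MBARResults` carries the reduced free energies, their asymptotic
covariance, and overlap diagnostics.

Higher-level routines turn a :class:`~abfekit.io.LegEnsemble` into per-stage
free energies (one MBAR solve per stage; thermodynamic integration as a
secondary cross-check), assemble the full binding thermodynamic cycle with
the analytic restraint and finite-size charge corrections, and aggregate
independent replicas.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from ._constants import kt_kcal
from .io import LegEnsemble, WindowSamples

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """MBAR solver failed to converge; carries the final residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


# ---------------------------------------------------------------------------
# Decorrelation
# ---------------------------------------------------------------------------


def statistical_inefficiency(series) -> float:
    """Statistical inefficiency g >= 1 of a stationary time series.

    g = 1 + 2 * sum_t (1 - t/N) * rho(t), with the integrated autocorrelation
    sum truncated at the first non-positive rho(t) and the result clamped to
    >= 1.  Samples taken every g frames are approximately independent.

    A zero-variance series returns g = 1 with a logged warning.  Series
    shorter than 4 raise ``ValueError``.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if n < 4:
        raise ValueError(f"series too short for autocorrelation analysis (n={n} < 4)")
    x = x - x.mean()
    c0 = np.dot(x, x) / n
    if c0 <= 0 or not np.isfinite(c0):
        logger.warning("zero-variance series; statistical inefficiency set to 1")
        return 1.0
    # biased autocovariance via FFT; the (1 - t/N) window in the definition
    # exactly cancels the 1/(N-t) unbiased normalisation, so the biased
    # estimate c[t]/c[0] is the summand.
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n] / n
    rho = acov / acov[0]
    neg = np.nonzero(rho[1:] <= 0)[0]
    cut = (neg[0] + 1) if neg.size else n
    g = 1.0 + 2.0 * rho[1:cut].sum()
    return max(g, 1.0)


def subsample(window: WindowSamples, g: float, min_frames: int = 50) -> WindowSamples:
    """Subsample a window at stride ``ceil(g)``, keeping at least *min_frames*.

    The stride is capped so that at least *min_frames* frames remain (the cap
    is logged); the first retained frame is frame 0.
    """
    if g < 1:
        raise ValueError(f"statistical inefficiency must be >= 1, got {g}")
    stride = math.ceil(g)
    if stride <= 1:
        return window
    max_stride = max(1, window.n_frames // min_frames)
    if stride > max_stride:
        logger.warning(
            "stride %d would leave fewer than %d of %d frames; capped at %d",
            stride,
            min_frames,
            window.n_frames,
            max_stride,
        )
        stride = max_stride
    return window.sliced(slice(0, None, stride))


def decorrelate_window(window: WindowSamples, component: int | None = None) -> WindowSamples:
    """Decorrelate one window on its dH/dlambda series.

    The observable is the window's own dH/dlambda time series (summed over
    components unless *component* selects one); g is estimated from it and
    the window subsampled accordingly.  Windows without dH/dlambda data are
    returned unchanged with a warning.
    """
    if window.dhdl is None or window.dhdl.size == 0:
        logger.warning(
            "window %d has no dH/dlambda series; skipping decorrelation", window.window_index
        )
        return window
    obs = window.dhdl[:, component] if component is not None else window.dhdl.sum(axis=1)
    g = statistical_inefficiency(obs)
    return subsample(window, g)


def decorrelate_leg(leg: LegEnsemble) -> LegEnsemble:
    """Apply :func:`decorrelate_window` to every window of a leg."""
    from dataclasses import replace

    return replace(leg, windows=[decorrelate_window(w) for w in leg.windows])


# ---------------------------------------------------------------------------
# BAR (pairwise; used to initialise MBAR and as an independent two-state path)
# ---------------------------------------------------------------------------


def bar_solve(w_forward, w_reverse, tol: float = 1e-12) -> float:
    """Bennett acceptance ratio estimate of Delta f (reduced units).

    *w_forward* are reduced work values u_1 - u_0 evaluated on samples from
    state 0; *w_reverse* are u_0 - u_1 on samples from state 1.  The Bennett
    implicit equation is solved by bracketed root finding.
    """
    w_f = np.asarray(w_forward, dtype=float)
    w_r = np.asarray(w_reverse, dtype=float)
    n_f, n_r = len(w_f), len(w_r)
    if n_f == 0 or n_r == 0:
        raise ValueError("BAR requires samples from both states")
    m = math.log(n_f / n_r)

    def fermi_residual(df: float) -> float:
        # Bennett implicit equation, log of each Fermi-function sum for stability:
        # sum_F 1/(1+exp(M + w_F - df)) = sum_R 1/(1+exp(-M + w_R + df))
        lf = logsumexp(-np.logaddexp(0.0, m + w_f - df))
        lr = logsumexp(-np.logaddexp(0.0, -m + w_r + df))
        return lf - lr

    # exponential-averaging estimates bracket the BAR solution loosely
    df0 = -(logsumexp(-w_f) - math.log(n_f))
    df1 = logsumexp(-w_r) - math.log(n_r)
    lo, hi = min(df0, df1) - 10.0, max(df0, df1) + 10.0
    flo, fhi = fermi_residual(lo), fermi_residual(hi)
    for _ in range(60):
        if flo * fhi <= 0:
            break
        lo -= 20.0
        hi += 20.0
        flo, fhi = fermi_residual(lo), fermi_residual(hi)
    else:
        raise ConvergenceError("could not bracket the BAR solution", float("nan"))
    return brentq(fermi_residual, lo, hi, xtol=tol)


# ---------------------------------------------------------------------------
# MBAR
# ---------------------------------------------------------------------------


@dataclass
class MBARResults:
    """Solution of the MBAR equations for one stage.

    ``f_k`` are reduced free energies anchored at ``f_0 = 0``; ``theta`` is
    the asymptotic covariance matrix of the ``f_k`` estimates, so
    ``var(f_j - f_i) = theta[i,i] + theta[j,j] - 2 theta[i,j]``.
    """

    f_k: np.ndarray
    theta: np.ndarray
    n_k: np.ndarray
    n_iterations: int
    final_residual: float
    overlap_matrix: np.ndarray
    low_overlap_pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return len(self.f_k)

    def delta_f(self, i: int = 0, j: int = -1) -> float:
        """Reduced free-energy difference f_j - f_i."""
        return float(self.f_k[j] - self.f_k[i])

    def d_delta_f(self, i: int = 0, j: int = -1) -> float:
        """Asymptotic standard error of f_j - f_i (reduced units)."""
        var = self.theta[i, i] + self.theta[j, j] - 2.0 * self.theta[i, j]
        return float(np.sqrt(max(var, 0.0)))

    def summary(self) -> str:
        lines = [
            "MBAR results",
            f"  states: {self.n_states}   iterations: {self.n_iterations}"
            f"   residual: {self.final_residual:.2e}",
            f"  Delta f (0 -> {self.n_states - 1}): "
            f"{self.delta_f():.4f} +/- {self.d_delta_f():.4f} kT",
            "  k    N_k      f_k        SE(f_k - f_0)",
        ]
        for k in range(self.n_states):
            lines.append(
                f"  {k:<4d} {self.n_k[k]:<8d} {self.f_k[k]: .4f}    {self.d_delta_f(0, k):.4f}"
            )
        if self.low_overlap_pairs:
            lines.append(f"  low-overlap window pairs: {self.low_overlap_pairs}")
        return "\n".join(lines)


class MBAR:
    """Multistate Bennett acceptance ratio model.

    Parameters
    ----------
    u_kn
        Reduced potentials, shape ``(K, N)``: ``u_kn[k, n]`` is the reduced
        energy of sample *n* evaluated in state *k*.  All samples must be
        evaluated at all states.
    n_k
        Number of samples drawn from each state; ``sum(n_k) == N`` and every
        entry must be >= 1.
    """

    def __init__(self, u_kn, n_k):
        self.u_kn = np.asarray(u_kn, dtype=float)
        self.n_k = np.asarray(n_k, dtype=int)
        if self.u_kn.ndim != 2:
            raise ValueError("u_kn must be a 2-D (K, N) matrix")
        K, N = self.u_kn.shape
        if len(self.n_k) != K:
            raise ValueError(f"n_k has {len(self.n_k)} entries for {K} states")
        if self.n_k.sum() != N:
            raise ValueError(f"sum(n_k)={self.n_k.sum()} does not match N={N}")
        if np.any(self.n_k < 1):
            empty = np.nonzero(self.n_k < 1)[0]
            raise ValueError(f"every state needs at least one sample; empty: {list(empty)}")
        if not np.all(np.isfinite(self.u_kn)):
            raise ValueError("u_kn contains non-finite entries")

    # -- initial guess ------------------------------------------------------

    def _chained_bar_guess(self) -> np.ndarray:
        """Initial f_k from BAR on each adjacent pair of states."""
        K = len(self.n_k)
        starts = np.concatenate([[0], np.cumsum(self.n_k)])
        f = np.zeros(K)
        for k in range(K - 1):
            sl_k = slice(starts[k], starts[k + 1])
            sl_k1 = slice(starts[k + 1], starts[k + 2])
            w_f = self.u_kn[k + 1, sl_k] - self.u_kn[k, sl_k]
            w_r = self.u_kn[k, sl_k1] - self.u_kn[k + 1, sl_k1]
            try:
                df = bar_solve(w_f, w_r, tol=1e-8)
            except (ConvergenceError, ValueError):
                # exponential averaging fallback
                df = -(logsumexp(-w_f) - math.log(len(w_f)))
            f[k + 1] = f[k] + df
        return f

    # -- solver -------------------------------------------------------------

    def _log_denominator(self, f_k: np.ndarray) -> np.ndarray:
        """log sum_k N_k exp(f_k - u_kn), shape (N,)."""
        a = (np.log(self.n_k) + f_k)[:, None] - self.u_kn
        m = a.max(axis=0)
        return m + np.log(np.exp(a - m[None, :]).sum(axis=0))

    def _weights(self, f_k: np.ndarray) -> np.ndarray:
        """W_nk = exp(f_k - u_kn) / sum_l N_l exp(f_l - u_ln), shape (N, K)."""
        log_denom = self._log_denominator(f_k)
        return np.exp(f_k[:, None] - self.u_kn - log_denom[None, :]).T

    def fit(self, tol: float = 1e-8, max_iter: int = 10_000) -> MBARResults:
        """Solve the MBAR equations.

        A short self-consistent warm-up from the chained-BAR guess is
        followed by Newton-Raphson steps on the convex MBAR objective (the
        self-consistent update is the fallback whenever the Newton system is
        singular).  Convergence is declared when the largest relative change
        in any ``f_k`` falls below *tol*.  Raises :class:`ConvergenceError`
        with the final residual if *max_iter* is exceeded.
        """
        f = self._chained_bar_guess()
        log_nk = np.log(self.n_k)
        residual = float("inf")
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            # one exponential pass per iteration: E_kn = exp(log N_k + f_k - u_kn - m_n)
            a = (log_nk + f)[:, None] - self.u_kn
            m = a.max(axis=0)
            E = np.exp(a - m[None, :])
            denom = E.sum(axis=0)  # exp(log_denominator - m)
            if n_iter <= 1:
                # self-consistent update: f_i = -log sum_n exp(-u_in - log_denom)
                # with exp(-u_in - log_denom) = (E_in / N_i) * exp(-f_i) / denom
                s = (E / denom[None, :]).sum(axis=1) / self.n_k
                f_new = f - np.log(s)
                f_new = f_new - f_new[0]
            else:
                # Newton-Raphson on the convex MBAR objective, holding f_0
                G = E / denom[None, :]  # (K, N); W = G.T / N_k
                col = G.sum(axis=1) / self.n_k  # column sums of W
                grad = self.n_k * (col - 1.0)
                H = -(G @ G.T)
                H[np.diag_indices_from(H)] += self.n_k * col
                f_new = f - np.log(col)
                f_new = f_new - f_new[0]  # self-consistent fallback
                try:
                    step = np.linalg.solve(H[1:, 1:], grad[1:])
                    cand = f.copy()
                    cand[1:] -= step
                    if np.all(np.isfinite(cand)):
                        f_new = cand - cand[0]
                except np.linalg.LinAlgError:
                    pass
            residual = float(np.max(np.abs(f_new - f) / (1.0 + np.abs(f_new))))
            f = f_new
            if residual < tol:
                break
        else:
            raise ConvergenceError(
                f"MBAR did not converge after {max_iter} iterations "
                f"(residual {residual:.3e} > tol {tol:.1e})",
                residual,
            )

        W = self._weights(f)
        theta = self._asymptotic_covariance(W)
        overlap = self._overlap_matrix(W)
        low = [
            (k, k + 1)
            for k in range(len(f) - 1)
            if min(overlap[k, k + 1], overlap[k + 1, k]) < 1e-3
        ]
        if low:
            logger.warning("window pairs with near-zero phase-space overlap: %s", low)
        return MBARResults(
            f_k=f,
            theta=theta,
            n_k=self.n_k.copy(),
            n_iterations=n_iter,
            final_residual=residual,
            overlap_matrix=overlap,
            low_overlap_pairs=low,
        )

    def _asymptotic_covariance(self, W: np.ndarray) -> np.ndarray:
        """Standard MBAR asymptotic covariance of the f_k estimates.

        In SVD form, with W = U S V^T (economy),
        Theta = V S (I - S V^T diag(N) V S)^+ S V^T; S and V are obtained
        from the K x K Gram matrix W^T W = V S^2 V^T, avoiding a tall SVD.
        """
        gram = W.T @ W
        vals, V = np.linalg.eigh(gram)
        S = np.sqrt(np.clip(vals, 0.0, None))
        Vt = V.T
        inner = np.eye(len(S)) - (S[:, None] * Vt) @ (self.n_k[:, None] * V) * S[None, :]
        inner_pinv = np.linalg.pinv(inner, rcond=1e-12)
        return (V * S[None, :]) @ inner_pinv @ (S[:, None] * Vt)

    def _overlap_matrix(self, W: np.ndarray) -> np.ndarray:
        """O_ij = N_j sum_n W_ni W_nj; row sums are 1."""
        return (W.T @ W) * self.n_k[None, :]


def mbar_solve(u_kn, n_k, tol: float = 1e-8, max_iter: int = 10_000) -> MBARResults:
    """Functional wrapper: ``MBAR(u_kn, n_k).fit(tol, max_iter)``."""
    return MBAR(u_kn, n_k).fit(tol=tol, max_iter=max_iter)


# ---------------------------------------------------------------------------
# Per-stage free energies from a leg
# ---------------------------------------------------------------------------


@dataclass
class StageFreeEnergy:
    """Free-energy change of one alchemical stage in the decoupling
    (or restraint-ON) direction, kcal/mol."""

    stage_name: str
    delta_g: float
    uncertainty: float
    n_effective: np.ndarray
    method: str = "mbar"

    def __post_init__(self):
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be non-negative")
        if np.any(np.asarray(self.n_effective) < 1):
            raise ValueError("every window needs at least one effective sample")


def _stage_u_kn(windows: list[WindowSamples]):
    """Stack per-window reduced potentials into the (K, N) MBAR input."""
    n_k = np.array([w.n_frames for w in windows], dtype=int)
    u_kn = np.concatenate([w.u_foreign() for w in windows], axis=0).T
    return u_kn, n_k


def leg_free_energy(
    leg: LegEnsemble, tol: float = 1e-8, max_iter: int = 10_000
) -> list[StageFreeEnergy]:
    """Per-stage free energies of a (truncated, decorrelated) leg via MBAR.

    Each stage is an independent alchemical path with its own window set and
    is solved as a separate MBAR problem; Delta G is reported in kcal/mol in
    the lambda 0 -> 1 direction (decoupling; restraint-ON for the restraint
    stage).  Uncertainties are the MBAR asymptotic standard errors.
    """
    kt = kt_kcal(leg.temperature)
    out = []
    for stage_name, _ in leg.schedule.stages:
        windows = leg.stage_windows(stage_name)
        u_kn, n_k = _stage_u_kn(windows)
        res = mbar_solve(u_kn, n_k, tol=tol, max_iter=max_iter)
        out.append(
            StageFreeEnergy(
                stage_name=stage_name,
                delta_g=res.delta_f() * kt,
                uncertainty=res.d_delta_f() * kt,
                n_effective=n_k,
                method="mbar",
            )
        )
    return out


def ti_integrate(leg: LegEnsemble) -> list[StageFreeEnergy]:
    """Per-stage free energies via trapezoidal thermodynamic integration.

    Integrates the mean total dH/dlambda of each window over the stage's
    lambda values.  A secondary estimator used as a cross-check on MBAR;
    results are flagged with ``method="ti"``.  Raises ``ValueError`` when a
    window lacks dH/dlambda data or a stage has a single window.
    """
    out = []
    for stage_name, lams in leg.schedule.stages:
        windows = leg.stage_windows(stage_name)
        if len(windows) < 2:
            raise ValueError(f"stage {stage_name!r} has fewer than 2 windows; cannot integrate")
        means = []
        for w in windows:
            if w.dhdl is None or w.dhdl.size == 0:
                raise ValueError(
                    f"window {w.window_index} of stage {stage_name!r} has no dH/dlambda data"
                )
            means.append(w.dhdl.sum(axis=1).mean())
        delta_g = float(np.trapezoid(means, lams))
        # crude uncertainty: standard errors of the window means, trapezoid-weighted
        sems = np.array(
            [w.dhdl.sum(axis=1).std(ddof=1) / math.sqrt(w.n_frames) for w in windows]
        )
        lam_arr = np.asarray(lams)
        weights = np.zeros(len(lams))
        weights[0] = (lam_arr[1] - lam_arr[0]) / 2
        weights[-1] = (lam_arr[-1] - lam_arr[-2]) / 2
        weights[1:-1] = (lam_arr[2:] - lam_arr[:-2]) / 2
        unc = float(np.sqrt(np.sum((weights * sems) ** 2)))
        out.append(
            StageFreeEnergy(
                stage_name=stage_name,
                delta_g=delta_g,
                uncertainty=unc,
                n_effective=np.array([w.n_frames for w in windows]),
                method="ti",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Cycle assembly and replica aggregation
# ---------------------------------------------------------------------------


@dataclass
class CycleResult:
    """Binding free energy assembled from the two legs of the cycle.

    ``delta_g_bind`` is the standard-state binding free energy in kcal/mol
    (more negative = stronger binding); ``components`` records every term of
    the combination.
    """

    ligand_id: str
    replica_id: str
    delta_g_bind: float
    uncertainty: float
    components: dict

    def summary(self) -> str:
        lines = [
            f"Binding free energy: ligand {self.ligand_id}, replica {self.replica_id}",
            f"  DG_bind = {self.delta_g_bind: .3f} +/- {self.uncertainty:.3f} kcal/mol",
        ]
        for key, value in self.components.items():
            lines.append(f"  {key:28s} {value: .3f}")
        return "\n".join(lines)


def assemble_cycle(
    solvent_stages: list[StageFreeEnergy],
    complex_stages: list[StageFreeEnergy],
    restraint_on_analytic: float,
    charge_correction: float = 0.0,
    ligand_id: str = "",
    replica_id: str = "",
    net_charge: int = 0,
) -> CycleResult:
    """Assemble the standard-state binding free energy from cycle components.

    DG_bind = [DG_solv,coul + DG_solv,vdw] + DG_restraint_on_analytic
              - [DG_complex,restraint + DG_complex,coul + DG_complex,vdw]
              + charge_correction

    All simulated stage values are in the decoupling / restraint-ON
    direction; *restraint_on_analytic* is the closed-form free energy of
    imposing the orientational restraint on the non-interacting ligand at
    standard concentration.  The uncertainty is the quadrature sum of stage
    uncertainties.  A net-charged ligand with zero *charge_correction*
    triggers a warning (finite-size corrections are supplied externally).
    """
    solv = {s.stage_name: s for s in solvent_stages}
    comp = {s.stage_name: s for s in complex_stages}
    missing = [f"solvent:{n}" for n in ("coul", "vdw") if n not in solv]
    missing += [f"complex:{n}" for n in ("restraint", "coul", "vdw") if n not in comp]
    if missing:
        raise ValueError(f"missing cycle stages: {', '.join(missing)}")
    if net_charge != 0 and charge_correction == 0.0:
        logger.warning(
            "ligand %s has net charge %+d but no finite-size charge correction",
            ligand_id or "<unnamed>",
            net_charge,
        )
    dg = (
        solv["coul"].delta_g
        + solv["vdw"].delta_g
        + restraint_on_analytic
        - (comp["restraint"].delta_g + comp["coul"].delta_g + comp["vdw"].delta_g)
        + charge_correction
    )
    unc = math.sqrt(
        sum(s.uncertainty**2 for s in (solv["coul"], solv["vdw"]))
        + sum(s.uncertainty**2 for s in (comp["restraint"], comp["coul"], comp["vdw"]))
    )
    components = {
        "solvent_coul": solv["coul"].delta_g,
        "solvent_vdw": solv["vdw"].delta_g,
        "restraint_on_analytic": restraint_on_analytic,
        "complex_restraint": comp["restraint"].delta_g,
        "complex_coul": comp["coul"].delta_g,
        "complex_vdw": comp["vdw"].delta_g,
        "charge_correction": charge_correction,
    }
    return CycleResult(
        ligand_id=ligand_id,
        replica_id=replica_id,
        delta_g_bind=dg,
        uncertainty=unc,
        components=components,
    )


@dataclass
class AggregatedEstimate:
    """Replica-mean binding free energy with the replica standard deviation
    (the reported sampling error)."""

    ligand_id: str
    mean: float
    replica_std: float | None
    n_replicas: int


def aggregate_replicas(results: list[CycleResult]) -> AggregatedEstimate:
    """Mean and sample standard deviation (ddof=1) over independent replicas.

    All results must share a ligand id.  With a single replica the standard
    deviation is undefined and reported as ``None`` with a warning.
    """
    if not results:
        raise ValueError("no replica results to aggregate")
    ids = {r.ligand_id for r in results}
    if len(ids) > 1:
        raise ValueError(f"cannot aggregate mixed ligand ids: {sorted(ids)}")
    values = np.array([r.delta_g_bind for r in results])
    if len(values) == 1:
        logger.warning("single replica for %s; replica std undefined", results[0].ligand_id)
        std = None
    else:
        std = float(values.std(ddof=1))
    return AggregatedEstimate(
        ligand_id=results[0].ligand_id,
        mean=float(values.mean()),
        replica_std=std,
        n_replicas=len(values),
    )
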