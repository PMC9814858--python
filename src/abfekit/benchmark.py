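"""Benchmark statistics: calculated vs experimental binding free energies.

Experimental affinities (Kd/Ki/IC50) are converted to free energies with
DG = RT ln(K / c0) at c0 = 1 M; IC50 values are treated as Ki-equivalent
since assay-specific conversions are rarely available across heterogeneous
datasets.  Censored affinities (reported only as a bound, e.g. Ki > 1 mM)
are carried with their bound direction and can be excluded from, or included
at their bound value in, the benchmark metrics.

The scoring model is :class:`AffinityBenchmark`: built from ligand records
(or a DataFrame), ``fit()`` computes Pearson r, Spearman r, Kendall tau-b
and RMSE between replica-mean calculated and experimental free energies,
with uncertainties from paired bootstrap resampling over ligands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._constants import DEFAULT_TEMPERATURE, KB_KCAL
from .io import AffinityRecord

logger = logging.getLogger(__name__)

METRIC_NAMES = ("pearson_r", "spearman_r", "kendall_tau", "rmse")


def affinity_to_dG(record: AffinityRecord, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Experimental binding free energy DG = RT ln(K/c0) in kcal/mol, c0 = 1 M.

    For a censored record the returned value is the free energy at the bound
    (an upper-affinity bound ``Ki > x`` maps to ``DG >= RT ln x``); the
    censoring itself stays on the record.
    """
    return KB_KCAL * temperature * np.log(record.value)


@dataclass
class LigandRecord:
    """One ligand's calculated and experimental binding free energies.

    ``dg_calc`` is the replica-mean estimate with ``replica_std`` its
    standard deviation over independent repeats (kcal/mol).  ``dg_exp`` is
    the experimental value, or the bound value when ``censored``.
    """

    ligand_id: str
    dg_calc: float
    replica_std: float | None
    dg_exp: float
    censored: bool = False
    bound_direction: str = "none"
    system_id: str = ""

    def __post_init__(self):
        if self.replica_std is not None and self.replica_std < 0:
            raise ValueError("replica_std must be non-negative")
        if self.censored and self.bound_direction not in ("upper", "lower"):
            raise ValueError("censored records need a bound direction")


def records_from_tables(
    aggregated: dict[str, tuple[float, float | None]],
    affinities: list[AffinityRecord],
    temperature: float = DEFAULT_TEMPERATURE,
) -> list[LigandRecord]:
    """Join aggregated calculated estimates with an affinity table.

    *aggregated* maps ligand_id -> (mean DG_calc, replica_std).  Ligands
    missing from either side are skipped with a warning.
    """
    out = []
    for rec in affinities:
        if rec.ligand_id not in aggregated:
            logger.warning("no calculated estimate for ligand %s; skipped", rec.ligand_id)
            continue
        mean, std = aggregated[rec.ligand_id]
        out.append(
            LigandRecord(
                ligand_id=rec.ligand_id,
                dg_calc=mean,
                replica_std=std,
                dg_exp=affinity_to_dG(rec, temperature),
                censored=rec.censored,
                bound_direction=rec.bound_direction,
                system_id=rec.system_id,
            )
        )
    return out


@dataclass
class MetricReport:
    """Benchmark metrics with optional bootstrap standard deviations."""

    pearson_r: float
    spearman_r: float
    kendall_tau: float
    rmse: float
    n_ligands: int
    censored_excluded: bool
    bootstrap_std: dict[str, float] | None = None
    n_degenerate_resamples: int = 0

    def __post_init__(self):
        for name in ("pearson_r", "spearman_r", "kendall_tau"):
            v = getattr(self, name)
            if np.isfinite(v) and not -1.0 - 1e-12 <= v <= 1.0 + 1e-12:
                raise ValueError(f"{name}={v} outside [-1, 1]")
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")

    def to_dict(self) -> dict:
        out = {
            "pearson_r": self.pearson_r,
            "spearman_r": self.spearman_r,
            "kendall_tau": self.kendall_tau,
            "rmse": self.rmse,
            "n_ligands": self.n_ligands,
            "censored_excluded": self.censored_excluded,
        }
        if self.bootstrap_std is not None:
            out.update({f"{k}_std": v for k, v in self.bootstrap_std.items()})
        return out

    def summary(self) -> str:
        def fmt(name, value):
            if self.bootstrap_std and name in self.bootstrap_std:
                return f"{value: .3f} +/- {self.bootstrap_std[name]:.3f}"
            return f"{value: .3f}"

        return "\n".join(
            [
                f"Benchmark over {self.n_ligands} ligands"
                + (" (censored excluded)" if self.censored_excluded else ""),
                f"  Pearson r    : {fmt('pearson_r', self.pearson_r)}",
                f"  Spearman r   : {fmt('spearman_r', self.spearman_r)}",
                f"  Kendall tau-b: {fmt('kendall_tau', self.kendall_tau)}",
                f"  RMSE (kcal/mol): {fmt('rmse', self.rmse)}",
            ]
        )


def _metrics_arrays(calc: np.ndarray, exp: np.ndarray) -> dict[str, float]:
    if np.std(calc) == 0 or np.std(exp) == 0:
        pearson = spearman = tau = float("nan")
    else:
        pearson = float(stats.pearsonr(calc, exp).statistic)
        spearman = float(stats.spearmanr(calc, exp).statistic)
        tau = float(stats.kendalltau(calc, exp, variant="b").statistic)
    rmse = float(np.sqrt(np.mean((calc - exp) ** 2)))
    return {"pearson_r": pearson, "spearman_r": spearman, "kendall_tau": tau, "rmse": rmse}


def _usable(records: list[LigandRecord], exclude_censored: bool) -> list[LigandRecord]:
    return [r for r in records if not (exclude_censored and r.censored)]


def compute_metrics(records: list[LigandRecord], exclude_censored: bool = False) -> MetricReport:
    """Pearson, Spearman, tie-corrected Kendall tau-b and RMSE.

    Censored records are either excluded or included at their bound value.
    RMSE uses the replica-mean calculated values only.  Requires at least 3
    usable records.
    """
    usable = _usable(records, exclude_censored)
    if len(usable) < 3:
        raise ValueError(f"need at least 3 usable records, got {len(usable)}")
    calc = np.array([r.dg_calc for r in usable])
    exp = np.array([r.dg_exp for r in usable])
    m = _metrics_arrays(calc, exp)
    return MetricReport(
        **m, n_ligands=len(usable), censored_excluded=exclude_censored
    )


def bootstrap_errors(
    records: list[LigandRecord],
    n_boot: int = 100_000,
    seed: int | np.random.Generator = 0,
    exclude_censored: bool = False,
) -> tuple[dict[str, float], int]:
    """Bootstrap standard deviations of the benchmark metrics.

    Ligands are resampled in pairs with replacement *n_boot* times
    (>= 100 required); each metric's uncertainty is the standard deviation
    of its resampled distribution.  Resamples with zero variance in either
    variable leave the correlation metrics undefined and are skipped for
    those metrics; their count is returned alongside the stds.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    usable = _usable(records, exclude_censored)
    if len(usable) < 3:
        raise ValueError(f"need at least 3 usable records, got {len(usable)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    calc = np.array([r.dg_calc for r in usable])
    exp = np.array([r.dg_exp for r in usable])
    n = len(usable)
    idx = rng.integers(0, n, size=(n_boot, n))
    c = calc[idx]
    e = exp[idx]

    # vectorised Pearson and RMSE
    cc = c - c.mean(axis=1, keepdims=True)
    ee = e - e.mean(axis=1, keepdims=True)
    sc = np.sqrt((cc**2).sum(axis=1))
    se = np.sqrt((ee**2).sum(axis=1))
    ok = (sc > 0) & (se > 0)
    n_degenerate = int((~ok).sum())
    pearson = (cc * ee).sum(axis=1)[ok] / (sc[ok] * se[ok])
    rmse = np.sqrt(((c - e) ** 2).mean(axis=1))

    # Spearman: Pearson on mid-ranks (vectorised rankdata)
    rc = stats.rankdata(c, axis=1)
    re = stats.rankdata(e, axis=1)
    rcc = rc - rc.mean(axis=1, keepdims=True)
    ree = re - re.mean(axis=1, keepdims=True)
    src = np.sqrt((rcc**2).sum(axis=1))
    sre = np.sqrt((ree**2).sum(axis=1))
    ok_s = (src > 0) & (sre > 0)
    spearman = (rcc * ree).sum(axis=1)[ok_s] / (src[ok_s] * sre[ok_s])

    # Kendall tau-b per resample (no stable vectorised form; loop in C calls)
    taus = np.empty(n_boot)
    taus.fill(np.nan)
    for i in range(n_boot):
        if ok[i]:
            taus[i] = stats.kendalltau(c[i], e[i], variant="b").statistic
    taus = taus[np.isfinite(taus)]

    stds = {
        "pearson_r": float(np.std(pearson)) if pearson.size else float("nan"),
        "spearman_r": float(np.std(spearman)) if spearman.size else float("nan"),
        "kendall_tau": float(np.std(taus)) if taus.size else float("nan"),
        "rmse": float(np.std(rmse)),
    }
    return stds, n_degenerate


class AffinityBenchmark:
    """Model object scoring calculated against experimental free energies.

    Parameters
    ----------
    records
        Ligand records with calculated and experimental values.
    temperature
        Used only when building from an affinity table.
    """

    def __init__(self, records: list[LigandRecord]):
        self.records = list(records)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "AffinityBenchmark":
        """Build from a DataFrame with columns ligand_id, dg_calc,
        replica_std, dg_exp and optional censored, bound_direction,
        system_id."""
        records = []
        for row in frame.itertuples(index=False):
            records.append(
                LigandRecord(
                    ligand_id=str(row.ligand_id),
                    dg_calc=float(row.dg_calc),
                    replica_std=None
                    if pd.isna(getattr(row, "replica_std", np.nan))
                    else float(row.replica_std),
                    dg_exp=float(row.dg_exp),
                    censored=bool(getattr(row, "censored", False)),
                    bound_direction=str(getattr(row, "bound_direction", "none")),
                    system_id=str(getattr(row, "system_id", "")),
                )
            )
        return cls(records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "ligand_id": r.ligand_id,
                    "dg_calc": r.dg_calc,
                    "replica_std": r.replica_std,
                    "dg_exp": r.dg_exp,
                    "censored": r.censored,
                    "bound_direction": r.bound_direction,
                    "system_id": r.system_id,
                }
                for r in self.records
            ]
        )

    def fit(
        self,
        exclude_censored: bool = False,
        n_boot: int = 100_000,
        seed: int | np.random.Generator = 0,
    ) -> MetricReport:
        """Compute the metric report with bootstrap uncertainties."""
        report = compute_metrics(self.records, exclude_censored=exclude_censored)
        stds, n_degenerate = bootstrap_errors(
            self.records, n_boot=n_boot, seed=seed, exclude_censored=exclude_censored
        )
        report.bootstrap_std = stds
        report.n_degenerate_resamples = n_degenerate
        return report


def plot_benchmark(records: list[LigandRecord], path, temperature_label: str = "kcal/mol"):
    """Scatter plot of calculated vs experimental free energies with replica
    error bars and the x=y diagonal; saved to *path*."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    systems = sorted({r.system_id for r in records})
    for system in systems:
        rs = [r for r in records if r.system_id == system]
        ax.errorbar(
            [r.dg_exp for r in rs],
            [r.dg_calc for r in rs],
            yerr=[r.replica_std or 0.0 for r in rs],
            fmt="o",
            ms=4,
            capsize=2,
            label=system or None,
        )
    lims = ax.get_xlim() + ax.get_ylim()
    lo, hi = min(lims), max(lims)
    ax.plot([lo, hi], [lo, hi], "k--", lw=0.8)
    ax.fill_between([lo, hi], [lo - 1, hi - 1], [lo + 1, hi + 1], color="grey", alpha=0.2)
    ax.set_xlabel(f"experimental DG ({temperature_label})")
    ax.set_ylabel(f"calculated DG ({temperature_label})")
    if any(systems):
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
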