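"""In-silico validation study: pathology × permeability × SNR grid.

For each liver condition (normal, CRN, HCC) a set of synthetic substrates is
generated, diffusion signals are FD-simulated once per (substrate,
permeability), Rician noise is injected at each SNR for several replicates,
and the tissue model is fitted at ROI level (signals averaged over the
field, as one value per image).  The long-format result table supports
group statistics (one-way ANOVA with Bonferroni-corrected pairwise tests)
and estimate-vs-truth correlations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .acquisition import ex_vivo_protocols
from .fd_engine import FDConfig, add_rician_noise, simulate_signalset
from .fitting import SignalModel, fit_voxel
from .substrate import (
    DEFAULT_PROFILES,
    generate_substrate,
    ground_truth_metrics,
)

__all__ = [
    "StudyConfig",
    "run_study",
    "compare_groups",
    "correlate",
    "report",
]


@dataclass
class StudyConfig:
    """Factorial design of the simulation study.

    Defaults reproduce the full design: 3 pathologies × 6 substrates ×
    permeabilities 0–0.05 µm/ms in steps of 0.01 × SNR ∈ {10, 20, 50}.
    ``reduced()`` gives a desk-scale variant.
    """

    pathologies: tuple = tuple(DEFAULT_PROFILES.values())
    n_substrates_per_pathology: int = 6
    kappa_grid: tuple = (0.0, 0.01, 0.02, 0.03, 0.04, 0.05)
    snr_grid: tuple = (10.0, 20.0, 50.0)
    n_noise_reps: int = 3
    master_seed: int = 0
    substrate_size_px: int = 1000
    resolution: float = 0.5
    D_in: float = 1.53
    D_ex: float = 2.0
    protocols: tuple = ()
    n_fit_starts: int = 20
    perfusion_removal: bool = False

    def __post_init__(self):
        if not self.protocols:
            self.protocols = tuple(ex_vivo_protocols())
        if not (self.pathologies and self.kappa_grid and self.snr_grid):
            raise ValueError("pathology, kappa and SNR grids must be non-empty")
        paths = []
        for p in self.pathologies:
            paths.append(DEFAULT_PROFILES[p] if isinstance(p, str) else p)
        self.pathologies = tuple(paths)

    @classmethod
    def reduced(cls, master_seed: int = 0, **overrides) -> "StudyConfig":
        """Desk-scale study: 500×500 px substrates, κ ∈ {0, 0.02}, SNR ∈ {20, 50}."""
        kwargs = dict(
            n_substrates_per_pathology=3,
            kappa_grid=(0.0, 0.02),
            snr_grid=(20.0, 50.0),
            n_noise_reps=3,
            substrate_size_px=500,
            master_seed=master_seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


def _child_seed(master: int, *idx) -> int:
    ss = np.random.SeedSequence([int(master), *[int(i) for i in idx]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_study(config: StudyConfig, progress: bool = False) -> pd.DataFrame:
    """Run the full grid and return the long-format study table.

    One row per (pathology, substrate, kappa, SNR, replicate) with fitted
    and ground-truth quantities.  Substrates differ across substrate ids
    but are shared across kappa (only the membrane property changes);
    noiseless signal sets are simulated once per (substrate, kappa).
    Deterministic for a fixed ``master_seed``.  Per-row failures are
    recorded with ``ok = False`` rather than aborting the grid.
    """
    protocols = list(config.protocols)
    model = SignalModel(protocols)
    fd_cfg = FDConfig()
    rows = []
    for i_path, profile in enumerate(config.pathologies):
        for i_sub in range(config.n_substrates_per_pathology):
            sub_seed = _child_seed(config.master_seed, 0, i_path, i_sub)
            sub = generate_substrate(
                profile, size_px=config.substrate_size_px,
                resolution=config.resolution, seed=sub_seed,
                D_in=config.D_in, D_ex=config.D_ex,
            )
            truth = ground_truth_metrics(sub)
            for i_k, kappa in enumerate(config.kappa_grid):
                sub_k = sub.with_properties(kappa=float(kappa))
                if progress:
                    print(f"[study] {profile.name} substrate {i_sub} "
                          f"kappa={kappa:g}", flush=True)
                clean = simulate_signalset(sub_k, protocols, fd_cfg)
                for i_snr, snr in enumerate(config.snr_grid):
                    for rep in range(config.n_noise_reps):
                        noise_seed = _child_seed(
                            config.master_seed, 1, i_path, i_sub, i_k,
                            i_snr, rep,
                        )
                        noisy = add_rician_noise(clean, snr, noise_seed)
                        row = {
                            "pathology": profile.name,
                            "substrate_id": i_sub,
                            "kappa": float(kappa),
                            "snr": float(snr),
                            "replicate": rep,
                            "truth_d_number": truth.mean_diameter_number,
                            "truth_d_volume": truth.mean_diameter_volume_weighted,
                            "truth_cellularity": truth.cellularity,
                            "truth_area_fraction": truth.area_fraction,
                            "ok": True,
                        }
                        try:
                            fit_seed = _child_seed(
                                config.master_seed, 2, i_path, i_sub, i_k,
                                i_snr, rep,
                            )
                            res = fit_voxel(
                                noisy, protocols,
                                n_starts=config.n_fit_starts,
                                seed=fit_seed, model=model,
                                perfusion_removal=config.perfusion_removal,
                            )
                            row.update(
                                fitted_d=res.params.d,
                                fitted_vin=res.params.vin,
                                fitted_Din=res.params.Din,
                                fitted_Dex=res.params.Dex,
                                fitted_tau_in=res.params.tau_in,
                                fitted_cellularity=res.cellularity,
                                residual=res.residual,
                            )
                        except Exception as err:  # record, keep going
                            row.update(ok=False, error=str(err))
                        rows.append(row)
    return pd.DataFrame(rows)


def compare_groups(
    table: pd.DataFrame,
    metric: str = "fitted_d",
    kappa: float | None = None,
    snr: float | None = None,
    group_col: str = "pathology",
) -> dict:
    """One-way ANOVA across pathologies plus Bonferroni pairwise tests.

    Restricts to one (kappa, SNR) stratum when given.  Pairwise comparisons
    are Welch two-sample t-tests with p-values multiplied by the number of
    pairs (capped at 1).
    """
    df = table[table.get("ok", True) == True]  # noqa: E712
    if kappa is not None:
        df = df[np.isclose(df["kappa"], kappa)]
    if snr is not None:
        df = df[np.isclose(df["snr"], snr)]
    groups = {name: g[metric].dropna().values for name, g in df.groupby(group_col)}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    names = sorted(groups)
    values = [groups[n] for n in names]
    if np.ptp(np.concatenate(values)) == 0:
        f_stat, p = 0.0, 1.0  # identical groups: no variance anywhere
    else:
        f_stat, p = stats.f_oneway(*values)
        if not np.isfinite(f_stat):
            f_stat, p = 0.0, 1.0
    pairs = list(itertools.combinations(names, 2))
    pairwise = {}
    for a, b in pairs:
        if np.ptp(np.concatenate([groups[a], groups[b]])) == 0:
            praw = 1.0
        else:
            praw = stats.ttest_ind(groups[a], groups[b], equal_var=False).pvalue
        pairwise[(a, b)] = {
            "p_raw": float(praw),
            "p_adjusted": float(min(1.0, len(pairs) * praw)),
        }
    return {"F": float(f_stat), "p": float(p), "pairwise": pairwise,
            "n": {k: len(v) for k, v in groups.items()}}


def correlate(estimates, truths) -> dict:
    """Pearson and Spearman correlation between estimates and ground truth."""
    x = np.asarray(estimates, float)
    y = np.asarray(truths, float)
    m = np.isfinite(x) & np.isfinite(y)
    x, y = x[m], y[m]
    if len(x) < 3:
        raise ValueError("need >= 3 paired finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    return {
        "pearson": float(stats.pearsonr(x, y).statistic),
        "spearman": float(stats.spearmanr(x, y).statistic),
    }


def report(table: pd.DataFrame, outdir=None, make_plots: bool = True):
    """Per-(pathology, kappa, SNR) summary of fitted d and cellularity.

    Returns a DataFrame of mean ± SEM per stratum; optionally writes it as
    CSV together with simple summary plots.
    """
    df = table[table.get("ok", True) == True]  # noqa: E712
    if df.empty:
        raise ValueError("empty study table")
    agg = df.groupby(["pathology", "kappa", "snr"]).agg(
        n=("fitted_d", "count"),
        fitted_d_mean=("fitted_d", "mean"),
        fitted_d_sem=("fitted_d", "sem"),
        fitted_cellularity_mean=("fitted_cellularity", "mean"),
        fitted_cellularity_sem=("fitted_cellularity", "sem"),
        truth_d_volume=("truth_d_volume", "mean"),
        truth_cellularity=("truth_cellularity", "mean"),
    ).reset_index()
    if outdir is not None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        agg.to_csv(outdir / "study_summary.csv", index=False)
        table.to_csv(outdir / "study_table.csv", index=False)
        if make_plots:
            _summary_plots(agg, outdir)
    return agg


def _summary_plots(agg: pd.DataFrame, outdir) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for metric, ylabel, stem in [
        ("fitted_d", "fitted cell size d (µm)", "cell_size"),
        ("fitted_cellularity", "fitted cellularity (1/mm²)", "cellularity"),
    ]:
        fig, axes = plt.subplots(
            1, len(agg["snr"].unique()), figsize=(4 * agg["snr"].nunique(), 3.2),
            sharey=True, squeeze=False,
        )
        for ax, (snr, g) in zip(axes[0], agg.groupby("snr")):
            for name, gg in g.groupby("pathology"):
                ax.errorbar(gg["kappa"], gg[f"{metric}_mean"],
                            yerr=gg[f"{metric}_sem"], marker="o", label=name)
            ax.set_title(f"SNR {snr:g}")
            ax.set_xlabel("membrane permeability κ (µm/ms)")
        axes[0, 0].set_ylabel(ylabel)
        axes[0, 0].legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(outdir / f"summary_{stem}.png", dpi=150)
        plt.close(fig)
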