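"""Theory-vs-simulation harness.

Each comparison cell names a metric family, a data model and the dimensions
(m, p, replicates); the harness generates that many seeded null datasets,
computes the pairwise distances, and tabulates simulated mean/SD (with
Monte-Carlo standard errors over replicates) next to the analytic
predictions.  A normality report (Shapiro-Wilk, QQ pairs, skewness) covers
the Gaussian-convergence checks, and ``run_figure_suite`` drives the standard
experiments end to end, writing TSV tables and plots.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._types import DistanceMatrix, MomentSummary
from .continuous_moments import lq_distance_moments
from .distances import fmri_distance_matrix, gwas_distance_matrix, lq_distance_matrix
from .extreme_values import maxmin_lq_moments
from .fmri_moments import fmri_distance_moments, fmri_maxmin_moments
from .gwas_moments import expected_gammas, gwas_distance_moments
from .synthetic_data import (
    gen_continuous,
    gen_fmri_stack,
    gen_gwas,
    impose_correlation,
    mean_abs_correlation,
    random_structured_correlation,
)

__all__ = ["ComparisonRow", "moment_comparison", "normality_report", "run_figure_suite"]

#: Shapiro-Wilk caps its sample size; larger distance collections are
#: subsampled to this many values with a fixed seed.
_SHAPIRO_CAP = 5000


@dataclass
class ComparisonRow:
    """One cell of a theory-vs-simulation moment comparison."""

    family: str
    data_model: str
    q: Optional[int]
    p: int
    m: int
    replicates: int
    seed: Optional[int]
    theory_mean: float
    theory_sd: float
    sim_mean: float
    sim_sd: float
    sim_mean_se: float
    sim_sd_se: float
    extra: dict = field(default_factory=dict)


def _theory_for_cell(cell: dict) -> MomentSummary:
    family = cell["family"]
    p, m = int(cell["p"]), int(cell["m"])
    if family == "lq":
        return lq_distance_moments(p, int(cell.get("q", 1)), cell["data_model"])
    if family == "lq_maxmin":
        return maxmin_lq_moments(p, int(cell.get("q", 1)), m, cell["data_model"])
    if family in ("gm", "am", "titv"):
        maf = np.asarray(cell["maf"], dtype=float)
        enc = cell.get("enc")
        if enc is None and family == "titv":
            enc = expected_gammas(float(cell.get("eta", 2.0)))
        return gwas_distance_moments(family, maf, enc)
    if family == "fmri":
        return fmri_distance_moments(p, corrected=cell.get("corrected", True))
    if family == "fmri_maxmin":
        return fmri_maxmin_moments(m, p)
    raise ValueError(f"unknown family: {family!r}")


def _simulate_cell_distances(cell: dict, rng: np.random.Generator) -> np.ndarray:
    family = cell["family"]
    p, m = int(cell["p"]), int(cell["m"])
    seed = int(rng.integers(2**31))
    if family in ("lq", "lq_maxmin"):
        X = gen_continuous(m, p, cell["data_model"], seed=seed)
        D = lq_distance_matrix(X, int(cell.get("q", 1)), normalized=family == "lq_maxmin")
    elif family in ("gm", "am", "titv"):
        G = gen_gwas(
            m,
            p,
            maf_low=float(cell.get("maf_low", 0.05)),
            maf_high=float(cell.get("maf_high", 0.5)),
            eta=float(cell.get("eta", 2.0)),
            seed=seed,
        )
        cell.setdefault("maf", G.maf)
        cell.setdefault("enc", G.encoding_model)
        D = gwas_distance_matrix(G, family)
    elif family in ("fmri", "fmri_maxmin"):
        S = gen_fmri_stack(m, p, T=cell.get("T"), seed=seed)
        D = fmri_distance_matrix(S, normalized=family == "fmri_maxmin")
    else:
        raise ValueError(f"unknown family: {family!r}")
    return D.condensed()


def moment_comparison(cells: Sequence[dict], seed: Optional[int] = None) -> pd.DataFrame:
    """Run a grid of theory-vs-simulation comparisons.

    Each cell is a dict with keys ``family`` (lq, lq_maxmin, gm, am, titv,
    fmri, fmri_maxmin), ``data_model`` (continuous families), ``q``, ``p``,
    ``m``, ``replicates`` and optional family-specific parameters
    (``maf_low``/``maf_high``/``eta`` for GWAS, ``T`` for stacks).  For each
    cell, ``replicates`` datasets are generated; the per-dataset mean and SD
    of pairwise distances are averaged and paired with the analytic
    prediction.  GWAS theory uses the MAFs realized in the first replicate
    (the prediction is conditional on the locus panel).
    """
    rng = np.random.default_rng(seed)
    rows: List[ComparisonRow] = []
    for cell_in in cells:
        cell = dict(cell_in)
        reps = int(cell.get("replicates", 20))
        means, sds = [], []
        for _ in range(reps):
            d = _simulate_cell_distances(cell, rng)
            means.append(d.mean())
            sds.append(d.std(ddof=1))
        theory = _theory_for_cell(cell)
        means = np.asarray(means)
        sds = np.asarray(sds)
        se = lambda v: float(v.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
        rows.append(
            ComparisonRow(
                family=cell["family"],
                data_model=cell.get("data_model", cell["family"]),
                q=cell.get("q"),
                p=int(cell["p"]),
                m=int(cell["m"]),
                replicates=reps,
                seed=seed,
                theory_mean=theory.mean,
                theory_sd=theory.sd,
                sim_mean=float(means.mean()),
                sim_sd=float(sds.mean()),
                sim_mean_se=se(means),
                sim_sd_se=se(sds),
            )
        )
    records = []
    for r in rows:
        rec = asdict(r)
        rec.pop("extra")
        records.append(rec)
    return pd.DataFrame.from_records(records)


@dataclass
class NormalityReport:
    statistic: float
    p_value: float
    skewness: float
    qq_theoretical: np.ndarray
    qq_sample: np.ndarray
    n: int


def normality_report(D: DistanceMatrix | np.ndarray) -> NormalityReport:
    """Shapiro-Wilk screen, QQ pairs and skewness of the pairwise distances.

    Operates on the upper-triangle distances; collections above the
    Shapiro-Wilk size cap are subsampled to 5000 values with a fixed seed.
    QQ pairs are against a normal fitted by mean/SD.
    """
    if isinstance(D, DistanceMatrix):
        d = D.condensed()
    else:
        arr = np.asarray(D, dtype=float)
        if arr.ndim == 2:
            iu = np.triu_indices(arr.shape[0], 1)
            d = arr[iu]
        else:
            d = arr
    if d.size < 20:
        raise ValueError("need at least 20 distances")
    if np.ptp(d) == 0:
        raise ValueError("degenerate (all-equal) distance collection")
    sample = d
    if d.size > _SHAPIRO_CAP:
        sub_rng = np.random.default_rng(0)
        sample = sub_rng.choice(d, _SHAPIRO_CAP, replace=False)
    stat, pval = stats.shapiro(sample)
    srt = np.sort(sample)
    n = srt.size
    probs = (np.arange(1, n + 1) - 0.5) / n
    theo = stats.norm.ppf(probs, loc=sample.mean(), scale=sample.std(ddof=1))
    return NormalityReport(
        statistic=float(stat),
        p_value=float(pval),
        skewness=float(stats.skew(d)),
        qq_theoretical=theo,
        qq_sample=srt,
        n=int(d.size),
    )


def _save_plot(fig, out_dir: Path, name: str) -> None:
    fig.savefig(out_dir / f"{name}.png", dpi=120, bbox_inches="tight")


def _write_manifest(out_dir: Path, which: str, seed, params: dict) -> None:
    manifest = {"experiment": which, "seed": seed, "params": params}
    (out_dir / f"{which}_manifest.json").write_text(json.dumps(manifest, indent=2))


def run_figure_suite(which: str, out_dir, seed: Optional[int] = 0) -> List[Path]:
    """Run one of the standard experiments and write its tables/plots.

    Selectors: ``fig1`` (Gaussian convergence of L1/L2 distances on uniform
    data), ``fig6`` (TiTv mean-distance curves over average MAF for several
    Ti/Tv ratios), ``fig7`` (TiTv theory vs simulation over eta and average
    MAF), ``fig11`` (theory vs simulated Manhattan moments on normal data),
    ``fig12`` (distance skewness under increasing attribute correlation),
    ``s_figures`` (range-normalized and stack-metric comparisons).
    Returns the written file paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    rng = np.random.default_rng(seed)

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        written.append(path)

    if which == "fig1":
        m = 100
        recs = []
        fig, axes = plt.subplots(2, 3, figsize=(11, 6))
        for col, p in enumerate((10, 100, 10000)):
            X = gen_continuous(m, p, "uniform", seed=int(rng.integers(2**31)))
            for row, q in enumerate((1, 2)):
                rep = normality_report(lq_distance_matrix(X, q))
                recs.append({"p": p, "q": q, "shapiro_W": rep.statistic,
                             "p_value": rep.p_value, "skewness": rep.skewness})
                ax = axes[row][col]
                ax.hist(lq_distance_matrix(X, q).condensed(), bins=40, density=True)
                ax.set_title(f"q={q}, p={p}, W={rep.statistic:.3f}")
        emit(pd.DataFrame(recs), "fig1_normality")
        _save_plot(fig, out_dir, "fig1_distance_histograms")
        plt.close(fig)
        _write_manifest(out_dir, which, seed, {"m": m, "p": [10, 100, 10000]})
    elif which == "fig6":
        from .gwas_moments import titv_mean_curve

        grid = np.arange(0.01, 0.91, 0.009)
        fig, ax = plt.subplots(figsize=(6, 4))
        recs = []
        for eta in (0.1, 1.0, 2.0):
            curve, argmax = titv_mean_curve(grid, eta, p=100)
            for f, v in zip(grid, curve):
                recs.append({"eta": eta, "fbar": f, "mean_titv": v})
            ax.plot(grid, curve, label=f"eta={eta} (argmax {argmax:.2f})")
        ax.set_xlabel("average minor allele frequency")
        ax.set_ylabel("predicted mean TiTv distance")
        ax.legend()
        emit(pd.DataFrame(recs), "fig6_titv_curves")
        _save_plot(fig, out_dir, "fig6_titv_curves")
        plt.close(fig)
        _write_manifest(out_dir, which, seed, {"p": 100, "eta": [0.1, 1.0, 2.0]})
    elif which == "fig7":
        fbar = 0.055
        w = 0.05
        cells = [
            dict(family="titv", p=100, m=100, replicates=10, eta=eta,
                 maf_low=fbar - w / 2, maf_high=fbar + w / 2)
            for eta in (0.5, 1.0, 1.5, 2.0)
        ]
        df = moment_comparison(cells, seed=int(rng.integers(2**31)))
        df["eta"] = [0.5, 1.0, 1.5, 2.0]
        emit(df, "fig7_titv_eta")
        cells = [
            dict(family="titv", p=100, m=100, replicates=10, eta=2.0,
                 maf_low=f - w / 2, maf_high=f + w / 2)
            for f in (0.055, 0.15, 0.25, 0.35)
        ]
        df2 = moment_comparison(cells, seed=int(rng.integers(2**31)))
        df2["fbar"] = [0.055, 0.15, 0.25, 0.35]
        emit(df2, "fig7_titv_fbar")
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        axes[0].errorbar(df["eta"], df["sim_mean"], yerr=df["sim_sd"], label="simulated")
        axes[0].plot(df["eta"], df["theory_mean"], "o--", label="theory")
        axes[0].set_xlabel("Ti/Tv ratio eta"); axes[0].legend()
        axes[1].errorbar(df2["fbar"], df2["sim_mean"], yerr=df2["sim_sd"], label="simulated")
        axes[1].plot(df2["fbar"], df2["theory_mean"], "o--", label="theory")
        axes[1].set_xlabel("average MAF"); axes[1].legend()
        _save_plot(fig, out_dir, "fig7_titv_moments")
        plt.close(fig)
        _write_manifest(out_dir, which, seed, {"m": 100, "p": 100})
    elif which == "fig11":
        cells = [
            dict(family="lq", data_model="normal", q=1, p=p, m=100, replicates=20)
            for p in (1000, 2000, 3000, 4000, 5000)
        ]
        df = moment_comparison(cells, seed=int(rng.integers(2**31)))
        emit(df, "fig11_manhattan_normal")
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        for ax, (t, s) in zip(
            axes, [("theory_mean", "sim_mean"), ("theory_sd", "sim_sd")]
        ):
            ax.plot(df[t], df[s], "o")
            lims = [min(df[t].min(), df[s].min()), max(df[t].max(), df[s].max())]
            ax.plot(lims, lims, "--", color="gray")
            ax.set_xlabel(f"{t}"); ax.set_ylabel(f"{s}")
        _save_plot(fig, out_dir, "fig11_theory_vs_sim")
        plt.close(fig)
        _write_manifest(out_dir, which, seed, {"m": 100, "p_grid": [1000, 2000, 3000, 4000, 5000]})
    elif which == "fig12":
        m = p = 100
        recs = []
        fig, ax = plt.subplots(figsize=(6, 4))
        for prob, hi in ((0.0, 0.0), (0.1, 0.9), (0.3, 0.9), (0.6, 0.9), (1.0, 0.9)):
            if prob == 0:
                X = gen_continuous(m, p, "normal", seed=int(rng.integers(2**31)))
            else:
                R = random_structured_correlation(p, prob, hi=hi,
                                                  seed=int(rng.integers(2**31)))
                X = impose_correlation(
                    gen_continuous(m, p, "normal", seed=int(rng.integers(2**31))), R
                )
            d = lq_distance_matrix(X, q=2).condensed()
            rbar = mean_abs_correlation(X)
            recs.append({"connection_prob": prob, "rbar_abs": rbar,
                         "skewness": float(stats.skew(d)),
                         "sim_mean": float(d.mean()), "sim_var": float(d.var(ddof=1))})
            ax.hist(d, bins=40, density=True, histtype="step",
                    label=f"rbar={rbar:.2f}")
        ax.legend(); ax.set_xlabel("Euclidean distance")
        emit(pd.DataFrame(recs), "fig12_correlation_skewness")
        _save_plot(fig, out_dir, "fig12_densities")
        plt.close(fig)
        _write_manifest(out_dir, which, seed, {"m": m, "p": p})
    elif which == "s_figures":
        cells = [
            dict(family="lq_maxmin", data_model="uniform", q=1, p=500, m=100, replicates=10),
            dict(family="lq_maxmin", data_model="normal", q=2, p=500, m=100, replicates=10),
            dict(family="fmri", p=30, m=100, replicates=10),
            dict(family="fmri_maxmin", p=30, m=100, replicates=10),
        ]
        df = moment_comparison(cells, seed=int(rng.integers(2**31)))
        emit(df, "sfig_maxmin_and_stack")
        _write_manifest(out_dir, which, seed, {})
    else:
        raise ValueError(f"unknown figure selector: {which!r}")
    written.append(out_dir / f"{which}_manifest.json")
    return written
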