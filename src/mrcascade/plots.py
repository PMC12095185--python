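"""Static diagnostic plots for one harmonized instrument set / MR fit.

Scatter (per-SNP effects with fitted slopes), forest (per-SNP Wald
ratios), funnel (precision against ratio) and leave-one-out forest —
written as image files, one pathway per call.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .estimators import MrResultSet, wald_ratio


def _ratios(rec):
    est, se = [], []
    for r in rec.itertuples(index=False):
        e, s = wald_ratio(r.beta_exp, r.beta_out, r.se_out)
        est.append(e)
        se.append(s)
    return np.array(est), np.array(se)


def pathway_diagnostics(
    hset, results: MrResultSet, outdir: str | Path, stem: str | None = None
) -> list[Path]:
    """Write scatter, forest, funnel and leave-one-out plots; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"{results.exposure_id}__{results.outcome_id}"
    rec = hset.records
    est, se = _ratios(rec)
    paths = []

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(
        rec.beta_exp, rec.beta_out, xerr=rec.se_exp, yerr=rec.se_out,
        fmt="o", ms=3, lw=0.7, alpha=0.7,
    )
    xs = np.linspace(0, rec.beta_exp.abs().max() * 1.05, 10)
    for name, fit in results.fits.items():
        if name in ("ivw", "egger"):
            ax.plot(xs, fit.beta * xs, label=f"{name} ({fit.beta:.3f})")
    ax.set_xlabel("SNP effect on exposure")
    ax.set_ylabel("SNP effect on outcome")
    ax.legend(fontsize=8)
    ax.set_title(f"{results.exposure_id} → {results.outcome_id}")
    paths.append(outdir / f"{stem}_scatter.png")
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)

    order = np.argsort(est)
    fig, ax = plt.subplots(figsize=(5, max(3, 0.18 * len(est))))
    y = np.arange(len(est))
    ax.errorbar(est[order], y, xerr=1.96 * se[order], fmt="o", ms=3, lw=0.8)
    ax.axvline(results.fits["ivw"].beta, color="firebrick", lw=1, label="IVW")
    ax.set_yticks(y)
    ax.set_yticklabels(rec.snp_id.to_numpy()[order], fontsize=6)
    ax.set_xlabel("per-SNP causal estimate (Wald ratio)")
    ax.legend(fontsize=8)
    paths.append(outdir / f"{stem}_forest.png")
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(est, 1.0 / se, s=12, alpha=0.7)
    ax.axvline(results.fits["ivw"].beta, color="firebrick", lw=1)
    ax.set_xlabel("per-SNP causal estimate")
    ax.set_ylabel("precision (1/SE)")
    paths.append(outdir / f"{stem}_funnel.png")
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)

    if results.loo is not None:
        loo = results.loo
        fig, ax = plt.subplots(figsize=(5, max(3, 0.18 * len(loo))))
        y = np.arange(len(loo))
        ax.errorbar(loo.beta, y, xerr=1.96 * loo.se, fmt="o", ms=3, lw=0.8)
        ax.axvline(results.fits["ivw"].beta, color="firebrick", lw=1)
        ax.set_yticks(y)
        ax.set_yticklabels(loo.snp_id, fontsize=6)
        ax.set_xlabel("IVW estimate with SNP omitted")
        paths.append(outdir / f"{stem}_leave_one_out.png")
        fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
        plt.close(fig)
    return paths
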