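"""Result tabulation and figure rendering.

No statistics live here: everything written out is computed by the gpc,
simulate and power modules and merely serialized or drawn.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .config import RunManifest
from .gpc import NetBenefitEstimate, PermutationTestResult
from .power import PowerResult

__all__ = ["power_results_frame", "write_report", "write_analysis_report", "plot_power_curves"]


def power_results_frame(results: Sequence[PowerResult]) -> pd.DataFrame:
    """Tidy frame: one row per (scenario, threshold fraction) cell."""
    if not results:
        raise ValueError("no results to tabulate")
    return pd.DataFrame([r.to_dict() for r in results])


def plot_power_curves(results: Sequence[PowerResult], path) -> bool:
    """Render power vs threshold fraction, one line per scenario label.

    Returns False (without writing) if no plotting backend is importable,
    so CSV output still proceeds in degraded environments.
    """
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:
        return False
    frame = power_results_frame(results)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label, sub in frame.groupby("scenario", sort=False):
        sub = sub.sort_values("threshold_fraction")
        ax.errorbar(
            sub["threshold_fraction"], sub["power"], yerr=sub["mc_se"],
            marker="o", capsize=2, label=label,
        )
    ax.set_xlabel("threshold (fraction of rate-of-change SD)")
    ax.set_ylabel("empirical power")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    ax.grid(alpha=0.3)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return True


def write_report(
    results: Sequence[PowerResult],
    manifest: RunManifest,
    outdir,
    plot: bool = True,
) -> list[Path]:
    """Write the tidy power CSV, optional power-curve figure and JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    csv_path = outdir / "power_results.csv"
    power_results_frame(results).to_csv(csv_path, index=False)
    manifest.add_output(csv_path)
    written.append(csv_path)

    if plot:
        fig_path = outdir / "power_curves.png"
        if plot_power_curves(results, fig_path):
            manifest.add_output(fig_path)
            written.append(fig_path)

    manifest_path = outdir / "manifest.json"
    manifest.write(manifest_path)
    written.append(manifest_path)
    return written


def write_analysis_report(
    estimate: NetBenefitEstimate,
    test: Optional[PermutationTestResult],
    specs,
    path,
) -> None:
    """Single-analysis JSON report: spec echo, net benefit decomposition, p-value."""
    payload = {
        "outcomes": [
            {
                "name": s.name,
                "direction": s.direction,
                "threshold": s.threshold,
                "priority": s.priority,
                "weight": s.weight,
            }
            for s in specs
        ],
        "net_benefit": estimate.to_dict(),
    }
    if test is not None:
        payload["permutation_test"] = test.to_dict()
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
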