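"""Bland-Altman series and report rendering.

The ratio Bland-Altman plot for a feature places each lesion at
x = geometric mean of the test and retest values, y = retest/test ratio,
both on log axes; the bias line sits at exp(d_bar) and the 95% limits of
agreement at exp(d_bar -/+ 1.96 sigma).  Points are colored per patient so
patient-level biases are visible as vertically shifted clusters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConsistencyError
from .repeatability import VarianceComponents

__all__ = ["BlandAltmanSeries", "bland_altman_series", "render_report"]

logger = logging.getLogger(__name__)


@dataclass
class BlandAltmanSeries:
    """Scatter data plus reference lines for one feature in one stratum."""

    feature: str
    stratum: str
    points: pd.DataFrame  # columns: patient_id, lesion_id, x, y
    bias_ratio: float
    loa_lower_ratio: float
    loa_upper_ratio: float


def bland_altman_series(
    pairs: pd.DataFrame,
    feature: str,
    vc: VarianceComponents,
    stratum: str = "all",
) -> BlandAltmanSeries:
    """Build the log-log Bland-Altman series for a stratum.

    ``vc`` must have been computed from the same stratum (lesion counts are
    checked); the reference lines are ratios exp(d_bar) and
    exp(d_bar -/+ 1.96 sigma).
    """
    if vc.n_lesions != len(pairs):
        raise ConsistencyError(
            f"variance components cover {vc.n_lesions} lesions but the pair "
            f"table has {len(pairs)}"
        )
    a = pairs[f"{feature}_test"].to_numpy(dtype=float)
    b = pairs[f"{feature}_retest"].to_numpy(dtype=float)
    points = pd.DataFrame(
        {
            "patient_id": pairs["patient_id"].to_numpy(),
            "lesion_id": pairs["lesion_id"].to_numpy(),
            "x": np.sqrt(a * b),
            "y": b / a,
        }
    )
    return BlandAltmanSeries(
        feature=feature,
        stratum=stratum,
        points=points,
        bias_ratio=float(np.exp(vc.d_bar)),
        loa_lower_ratio=float(np.exp(vc.d_bar - 1.96 * vc.sigma)),
        loa_upper_ratio=float(np.exp(vc.d_bar + 1.96 * vc.sigma)),
    )


_AXIS_LABELS = {
    "suv_max": "SUV$_{max}$",
    "suv_mean": "SUV$_{mean}$",
    "suv_total": "SUV$_{total}$ (SUV$\\cdot$cm$^3$)",
    "volume_cc": "volume (cm$^3$)",
}


def _plot_series(series: BlandAltmanSeries, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 4.2))
    patients = series.points["patient_id"].unique()
    cmap = plt.get_cmap("tab20")
    for i, pid in enumerate(patients):
        sub = series.points[series.points["patient_id"] == pid]
        ax.scatter(sub["x"], sub["y"], s=14, color=cmap(i % 20), label=pid, alpha=0.8)
    ax.axhline(series.bias_ratio, color="k", lw=1.2)
    ax.axhline(series.loa_lower_ratio, color="k", lw=1.0, ls="--")
    ax.axhline(series.loa_upper_ratio, color="k", lw=1.0, ls="--")
    ax.set_xscale("log")
    ax.set_yscale("log")
    label = _AXIS_LABELS.get(series.feature, series.feature)
    ax.set_xlabel(f"geometric mean of test/retest {label}")
    ax.set_ylabel("retest / test ratio")
    ax.set_title(f"{label} — {series.stratum}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_report(
    results: pd.DataFrame,
    series: list[BlandAltmanSeries],
    out_dir: str | Path,
    *,
    plots: bool = True,
) -> dict:
    """Write the stratified report (CSV + JSON), Bland-Altman plots and a
    manifest JSON listing every file produced.  Returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    csv_path = out / "repeatability_report.csv"
    results.to_csv(csv_path, index=False)
    files.append(csv_path.name)

    json_path = out / "repeatability_report.json"
    json_path.write_text(
        json.dumps(results.to_dict(orient="records"), indent=2, sort_keys=True) + "\n"
    )
    files.append(json_path.name)

    if plots:
        for s in series:
            name = f"bland_altman_{s.feature}_{s.stratum.replace('>', 'gt').replace('.', 'p')}.png"
            _plot_series(s, out / name)
            files.append(name)

    manifest = {"out_dir": str(out), "files": sorted(files)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    manifest["files"] = sorted(files + ["manifest.json"])
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
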