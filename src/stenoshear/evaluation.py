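"""Evaluation: error metrics, node-wise Bland–Altman agreement, axial mean
WSS profiles and visual reports.

Conventions: all node-wise statistics use the population (1/N) variance;
R² is the squared node-wise Pearson correlation (scatter-plot usage);
"standard error" is the standard deviation of the signed prediction errors.
Bland–Altman limits of agreement are bias ± 1.96 standard deviations of the
node-wise differences.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import CorrelationUndefinedError, ShapeError
from .oracle import WSSField


def _as_flat(pred, ref):
    p = pred.values if isinstance(pred, WSSField) else np.asarray(pred, float)
    r = ref.values if isinstance(ref, WSSField) else np.asarray(ref, float)
    if p.shape != r.shape:
        raise ShapeError(f"shape mismatch: {p.shape} vs {r.shape}")
    return p.ravel(), r.ravel()


@dataclass
class MetricsRecord:
    MAE: float
    MdnAE: float
    p75AE: float
    StdError: float
    RMSE: float
    PearsonR: float
    R2: float
    n_nodes: int

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class AgreementRecord:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_nodes: int


def compute_metrics(pred, ref) -> MetricsRecord:
    """Node-wise error metrics between a prediction and a reference field."""
    p, r = _as_flat(pred, ref)
    if p.size < 2:
        raise ShapeError("need at least 2 nodes")
    if np.std(p) == 0 or np.std(r) == 0:
        raise CorrelationUndefinedError(
            "constant field: Pearson correlation undefined"
        )
    err = p - r
    ae = np.abs(err)
    pearson = float(np.corrcoef(p, r)[0, 1])
    return MetricsRecord(
        MAE=float(ae.mean()),
        MdnAE=float(np.median(ae)),
        p75AE=float(np.percentile(ae, 75)),
        StdError=float(err.std()),          # population convention
        RMSE=float(np.sqrt((err**2).mean())),
        PearsonR=pearson,
        R2=pearson**2,
        n_nodes=int(p.size),
    )


def bland_altman(pred, ref) -> AgreementRecord:
    """Mean difference and 95% limits of agreement over all nodes."""
    p, r = _as_flat(pred, ref)
    if p.size < 2:
        raise ShapeError("need at least 2 nodes")
    diff = p - r
    bias = float(diff.mean())
    sd = float(diff.std())
    return AgreementRecord(
        bias=bias, sd_diff=sd,
        loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        n_nodes=int(p.size),
    )


def axial_profile(field) -> tuple[np.ndarray, np.ndarray]:
    """Per-station circumferential mean WSS on the normalized axial
    coordinate l/l0 in [0, 1].  Returns (l_over_l0, profile)."""
    vals = field.values if isinstance(field, WSSField) else np.asarray(field, float)
    if vals.ndim != 2:
        raise ShapeError("field must be 2D (axial x circumferential)")
    profile = vals.mean(axis=1)
    x = np.linspace(0.0, 1.0, vals.shape[0])
    return x, profile


REPORT_ARTIFACTS = (
    "heatmap_reference.png",
    "heatmap_prediction.png",
    "heatmap_abs_error.png",
    "scatter.png",
    "bland_altman.png",
    "axial_profile.png",
)


def render_report(case_name: str, pred, ref, out_dir) -> dict:
    """Write unwrapped-surface heatmaps, a scatter plot with the identity
    line and R², a Bland–Altman plot, the axial-profile overlay and a
    metrics CSV.  Returns {artifact name: path}."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(out_dir, exist_ok=True)
    p, r = _as_flat(pred, ref)
    pv = p.reshape(np.asarray(
        pred.values if isinstance(pred, WSSField) else pred).shape)
    rv = r.reshape(pv.shape)
    metrics = compute_metrics(pred, ref)
    agree = bland_altman(pred, ref)
    paths = {}

    def heat(data, title, fname, cmap="turbo"):
        fig, ax = plt.subplots(figsize=(8, 2.2))
        im = ax.imshow(data.T, aspect="auto", origin="lower", cmap=cmap)
        ax.set_xlabel("axial station")
        ax.set_ylabel("circumferential")
        ax.set_title(title)
        fig.colorbar(im, ax=ax, label="WSS (Pa)")
        path = os.path.join(out_dir, fname)
        fig.savefig(path, dpi=110)
        plt.close(fig)
        paths[fname] = path

    heat(rv, f"{case_name}: reference WSS", "heatmap_reference.png")
    heat(pv, f"{case_name}: predicted WSS", "heatmap_prediction.png")
    heat(np.abs(pv - rv), f"{case_name}: |error|", "heatmap_abs_error.png",
         cmap="magma")

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(r, p, ".", ms=2, alpha=0.4)
    lim = [0, max(r.max(), p.max()) * 1.05]
    ax.plot(lim, lim, "k--", lw=1)
    ax.set_xlabel("reference WSS (Pa)")
    ax.set_ylabel("predicted WSS (Pa)")
    ax.set_title(f"{case_name}: R² = {metrics.R2:.4f}")
    fig.savefig(os.path.join(out_dir, "scatter.png"), dpi=110)
    plt.close(fig)
    paths["scatter.png"] = os.path.join(out_dir, "scatter.png")

    fig, ax = plt.subplots(figsize=(5, 4))
    mean_pr = (p + r) / 2
    ax.plot(mean_pr, p - r, ".", ms=2, alpha=0.4)
    for y, label in [(agree.bias, "bias"), (agree.loa_low, "LL"),
                     (agree.loa_high, "UL")]:
        ax.axhline(y, ls="--", lw=1, color="k")
        ax.annotate(f"{label} = {y:.2f}", (0.99, y), xycoords=("axes fraction", "data"),
                    ha="right", fontsize=8)
    ax.set_xlabel("mean WSS (Pa)")
    ax.set_ylabel("difference (Pa)")
    ax.set_title(f"{case_name}: Bland–Altman")
    fig.savefig(os.path.join(out_dir, "bland_altman.png"), dpi=110)
    plt.close(fig)
    paths["bland_altman.png"] = os.path.join(out_dir, "bland_altman.png")

    fig, ax = plt.subplots(figsize=(6, 3))
    x, prof_r = axial_profile(rv)
    _, prof_p = axial_profile(pv)
    ax.plot(x, prof_r, label="reference")
    ax.plot(x, prof_p, label="prediction")
    ax.set_xlabel("l / l0")
    ax.set_ylabel("mean WSS (Pa)")
    ax.legend()
    ax.set_title(f"{case_name}: axial mean WSS")
    fig.savefig(os.path.join(out_dir, "axial_profile.png"), dpi=110)
    plt.close(fig)
    paths["axial_profile.png"] = os.path.join(out_dir, "axial_profile.png")

    table = pd.DataFrame([{**metrics.as_dict(), "bias": agree.bias,
                           "loa_low": agree.loa_low,
                           "loa_high": agree.loa_high,
                           "case": case_name}])
    csv_path = os.path.join(out_dir, "metrics.csv")
    table.to_csv(csv_path, index=False)
    paths["metrics.csv"] = csv_path
    return paths


def metrics_table(
    records: dict[str, tuple[np.ndarray, np.ndarray]]
) -> pd.DataFrame:
    """Pooled metrics over concatenated test-case nodes, one row per
    (model, scenario) entry: records maps name -> (pred_concat, ref_concat)."""
    rows = []
    for name, (p, r) in records.items():
        m = compute_metrics(p, r)
        a = bland_altman(p, r)
        model, _, scenario = name.partition("/")
        rows.append({"model": model, "scenario": scenario or "all",
                     **m.as_dict(), "bias": a.bias,
                     "loa_low": a.loa_low, "loa_high": a.loa_high})
    return pd.DataFrame(rows)
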