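"""Summaries of realization-level simulation output.

Stage proportions across realizations are summarized by their median and a
95% percentile interval taken between the lower and upper 2.25% of the ranked
values (the tail the source tables print; a conventional 2.5% tail is one
keyword away).  Percent-change tables report the average over realizations of
100 x (shifted - baseline) per stage, annotated with the factor's risk
direction from its odds ratio.
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "percentile_interval",
    "summary_table",
    "percent_change_table",
    "write_outputs",
    "plot_stage_intervals",
]


def percentile_interval(values, tail: float = 0.0225) -> tuple[float, float, float]:
    """(lower, median, upper) empirical quantiles at (tail, 0.5, 1 - tail).

    Linear interpolation between order statistics; ``tail=0`` degenerates to
    (min, median, max).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("percentile_interval needs at least one value")
    if not 0.0 <= tail < 0.5:
        raise ValueError(f"tail must be in [0, 0.5), got {tail}")
    lo, med, hi = np.quantile(v, [tail, 0.5, 1.0 - tail], method="linear")
    return float(lo), float(med), float(hi)


def summary_table(results: Sequence, tail: float = 0.0225) -> pd.DataFrame:
    """Long-format table: one row per (design, grid value, stage)."""
    rows = []
    for res in results:
        for j, stage in enumerate(res.stage_labels):
            lo, med, hi = percentile_interval(res.proportions[:, j], tail)
            rows.append(
                {
                    "design_id": res.design_id,
                    "factor": res.factor,
                    "grid_value": res.grid_value,
                    "stage": stage,
                    "median_proportion": med,
                    "pi_lower": lo,
                    "pi_upper": hi,
                    "avg_percent_change": float(res.mean_percent_change[j]),
                }
            )
    columns = ["design_id", "factor", "grid_value", "stage", "median_proportion",
               "pi_lower", "pi_upper", "avg_percent_change"]
    return pd.DataFrame(rows, columns=columns)


def percent_change_table(
    results: Sequence,
    baseline,
    odds_ratios: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Average stage-wise percent change (points) per design vs. baseline.

    Requires every result to carry the same realization count as the
    baseline.  When ``odds_ratios`` is given, each row is annotated with the
    factor's risk direction (OR > 1: increased late-stage risk).
    """
    rows = []
    for res in results:
        if res.proportions.shape != baseline.proportions.shape:
            raise ValueError(
                f"design {res.design_id}: {res.proportions.shape[0]} realizations "
                f"vs. baseline {baseline.proportions.shape[0]}"
            )
        change = 100.0 * (res.proportions - baseline.proportions)
        row = {
            "design_id": res.design_id,
            "factor": res.factor,
            "grid_value": res.grid_value,
        }
        for j, stage in enumerate(res.stage_labels):
            row[f"avg_change_{stage}"] = float(change[:, j].mean())
        if odds_ratios is not None and res.factor in odds_ratios:
            row["effect"] = (
                "Increased Risk" if odds_ratios[res.factor] > 1.0 else "Decreased Risk"
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_outputs(
    table: pd.DataFrame,
    out_dir,
    meta: Mapping | None = None,
    scenario: str = "scenario",
    figures: Mapping[str, "object"] | None = None,
) -> dict[str, Path]:
    """Write summary.csv (long), summary.json (nested), run_meta.json, figures.

    Returns the paths written.  CSV floats use Python's shortest round-trip
    representation; re-read with ``pd.read_csv(..., float_precision=
    "round_trip")`` to recover the values bit for bit.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        csv_path = out_dir / "summary.csv"
        table.to_csv(csv_path, index=False,
                     float_format=lambda x: repr(float(x)))
        paths["summary_csv"] = csv_path

        nested = {scenario: table.to_dict(orient="records")}
        json_path = out_dir / "summary.json"
        json_path.write_text(json.dumps(nested, indent=2, allow_nan=True))
        paths["summary_json"] = json_path

        meta_path = out_dir / "run_meta.json"
        meta_path.write_text(json.dumps(dict(meta or {}), indent=2, default=str))
        paths["run_meta"] = meta_path

        for name, fig in (figures or {}).items():
            fig_path = out_dir / f"{name}.png"
            fig.savefig(fig_path, dpi=150, bbox_inches="tight")
            paths[name] = fig_path
        return paths
    except OSError as exc:
        raise OSError(f"writing outputs under {out_dir}: {exc}") from exc


def plot_stage_intervals(
    results: Sequence,
    baseline,
    stage_index: int = 0,
):
    """Dot-and-interval chart of one stage's proportion across design cells.

    Medians as dots, percentile intervals as horizontal lines, the baseline
    median as a dashed vertical reference.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, max(2.0, 0.35 * len(results))))
    labels = []
    for y, res in enumerate(results):
        ax.hlines(y, res.pi_lower[stage_index], res.pi_upper[stage_index],
                  color="black", lw=1.2)
        ax.plot(res.median[stage_index], y, "o", color="black", ms=4)
        value = "" if res.grid_value is None else f" @ {res.grid_value:g}"
        labels.append(f"{res.design_id}{value}")
    ax.axvline(baseline.median[stage_index], color="tab:blue", ls="--", lw=1)
    ax.set_yticks(range(len(results)), labels)
    ax.set_xlabel(f"proportion diagnosed at stage {baseline.stage_labels[stage_index]}")
    ax.invert_yaxis()
    fig.tight_layout()
    return fig
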