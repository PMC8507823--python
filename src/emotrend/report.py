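"""Figure and table rendering from weekly series and fitted models."""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .aggregate import scale_for_display
from .config import MH, MH_COMMUNITIES, NMH, TEEN_COMMUNITY
from .itsa import ITSAFit

__all__ = ["load_events", "plot_series", "export_tables"]


def load_events(path=None) -> pd.DataFrame:
    """Week/label annotation table (defaults to the bundled pandemic
    timeline, used only for figure markers)."""
    if path is None:
        with resources.as_file(resources.files("emotrend.resources").joinpath("events.csv")) as p:
            return pd.read_csv(p)
    return pd.read_csv(path)


def _annotate(ax, annotations: Optional[pd.DataFrame]) -> None:
    if annotations is None or annotations.empty:
        return
    for _, row in annotations.iterrows():
        ax.axvline(row["week"], color="0.75", linestyle=":", linewidth=0.8, zorder=0)
        ax.text(
            row["week"], ax.get_ylim()[1], str(row.get("label", "")),
            rotation=90, va="top", ha="right", fontsize=5, color="0.4",
        )


def _line_plot(series, value_col, keys, title, ylabel, out_path, annotations, scale_keys=(), factor=1.0):
    fig, ax = plt.subplots(figsize=(9, 4.5))
    for key in keys:
        sub = series.loc[series["key"] == key].sort_values("week")
        if sub.empty:
            continue
        vals = sub[value_col]
        label = key
        if key in scale_keys and factor != 1.0:
            vals = scale_for_display(vals, factor)
            label = f"{key} (x{factor:g})"
        ax.plot(sub["week"], vals, label=label, linewidth=1.2)
    ax.set_xlabel("week")
    ax.set_ylabel(ylabel)
    ax.set_title(title)
    ax.legend(fontsize=7)
    _annotate(ax, annotations)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def plot_series(
    community_series: pd.DataFrame,
    cohort_series: pd.DataFrame,
    out_dir,
    annotations: Optional[pd.DataFrame] = None,
    display_scale: float = 30.0,
) -> Dict[str, Path]:
    """Render the five standard figures from tidy weekly series.

    1. participants by community (mental-health communities display-scaled),
    2. posting frequency by community, 3. mean emotion by community,
    4. posting frequency by cohort, 5. mean emotion by cohort.
    """
    if community_series.empty or cohort_series.empty:
        raise ValueError("empty weekly series")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    communities = [TEEN_COMMUNITY, *MH_COMMUNITIES]
    cohorts = [NMH, MH]
    paths = {
        "participants_by_community": _line_plot(
            community_series, "n_participants", communities,
            "Weekly active participants by community", "participants",
            out_dir / "participants_by_community.png", annotations,
            scale_keys=set(MH_COMMUNITIES), factor=display_scale,
        ),
        "frequency_by_community": _line_plot(
            community_series, "posts_per_participant", communities,
            "Weekly posts/comments per participant by community", "items per participant",
            out_dir / "frequency_by_community.png", annotations,
        ),
        "emotion_by_community": _line_plot(
            community_series, "mean_compound", communities,
            "Weekly mean compound negative emotion by community", "compound emotion",
            out_dir / "emotion_by_community.png", annotations,
        ),
        "frequency_by_cohort": _line_plot(
            cohort_series, "posts_per_participant", cohorts,
            "Weekly posts/comments per participant by cohort (teen community)", "items per participant",
            out_dir / "frequency_by_cohort.png", annotations,
        ),
        "emotion_by_cohort": _line_plot(
            cohort_series, "mean_compound", cohorts,
            "Weekly mean compound negative emotion by cohort (teen community)", "compound emotion",
            out_dir / "emotion_by_cohort.png", annotations,
        ),
    }
    return paths


def summary_table(series: pd.DataFrame) -> pd.DataFrame:
    """Per-key mean and range of the weekly frequency and emotion series."""
    rows = []
    for key, sub in series.groupby("key"):
        for col in ("n_participants", "posts_per_participant", "mean_compound"):
            vals = sub[col].dropna()
            if vals.empty:
                continue
            rows.append(
                {
                    "key": key,
                    "measure": col,
                    "mean": float(vals.mean()),
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                }
            )
    return pd.DataFrame(rows)


def export_tables(
    fit: Optional[ITSAFit],
    community_series: pd.DataFrame,
    cohort_series: pd.DataFrame,
    out_dir,
) -> Dict[str, Path]:
    """Write the coefficient table (eight parameter rows plus R-square) and
    the per-key weekly summary statistics."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    if fit is not None:
        coef = fit.to_frame()
        r2_row = pd.DataFrame(
            [{"parameter": "R-square", "b": fit.r_square,
              "approx_se": np.nan, "t_value": np.nan, "p_value": np.nan}]
        )
        coef = pd.concat([coef, r2_row], ignore_index=True)
        coef_path = out_dir / "itsa_coefficients.csv"
        coef.to_csv(coef_path, index=False)
        paths["itsa_coefficients"] = coef_path
        fit.to_json(out_dir / "itsa_fit.json")
        paths["itsa_fit"] = out_dir / "itsa_fit.json"
        (out_dir / "itsa_summary.txt").write_text(fit.summary() + "\n", encoding="utf-8")
        paths["itsa_summary"] = out_dir / "itsa_summary.txt"
    summary = pd.concat(
        [summary_table(community_series).assign(grouping="community"),
         summary_table(cohort_series).assign(grouping="cohort")],
        ignore_index=True,
    )
    summary_path = out_dir / "weekly_summary.csv"
    summary.to_csv(summary_path, index=False)
    paths["weekly_summary"] = summary_path
    return paths
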