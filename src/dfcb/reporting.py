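"""Human-readable result tables: method comparison, (T,S) surface, edges.

Outputs are plain pandas DataFrames (CSV/Markdown-ready); plotting is left
to the caller — the accuracy-surface table is heat-map ready as is.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import CVResult
from .selection import BackProjectedFeature

__all__ = ["render_comparison", "render_surface", "render_edge_report"]

_METRICS = ("ACC", "TPR", "TNR", "PPV", "NPV", "F1")


def render_comparison(results: list[CVResult]) -> pd.DataFrame:
    """Method-by-metric table (percent, one decimal) with best-per-column flags.

    The ``best`` column lists the metrics on which that method is (tied
    for) best — the tabular analogue of bold-facing winners.
    """
    if not results:
        raise ValueError("no results to render")
    rows = {r.method: [getattr(r.final, m) for m in _METRICS] for r in results}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(_METRICS)).round(1)
    best_flags = []
    for method in df.index:
        flags = [m for m in _METRICS
                 if np.isfinite(df.loc[method, m]) and df.loc[method, m] == df[m].max()]
        best_flags.append(",".join(flags))
    df["best"] = best_flags
    df.index.name = "method"
    return df


def render_surface(surface: list[dict]) -> pd.DataFrame:
    """Accuracy surface over the (T, S) grid, T as rows and S as columns."""
    df = pd.DataFrame([{k: c[k] for k in ("T", "S", "ACC")} for c in surface])
    return df.pivot(index="T", columns="S", values="ACC")


def render_edge_report(
    features: list[BackProjectedFeature], roi_labels: list[str] | None = None
) -> pd.DataFrame:
    """Selected-feature table: coordinates, contributing edge, frequency bin."""
    rows = []
    for f in features:
        i, j = f.spatial_edge
        names = f.spatial_names
        if names is None and roi_labels is not None:
            names = (roi_labels[i - 1], roi_labels[j - 1])
        rows.append(
            {
                "feature": f.flat_index,
                "row_component": f.coord[0],
                "col_component": f.coord[1],
                "roi_i": i,
                "roi_j": j,
                "roi_i_name": names[0] if names else str(i),
                "roi_j_name": names[1] if names else str(j),
                "temporal_bin": f.temporal_bin,
                "p_value": f.p_value,
            }
        )
    columns = ["feature", "row_component", "col_component", "roi_i", "roi_j",
               "roi_i_name", "roi_j_name", "temporal_bin", "p_value"]
    return pd.DataFrame(rows, columns=columns)


def write_report(df: pd.DataFrame, out: str | Path, stem: str) -> None:
    """CSV + Markdown dump of one table."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / f"{stem}.csv")
    with open(out / f"{stem}.md", "w") as fh:
        fh.write(df.to_markdown())
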