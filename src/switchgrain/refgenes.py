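"""Reference-gene stability selection by coefficient of variation.

Stable normalizer genes are screened by the coefficient of variation
(CV% = 100 · sd / mean) of their expression across many columns — in the
original screen, hundreds of public microarray samples — and selected when
the CV falls strictly below a threshold (10% by default). The single most
stable gene serves as the qPCR-style normalizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CountMatrix
from .exceptions import ConfigError, DesignError, SelectionError

__all__ = ["StabilityTable", "stability_screen", "pick_normalizer"]


@dataclass
class StabilityTable:
    """Per-gene stability statistics, sorted ascending by CV%.

    ``frame`` columns: mean, sd, cv_pct, n_samples, selected. Genes with mean
    0 are excluded (their CV is undefined), not given CV 0. Ties on CV are
    broken by descending mean, then lexical gene id.
    """

    frame: pd.DataFrame
    threshold_pct: float

    @property
    def selected_ids(self) -> tuple[str, ...]:
        return tuple(self.frame.index[self.frame["selected"]])


def stability_screen(expression, threshold_pct: float = 10.0,
                     z_scale_datasets: list[list[str]] | None = None) -> StabilityTable:
    """Compute per-gene CV% over all columns and flag genes below threshold.

    ``expression`` is a CountMatrix or a plain DataFrame (genes × columns);
    at least 3 columns are required. ``z_scale_datasets`` optionally lists
    column groups (one per source dataset) whose columns are rescaled to unit
    mean before concatenation, for screens that pool heterogeneous datasets;
    the default is plain concatenation.
    """
    df = expression.data if isinstance(expression, CountMatrix) else pd.DataFrame(expression)
    df = df.astype(float)
    if df.shape[1] < 3:
        raise DesignError("stability screen needs >=3 columns")
    if threshold_pct <= 0:
        raise ConfigError("threshold must be positive")
    if z_scale_datasets:
        df = df.copy()
        for cols in z_scale_datasets:
            block = df[cols]
            scale = block.to_numpy().mean()
            if scale > 0:
                df[cols] = block / scale
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    keep = mean > 0
    mean, sd = mean[keep], sd[keep]
    cv = 100.0 * sd / mean
    frame = pd.DataFrame(
        {
            "mean": mean,
            "sd": sd,
            "cv_pct": cv,
            "n_samples": df.shape[1],
            "selected": cv < threshold_pct,
        }
    )
    frame = (
        frame.assign(_id=frame.index.astype(str))
        .sort_values(by=["cv_pct", "mean", "_id"], ascending=[True, False, True])
        .drop(columns="_id")
    )
    return StabilityTable(frame=frame, threshold_pct=float(threshold_pct))


def pick_normalizer(table: StabilityTable) -> str:
    """The minimum-CV gene under the table's tie-breaking; order-invariant."""
    finite = table.frame[np.isfinite(table.frame["cv_pct"])]
    if finite.empty:
        raise SelectionError("no gene with a finite CV to pick from")
    return str(finite.index[0])
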