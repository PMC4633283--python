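"""Reproducibility and bias metrics for comparing correction schemes.

Three metrics summarize how well a correction restores agreement between
biological replicates and removes systematic between-condition shifts:

* ``replicate_slope`` — ordinary least squares through the origin of one
  replicate on another, over events expressed in both; 1 means perfect
  proportional reproducibility.
* ``ratio_deviation`` — mean of (max/min − 1) × 100 over co-expressed events
  in a replicate pair; 0 means identical replicates. This is the sensitive
  deviation-from-perfect-reproducibility measure.
* ``inter_treatment_bias`` — mean |log2| ratio of reference-gene means
  between two samples; ≈0 when the data carry no between-condition bias on
  genes expected to be stable.

``compare_schemes`` evaluates a list of correction schemes on one raw matrix
and emits one report per scheme, sorted best-first by ratio deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .data import Comparison, CountMatrix
from .exceptions import DesignError, DiagnosticError
from .normalization import apply_scheme

__all__ = [
    "BiasReport",
    "replicate_slope",
    "ratio_deviation",
    "inter_treatment_bias",
    "inter_replicate_sd",
    "compare_schemes",
    "plot_replicates",
]


@dataclass(frozen=True)
class BiasReport:
    scheme: str
    slope_mean: float
    ratio_deviation_pct: float
    inter_replicate_sd: float
    inter_treatment_bias: float
    n_events_used: int

    def __post_init__(self) -> None:
        if self.ratio_deviation_pct < 0:
            raise DiagnosticError("ratio deviation cannot be negative")


def _replicate_pairs(matrix: CountMatrix, sample: str) -> list[tuple[np.ndarray, np.ndarray]]:
    vals = matrix.sample_values(sample)
    r = vals.shape[1]
    if r < 2:
        raise DesignError(f"sample {sample!r} needs >=2 replicates")
    return [(vals[:, i], vals[:, j]) for i, j in combinations(range(r), 2)]


def replicate_slope(matrix: CountMatrix, sample: str) -> float:
    """Mean through-the-origin OLS slope over all replicate pairs of a sample.

    For each pair (i < j), the slope of replicate j regressed on replicate i
    is the closed form sum(x*y)/sum(x^2) over events expressed (> 0) in both.
    """
    slopes = []
    for x, y in _replicate_pairs(matrix, sample):
        mask = (x > 0) & (y > 0)
        if not mask.any():
            raise DiagnosticError(f"no co-expressed events in a replicate pair of {sample!r}")
        xm, ym = x[mask], y[mask]
        slopes.append(float((xm * ym).sum() / (xm * xm).sum()))
    return float(np.mean(slopes))


def ratio_deviation(matrix: CountMatrix, sample: str, floor: float = 0.0) -> float:
    """Average percent deviation of replicate ratios from 1.

    Over events with both values > ``floor`` in a replicate pair, the ratio
    is oriented max/min so the deviation (ratio − 1) × 100 is non-negative;
    the mean is pooled over all qualifying (event, pair) observations.
    """
    devs = []
    for x, y in _replicate_pairs(matrix, sample):
        mask = (x > floor) & (y > floor)
        if mask.any():
            hi = np.maximum(x[mask], y[mask])
            lo = np.minimum(x[mask], y[mask])
            devs.append((hi / lo - 1.0) * 100.0)
    if not devs:
        raise DiagnosticError(f"no qualifying events for ratio deviation in {sample!r}")
    return float(np.concatenate(devs).mean())


def inter_treatment_bias(matrix: CountMatrix, reference_ids, pair: Comparison) -> float:
    """Mean |log2| ratio of reference-gene sample means between two samples."""
    pair.validate(matrix.design)
    reference_ids = list(reference_ids)
    ref = matrix.data.loc[reference_ids]
    num = ref[list(matrix.design.columns_of(pair.numerator))].to_numpy(float).mean(axis=1)
    den = ref[list(matrix.design.columns_of(pair.denominator))].to_numpy(float).mean(axis=1)
    if (num <= 0).any() or (den <= 0).any():
        raise DiagnosticError("reference gene with zero mean in a compared sample")
    return float(np.abs(np.log2(num / den)).mean())


def inter_replicate_sd(matrix: CountMatrix, reference_ids) -> float:
    """Standard deviation of reference-gene log2 inter-replicate ratios,
    pooled over all samples and replicate pairs."""
    ratios = []
    ref = matrix.data.loc[list(reference_ids)]
    for sample in matrix.design.samples:
        vals = ref[list(matrix.design.columns_of(sample))].to_numpy(float)
        for i, j in combinations(range(vals.shape[1]), 2):
            mask = (vals[:, i] > 0) & (vals[:, j] > 0)
            if mask.any():
                ratios.append(np.log2(vals[mask, i] / vals[mask, j]))
    if not ratios:
        raise DiagnosticError("no usable reference-gene replicate ratios")
    pooled = np.concatenate(ratios)
    return float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0


def compare_schemes(raw: CountMatrix, schemes, reference_ids) -> list[BiasReport]:
    """One BiasReport per scheme, computed on the scheme-corrected matrix.

    Slope and ratio deviation are averaged over all design samples;
    inter-treatment bias over all unordered sample pairs. Reports are sorted
    ascending by ratio deviation (best reproducibility first).
    """
    schemes = list(schemes)
    if not schemes:
        raise DesignError("compare_schemes requires >=1 scheme")
    reference_ids = list(reference_ids)
    reports = []
    for scheme in schemes:
        corrected = apply_scheme(raw, scheme)
        slopes = [replicate_slope(corrected, s) for s in corrected.design.samples]
        devs = [ratio_deviation(corrected, s) for s in corrected.design.samples]
        biases = [
            inter_treatment_bias(corrected, reference_ids, Comparison(a, b))
            for a, b in combinations(corrected.design.samples, 2)
        ]
        n_used = int((corrected.data.to_numpy(float) > 0).all(axis=1).sum())
        reports.append(
            BiasReport(
                scheme=scheme.label,
                slope_mean=float(np.mean(slopes)),
                ratio_deviation_pct=float(np.mean(devs)),
                inter_replicate_sd=inter_replicate_sd(corrected, reference_ids),
                inter_treatment_bias=float(np.mean(biases)),
                n_events_used=n_used,
            )
        )
    return sorted(reports, key=lambda r: r.ratio_deviation_pct)


def plot_replicates(matrix: CountMatrix, sample: str, path) -> None:
    """Scatter plots of all replicate pairs of one sample (log-log)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pairs = _replicate_pairs(matrix, sample)
    fig, axes = plt.subplots(1, len(pairs), figsize=(4 * len(pairs), 4), squeeze=False)
    for ax, (x, y) in zip(axes[0], pairs):
        mask = (x > 0) & (y > 0)
        ax.loglog(x[mask], y[mask], ".", ms=2, alpha=0.5)
        lims = [min(x[mask].min(), y[mask].min()), max(x[mask].max(), y[mask].max())]
        ax.plot(lims, lims, "k--", lw=0.8)
        ax.set_xlabel("replicate i")
        ax.set_ylabel("replicate j")
    fig.suptitle(f"{sample} ({matrix.unit})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
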