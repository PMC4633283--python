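"""Negative-binomial exact-test differential expression with one global
dispersion.

Model
-----
Counts of an event in replicate libraries of one condition are modelled as
negative binomial with mean mu and variance mu + phi * mu**2; a single
dispersion phi is shared by every event ("common" or global dispersion).
After equalizing library sizes to their geometric mean, the replicate sums
of the two compared groups, S_A and S_B, are NB with means n_A*mu, n_B*mu and
dispersions phi/n_A, phi/n_B under the null of no change. Conditional on the
total t = S_A + S_B the distribution of S_A is free of mu:

    P(S_A = y | t)  proportional to  C(y + r_A - 1, y) * C(t - y + r_B - 1, t - y)

with r_g = n_g / phi; at phi = 0 this is Binomial(t, n_A / (n_A + n_B)).
The two-sided p-value sums the probabilities of all outcomes no more likely
than the observed one (minimum-likelihood method; tail doubling is available
as an alternative).

The global dispersion is estimated by maximizing the conditional
log-likelihood of the within-sample replicate counts given their sums — the
same conditioning trick, applied per sample — summed over events and
samples. A method-of-moments fallback solves pooled variance = mu + phi*mu**2.

Workflow
--------
``NBExactTestModel`` wraps a raw count matrix; ``fit(comparison)`` runs the
full per-comparison pipeline — RPM conversion for filtering, the low-quantity
filter, the exact test on (equalized) raw counts, Benjamini–Hochberg
adjustment over tested events only, and Induced/Repressed classification —
and returns a ``DEResults`` with per-event estimates and a ``summary()``.
The module-level functions expose each step individually.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp

from .data import Comparison, CountMatrix
from .exceptions import ConfigError, DesignError, EstimationError
from .normalization import rpm_normalize

__all__ = [
    "DEConfig",
    "DispersionEstimate",
    "low_quantity_filter",
    "equalize_library_sizes",
    "estimate_global_dispersion",
    "nb_exact_test",
    "bh_adjust",
    "run_comparison",
    "NBExactTestModel",
    "DEResults",
]

INDUCED = "Induced"
REPRESSED = "Repressed"
NOT_SIGNIFICANT = "NotSignificant"


@dataclass(frozen=True)
class DEConfig:
    """Thresholds of the DE pipeline.

    min_rpm
        Low-quantity filter threshold theta, in reads per million (default 5).
    min_fold_change
        Minimum fold change for significance calls (default 2).
    alpha
        Adjusted-p cut-off (default 0.01).
    adjust_method
        Multiple-testing correction; only Benjamini–Hochberg ("BH").
    two_sided
        "minlik" sums all conditional outcomes no more likely than the
        observed one; "doubling" doubles the smaller exact tail.
    filter_scope
        "whole": keep an event when at least one sample satisfies both the
        full-replicate-mean and the every-pair-mean clause (default).
        "mean_both": require the full mean in *both* samples plus the
        pairwise clause in at least one — the alternative reading of an
        ambiguous rule.
    """

    min_rpm: float = 5.0
    min_fold_change: float = 2.0
    alpha: float = 0.01
    adjust_method: str = "BH"
    two_sided: str = "minlik"
    filter_scope: str = "whole"

    def __post_init__(self) -> None:
        if self.min_rpm < 0:
            raise ConfigError("min_rpm must be >= 0")
        if self.min_fold_change < 1:
            raise ConfigError("min_fold_change must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.adjust_method != "BH":
            raise ConfigError("only BH adjustment is supported")
        if self.two_sided not in ("minlik", "doubling"):
            raise ConfigError("two_sided must be 'minlik' or 'doubling'")
        if self.filter_scope not in ("whole", "mean_both"):
            raise ConfigError("filter_scope must be 'whole' or 'mean_both'")


@dataclass(frozen=True)
class DispersionEstimate:
    phi: float
    method: str
    n_events_used: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.phi) or self.phi < 0:
            raise EstimationError(f"dispersion must be finite and >= 0, got {self.phi}")


# ---------------------------------------------------------------------------
# Low-quantity filter
# ---------------------------------------------------------------------------

def _subset_mean_ok(vals: np.ndarray, theta: float) -> np.ndarray:
    """Per-event flag: full mean >= theta AND every leave-one-out subset mean
    >= theta. With 3 replicates the leave-one-out subsets are exactly the
    three two-replicate combinations."""
    r = vals.shape[1]
    full_ok = vals.mean(axis=1) >= theta
    if r < 2:
        return full_ok
    totals = vals.sum(axis=1, keepdims=True)
    loo_means = (totals - vals) / (r - 1)
    return full_ok & (loo_means >= theta).all(axis=1)


def low_quantity_filter(matrix: CountMatrix, pair: Comparison, theta: float = 5.0,
                        scope: str = "whole") -> pd.Index:
    """Event ids kept for testing in one comparison.

    Operates on RPM. An event is kept when, in at least one of the two
    compared samples, the full-replicate mean and every leave-one-out
    (r−1)-replicate mean are all >= theta; with 3 replicates the (r−1)-subsets
    are the three possible two-replicate combinations. This guards against a
    single outlier replicate carrying the whole average. ``scope="mean_both"``
    additionally requires the full mean in both samples.
    """
    if matrix.unit != "RPM":
        raise ConfigError(f"low_quantity_filter expects RPM, got unit={matrix.unit!r}")
    pair.validate(matrix.design)
    a = matrix.sample_values(pair.numerator)
    b = matrix.sample_values(pair.denominator)
    if scope == "whole":
        keep = _subset_mean_ok(a, theta) | _subset_mean_ok(b, theta)
    else:
        pairwise = _pair_clause(a, theta) | _pair_clause(b, theta)
        keep = pairwise & (a.mean(axis=1) >= theta) & (b.mean(axis=1) >= theta)
    return matrix.event_ids[keep]


def _pair_clause(vals: np.ndarray, theta: float) -> np.ndarray:
    r = vals.shape[1]
    if r < 2:
        return vals.mean(axis=1) >= theta
    totals = vals.sum(axis=1, keepdims=True)
    loo_means = (totals - vals) / (r - 1)
    return (loo_means >= theta).all(axis=1)


# ---------------------------------------------------------------------------
# Library-size equalization
# ---------------------------------------------------------------------------

def equalize_library_sizes(counts: np.ndarray, library_sizes: np.ndarray) -> np.ndarray:
    """Scale raw counts column-wise to the geometric-mean library size and
    round to integer pseudo-counts.

    This is a linear approximation of a quantile adjustment: after scaling,
    every column behaves as if sequenced to the same depth, which the exact
    test's equal-mean null requires.
    """
    library_sizes = np.asarray(library_sizes, float)
    if np.any(library_sizes <= 0):
        raise DesignError("library sizes must be strictly positive")
    target = np.exp(np.mean(np.log(library_sizes)))
    return np.rint(np.asarray(counts, float) * (target / library_sizes)).astype(np.int64)


# ---------------------------------------------------------------------------
# Global dispersion
# ---------------------------------------------------------------------------

def _conditional_loglik(phi: float, groups: list[np.ndarray]) -> float:
    """Sum over samples/events of log P(replicate counts | their sum) under
    NB(phi) with equal library sizes. Free of the per-event means."""
    r = 1.0 / phi
    ll = 0.0
    for y in groups:
        n = y.shape[1]
        z = y.sum(axis=1)
        ll += float(
            (gammaln(y + r).sum(axis=1) - n * gammaln(r) - gammaln(y + 1).sum(axis=1)
             - gammaln(z + n * r) + gammaln(n * r) + gammaln(z + 1)).sum()
        )
    return ll


def estimate_global_dispersion(matrix: CountMatrix, method: str = "cml",
                               max_events: int | None = None) -> DispersionEstimate:
    """One dispersion phi shared by all events.

    ``cml`` (default) maximizes the summed conditional log-likelihood of
    within-sample counts given their totals, after equalizing library sizes
    to their geometric mean. ``moments`` solves pooled within-sample
    variance = mu + phi * mu**2 by least squares. phi is clamped to >= 0.
    """
    if matrix.unit != "raw":
        raise ConfigError("dispersion is estimated from raw counts")
    design = matrix.design
    if design.replicates < 2:
        raise EstimationError("need a sample with >=2 replicates")
    lib = matrix.mapped_totals.to_numpy(float)
    eq = equalize_library_sizes(matrix.data.to_numpy(float), lib)
    cols = list(matrix.columns)
    groups = []
    used = 0
    for sample in design.samples:
        idx = [cols.index(c) for c in design.columns_of(sample)]
        y = eq[:, idx]
        y = y[y.sum(axis=1) > 0]
        if max_events is not None and len(y) > max_events:
            y = y[:max_events]
        if len(y):
            groups.append(y)
            used = max(used, len(y))
    if not groups:
        raise EstimationError("no events with non-zero counts in any replicated sample")
    n_used = sum(len(g) for g in groups)

    if method == "moments":
        # per-event solutions of var = mu + phi mu^2, averaged; low-mean
        # events are excluded because their ratio is dominated by shot noise
        m = np.concatenate([g.mean(axis=1) for g in groups])
        v = np.concatenate([g.var(axis=1, ddof=1) for g in groups])
        ok = m >= 1.0
        if not ok.any():
            raise EstimationError("no events with mean count >= 1 for moments estimate")
        phi = max(0.0, float(((v[ok] - m[ok]) / m[ok] ** 2).mean()))
        return DispersionEstimate(phi=phi, method="moments", n_events_used=int(ok.sum()))
    if method != "cml":
        raise ConfigError(f"unknown dispersion method {method!r}")

    def neg_ll(log_phi: float) -> float:
        return -_conditional_loglik(float(np.exp(log_phi)), groups)

    res = minimize_scalar(neg_ll, bounds=(np.log(1e-8), np.log(50.0)), method="bounded",
                          options={"xatol": 1e-6})
    phi = float(np.exp(res.x))
    if phi <= 2e-8:  # boundary: no measurable overdispersion
        phi = 0.0
    return DispersionEstimate(phi=phi, method="cml", n_events_used=n_used)


# ---------------------------------------------------------------------------
# Exact test
# ---------------------------------------------------------------------------

def _conditional_log_pmf(t: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """log P(S_A = y | S_A + S_B = t) for y = 0..t."""
    # grouped so that for n_a == n_b the array is exactly palindromic in
    # floating point: swapping the groups then negates p-value asymmetry
    y = np.arange(t + 1, dtype=float)
    if phi == 0.0:
        # Poisson limit: Binomial(t, n_a / (n_a + n_b))
        logit = np.log(n_a) - np.log(n_b)
        logw = -(gammaln(y + 1) + gammaln(t - y + 1)) + y * logit
    else:
        ra, rb = n_a / phi, n_b / phi
        logw = (gammaln(y + ra) - gammaln(y + 1)) + (gammaln(t - y + rb) - gammaln(t - y + 1))
    return logw - logsumexp(logw)


def _pvalue_from_sums(s_a: int, t: int, n_a: int, n_b: int, phi: float,
                      method: str = "minlik") -> float:
    if t == 0:
        return 1.0
    logp = _conditional_log_pmf(t, n_a, n_b, phi)
    obs = logp[s_a]
    if method == "doubling":
        lower = float(np.exp(logsumexp(logp[: s_a + 1])))
        upper = float(np.exp(logsumexp(logp[s_a:])))
        return float(min(1.0, 2.0 * min(lower, upper)))
    mask = logp <= obs + 1e-12  # tolerate float ties at symmetric outcomes
    return float(min(1.0, np.exp(logsumexp(logp[mask]))))


def nb_exact_test(counts_num, counts_den, phi: float,
                  library_sizes=None, method: str = "minlik") -> float:
    """Two-sided exact p-value for one event.

    ``counts_num``/``counts_den`` are the replicate counts of the two groups
    (raw; equalized and rounded here when ``library_sizes`` — ordered
    numerator replicates then denominator replicates — is given). p = 1 for
    a perfectly symmetric outcome; at phi = 0 the test reduces to the
    binomial-conditioned Poisson exact test.
    """
    if phi < 0:
        raise ConfigError("dispersion must be >= 0")
    a = np.asarray(counts_num, float)
    b = np.asarray(counts_den, float)
    if library_sizes is not None:
        both = equalize_library_sizes(np.concatenate([a, b])[None, :],
                                      np.asarray(library_sizes, float))[0]
        a, b = both[: len(a)], both[len(a):]
    s_a = int(round(a.sum()))
    s_b = int(round(b.sum()))
    return _pvalue_from_sums(s_a, s_a + s_b, len(a), len(b), phi, method)


# ---------------------------------------------------------------------------
# Benjamini–Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D array")
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

@dataclass
class DEResults:
    """Per-event differential-expression results for one comparison.

    ``frame`` is indexed by event id with columns: mean_rpm_num,
    mean_rpm_den, log2_fc, pvalue, padj, status, filtered. Filtered events
    carry no class (empty status) and NaN p-values.
    """

    frame: pd.DataFrame
    comparison: Comparison
    level: str
    config: DEConfig
    dispersion: DispersionEstimate

    @property
    def tested(self) -> pd.DataFrame:
        return self.frame[~self.frame["filtered"]]

    @property
    def n_tested(self) -> int:
        return int((~self.frame["filtered"]).sum())

    @property
    def n_induced(self) -> int:
        return int((self.frame["status"] == INDUCED).sum())

    @property
    def n_repressed(self) -> int:
        return int((self.frame["status"] == REPRESSED).sum())

    @property
    def n_de(self) -> int:
        return self.n_induced + self.n_repressed

    @property
    def de_ids(self) -> pd.Index:
        return self.frame.index[self.frame["status"].isin((INDUCED, REPRESSED))]

    def status_of(self, event_id: str) -> str:
        if event_id not in self.frame.index:
            return NOT_SIGNIFICANT
        s = self.frame.at[event_id, "status"]
        return s if s in (INDUCED, REPRESSED) else NOT_SIGNIFICANT

    def summary(self) -> str:
        c = self.config
        lines = [
            f"NB exact test — {self.level}-level comparison {self.comparison.name}",
            "=" * 58,
            f"events                {len(self.frame):>8d}",
            f"tested (RPM filter)   {self.n_tested:>8d}   (theta = {c.min_rpm} RPM)",
            f"global dispersion     {self.dispersion.phi:>8.4f}   ({self.dispersion.method})",
            f"DE (adj p <= {c.alpha:g}, "
            f"|FC| >= {c.min_fold_change:g})  {self.n_de:>5d}",
            f"  induced             {self.n_induced:>8d}",
            f"  repressed           {self.n_repressed:>8d}",
        ]
        return "\n".join(lines)

    def write_tsv(self, path, *, extra_header=None) -> None:
        from . import __version__

        with open(path, "w") as fh:
            fh.write(f"#switchgrain\tversion={__version__}\tlevel={self.level}"
                     f"\tcomparison={self.comparison.name}\tphi={self.dispersion.phi!r}"
                     f"\talpha={self.config.alpha}\tmin_fold_change={self.config.min_fold_change}"
                     f"\tmin_rpm={self.config.min_rpm}\n")
            for k, v in (extra_header or {}).items():
                fh.write(f"#{k}\t{v}\n")
            self.frame.to_csv(fh, sep="\t", index_label="event_id")


class NBExactTestModel:
    """Common-dispersion NB exact-test model over a raw count matrix.

    Examples
    --------
    >>> model = NBExactTestModel(raw_counts)          # doctest: +SKIP
    >>> res = model.fit(Comparison("24Fe", "UT"))     # doctest: +SKIP
    >>> print(res.summary())                          # doctest: +SKIP
    """

    def __init__(self, counts: CountMatrix, config: DEConfig | None = None):
        if counts.unit != "raw":
            raise ConfigError("NBExactTestModel expects raw counts")
        self.counts = counts
        self.config = config or DEConfig()
        self._rpm = rpm_normalize(counts)
        self._dispersion: DispersionEstimate | None = None

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, mapped_totals, design=None,
                       level: str = "gene", config: DEConfig | None = None) -> "NBExactTestModel":
        from .data import StudyDesign

        design = design or StudyDesign()
        totals = pd.Series(mapped_totals)
        if not isinstance(totals.index, pd.Index) or totals.index.dtype != object:
            totals = pd.Series(np.asarray(mapped_totals, float), index=frame.columns)
        matrix = CountMatrix(data=frame, mapped_totals=totals, design=design, level=level)
        return cls(matrix, config)

    @property
    def dispersion(self) -> DispersionEstimate:
        if self._dispersion is None:
            self._dispersion = estimate_global_dispersion(self.counts)
        return self._dispersion

    def fit(self, comparison: Comparison | str,
            dispersion: DispersionEstimate | float | None = None) -> DEResults:
        if isinstance(comparison, str):
            comparison = Comparison.from_name(comparison)
        comparison.validate(self.counts.design)
        if dispersion is None:
            disp = self.dispersion
        elif isinstance(dispersion, DispersionEstimate):
            disp = dispersion
        else:
            disp = DispersionEstimate(phi=float(dispersion), method="fixed", n_events_used=0)
        cfg = self.config

        kept = low_quantity_filter(self._rpm, comparison, cfg.min_rpm, cfg.filter_scope)
        design = self.counts.design
        num_cols = list(design.columns_of(comparison.numerator))
        den_cols = list(design.columns_of(comparison.denominator))

        rpm_num = self._rpm.data[num_cols].mean(axis=1)
        rpm_den = self._rpm.data[den_cols].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            log2_fc = np.log2(rpm_num / rpm_den)
        log2_fc = pd.Series(log2_fc, index=self._rpm.event_ids)
        log2_fc[(rpm_num == 0) & (rpm_den == 0)] = 0.0

        raw = self.counts.data
        lib = self.counts.mapped_totals
        eq = equalize_library_sizes(
            raw[num_cols + den_cols].to_numpy(float),
            lib[num_cols + den_cols].to_numpy(float),
        )
        eq = pd.DataFrame(eq, index=raw.index, columns=num_cols + den_cols)
        n_a, n_b = len(num_cols), len(den_cols)
        s_a = eq.loc[kept, num_cols].sum(axis=1).to_numpy(np.int64)
        t = s_a + eq.loc[kept, den_cols].sum(axis=1).to_numpy(np.int64)
        pvals = np.array([
            _pvalue_from_sums(int(sa), int(tt), n_a, n_b, disp.phi, cfg.two_sided)
            for sa, tt in zip(s_a, t)
        ]) if len(kept) else np.array([])
        padj = bh_adjust(pvals)

        frame = pd.DataFrame(
            {
                "mean_rpm_num": rpm_num,
                "mean_rpm_den": rpm_den,
                "log2_fc": log2_fc,
                "pvalue": np.nan,
                "padj": np.nan,
                "status": "",
                "filtered": True,
            },
            index=self._rpm.event_ids,
        )
        frame.loc[kept, "pvalue"] = pvals
        frame.loc[kept, "padj"] = padj
        frame.loc[kept, "filtered"] = False
        min_lfc = np.log2(cfg.min_fold_change)
        sig = frame["padj"] <= cfg.alpha
        frame.loc[kept, "status"] = NOT_SIGNIFICANT
        frame.loc[sig & (frame["log2_fc"] >= min_lfc) & ~frame["filtered"], "status"] = INDUCED
        frame.loc[sig & (frame["log2_fc"] <= -min_lfc) & ~frame["filtered"], "status"] = REPRESSED
        return DEResults(frame=frame, comparison=comparison, level=self.counts.level,
                         config=cfg, dispersion=disp)


def run_comparison(raw: CountMatrix, pair: Comparison, config: DEConfig | None = None,
                   dispersion: DispersionEstimate | float | None = None) -> DEResults:
    """Functional wrapper: fit the common-dispersion exact-test model for one
    comparison of a raw count matrix."""
    return NBExactTestModel(raw, config).fit(pair, dispersion)
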