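"""Count-correction schemes: RPM, reference-gene based, and sequential.

Two corrections are compared in the study this package serves:

* genome-wide correction to reads per million exonic mapped reads (RPM),
  ``value * 1e6 / mapped_total``;
* reference-gene based correction, where each column is divided by the
  geometric mean of a reference-gene panel in that column, anchored to the
  grand geometric mean over columns so the correction has no net scale
  effect. With a single reference gene this reduces to single-gene
  correction; the panel generalizes it for robustness to one aberrant
  reference.

Schemes can be composed sequentially.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import CountMatrix
from .exceptions import ConfigError, CorrectionError

__all__ = ["CorrectionScheme", "rpm_normalize", "reference_correct", "apply_scheme"]

_KINDS = ("none", "rpm", "reference_gene", "sequential")


@dataclass(frozen=True)
class CorrectionScheme:
    kind: str = "none"
    reference_ids: tuple[str, ...] = ()
    order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigError(f"unknown correction kind {self.kind!r}")
        object.__setattr__(self, "reference_ids", tuple(self.reference_ids))
        object.__setattr__(self, "order", tuple(self.order))
        if self.kind == "reference_gene" and not self.reference_ids:
            raise ConfigError("reference_gene correction requires >=1 reference id")
        if self.kind == "sequential":
            if not self.order:
                raise ConfigError("sequential correction requires a non-empty order")
            for k in self.order:
                if k not in ("rpm", "reference_gene", "none"):
                    raise ConfigError(f"sequential order may not contain {k!r}")
            if "reference_gene" in self.order and not self.reference_ids:
                raise ConfigError("sequential order with reference_gene requires reference ids")

    @property
    def label(self) -> str:
        if self.kind == "sequential":
            return "sequential[" + "+".join(self.order) + "]"
        return self.kind


def rpm_normalize(matrix: CountMatrix) -> CountMatrix:
    """Reads-per-million correction: ``value * 1e6 / mapped_total(column)``.

    Requires raw counts. When the matrix covers all exonic events of each
    column (mapped totals equal column sums), every RPM column sums to 1e6.
    """
    if matrix.unit != "raw":
        raise ConfigError(f"rpm_normalize expects raw counts, got unit={matrix.unit!r}")
    totals = matrix.mapped_totals.to_numpy(float)
    if not np.all(totals > 0):
        raise ZeroDivisionError("zero mapped_total")
    data = matrix.data * (1e6 / totals)
    return matrix.with_data(data, unit="RPM")


def reference_correct(matrix: CountMatrix, reference_ids) -> CountMatrix:
    """Divide each column by its reference-panel geometric mean, anchored to
    the grand geometric mean over columns.

    Every reference gene must be present and strictly positive in every
    column. Noise-free references become exactly constant across columns, and
    applying the correction twice equals applying it once (all factors are 1
    on the second pass, up to rounding).
    """
    reference_ids = list(reference_ids)
    if not reference_ids:
        raise ConfigError("reference_correct requires >=1 reference id")
    missing = [r for r in reference_ids if r not in matrix.event_ids]
    if missing:
        raise CorrectionError(f"reference gene(s) not in matrix: {missing}")
    ref = matrix.data.loc[reference_ids]
    zero = ref <= 0
    if zero.any().any():
        gene = zero.index[zero.any(axis=1)][0]
        col = zero.columns[zero.loc[gene]][0]
        raise CorrectionError(f"reference gene {gene!r} has zero quantity in column {col!r}")
    log_ref = np.log(ref.to_numpy(float))
    col_factors = np.exp(log_ref.mean(axis=0))        # per-column geometric mean
    grand = np.exp(np.log(col_factors).mean())        # anchor: no net scale effect
    factors = col_factors / grand
    data = matrix.data / factors
    return matrix.with_data(data, unit="corrected")


def apply_scheme(matrix: CountMatrix, scheme: CorrectionScheme) -> CountMatrix:
    """Apply a correction scheme; ``none`` is the identity, ``sequential``
    composes its ``order`` left to right."""
    if scheme.kind == "none":
        return matrix.copy()
    if scheme.kind == "rpm":
        return rpm_normalize(matrix)
    if scheme.kind == "reference_gene":
        return reference_correct(matrix, scheme.reference_ids)
    out = matrix
    for kind in scheme.order:
        if kind == "rpm":
            out = rpm_normalize(out)
        elif kind == "reference_gene":
            out = reference_correct(out, scheme.reference_ids)
    return out
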