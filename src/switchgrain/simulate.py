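"""Synthetic RNA-seq count generator emulating the 5-sample x 3-replicate
transfer-cell study design.

The generator produces a transcript-level and a gene-level count matrix, the
matching gene/transcript/protein annotation, and a ground-truth object, so
every downstream stage (normalization, diagnostics, reference-gene selection,
DE testing, switch classification) can be exercised without external data.

Generative model
----------------
* Each gene g has an expected expression level in reads per million (RPM):
  reference genes log-uniform in ``reference_range``, a configurable
  low-expression tail in ``low_expression_range`` (to exercise the filter
  boundary) and the remaining genes log-uniform in ``expression_range``.
* Isoform proportions within a gene follow a symmetric Dirichlet.
* Replicate counts of transcript i in column c are negative binomial with
  mean  rpm_i(sample(c)) * depth / 1e6 * bias(c)  and variance
  mu + phi * mu**2; reference genes get their own, smaller dispersion.
* Induced/repressed genes have their mean multiplied by ``fold_change_de``
  (respectively its reciprocal) in one randomly chosen affected (treated)
  sample; switching genes move ``switch_shift`` proportion-mass points from
  the dominant isoform to the second isoform in the affected sample, leaving
  the gene total unchanged in expectation. A switch is only meaningful when
  the dominant isoform actually carries the mass being moved, so switch
  genes are conditioned on a dominant major isoform (proportion at least
  ``switch_shift`` + 0.02) — the configuration in which annotated isoform
  switches are observable at all.
* Gene counts are the exact sums of their member transcript counts.

Two bookkeeping modes for the RPM denominator:

* subset mode (default): ``mapped_totals = depth`` exactly — the matrix
  models a highly expressed subset of a transcriptome whose exonic total is
  given externally, so nominal RPM values (and hence the 5-RPM filter
  boundary) are exact. The generator rejects configurations whose expected
  RPM budget exceeds one million.
* ``full_transcriptome=True``: ``mapped_totals`` are the realized column
  sums — the matrix *is* the whole transcriptome and RPM columns sum to 1e6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .data import DEFAULT_SAMPLES, Comparison, CountMatrix, GeneModel, StudyDesign
from .exceptions import ConfigError, DesignError

__all__ = ["SimulationConfig", "SyntheticTruth", "SyntheticDataset",
           "simulate_dataset", "inject_bias"]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study design where it is stated (5 samples, 3
    biological replicates, 18 reference genes, exonic depth 17.2 million
    reads per column); the remaining knobs are desk-scale choices documented
    in the methods note.
    """

    n_genes: int = 1200
    isoforms_per_gene: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.55, 2: 0.25, 3: 0.12, 4: 0.05, 5: 0.03})
    replicates: int = 3
    samples: tuple[str, ...] = DEFAULT_SAMPLES
    depth: float = 17_200_000.0
    dispersion: float = 0.1
    fraction_induced: float = 0.02
    fraction_repressed: float = 0.02
    fraction_switch: float = 0.02
    fold_change_de: float = 4.0
    switch_shift: float = 0.8
    fraction_identical_protein_pairs: float = 0.05
    fraction_utr_only_pairs: float = 0.05
    fraction_noncoding: float = 0.05
    n_reference_genes: int = 18
    reference_dispersion: float = 0.005
    bias_factors: tuple[float, ...] | None = None
    low_expression_fraction: float = 0.2
    expression_range: tuple[float, float] = (5.0, 5000.0)
    low_expression_range: tuple[float, float] = (0.5, 5.0)
    reference_range: tuple[float, float] = (200.0, 2000.0)
    dirichlet_concentration: float = 1.0
    full_transcriptome: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.fraction_induced, self.fraction_repressed, self.fraction_switch)
        if any(not 0 <= f <= 1 for f in fr) or sum(fr) > 1:
            raise ConfigError("role fractions must lie in [0,1] and jointly sum to <= 1")
        for f in (self.fraction_identical_protein_pairs, self.fraction_utr_only_pairs,
                  self.fraction_noncoding, self.low_expression_fraction):
            if not 0 <= f <= 1:
                raise ConfigError("fractions must lie in [0, 1]")
        if (self.fraction_identical_protein_pairs + self.fraction_utr_only_pairs) > 1:
            raise ConfigError("protein-pair fractions jointly exceed 1")
        if self.dispersion < 0 or self.reference_dispersion < 0:
            raise ConfigError("dispersions must be >= 0")
        if self.fold_change_de <= 1:
            raise ConfigError("fold_change_de must be > 1")
        if not 0 < self.switch_shift <= 0.95:
            raise ConfigError("switch_shift must lie in (0, 0.95]: the dominant isoform "
                              "must be able to hold the moved mass")
        if self.n_reference_genes >= self.n_genes:
            raise ConfigError("n_reference_genes must be smaller than n_genes")
        probs = np.array(list(self.isoforms_per_gene.values()), float)
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0, atol=1e-6):
            raise ConfigError("isoforms_per_gene must be a distribution over {1..5}")
        if any(k < 1 or k > 5 for k in self.isoforms_per_gene):
            raise ConfigError("isoform counts must lie in 1..5")

    @property
    def design(self) -> StudyDesign:
        return StudyDesign(samples=self.samples, replicates=self.replicates)


class SyntheticDataset(NamedTuple):
    gene_counts: CountMatrix
    transcript_counts: CountMatrix
    gene_model: GeneModel
    truth: "SyntheticTruth"


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset.

    ``gene_roles`` (indexed by gene id) columns: role (none / induced /
    repressed / switch / reference), affected_sample, base_rpm, n_isoforms,
    pair_kind (distinct / utr_only / identical_protein / noncoding_pair /
    none), donor_tx, recipient_tx. ``tx_gene`` maps transcript to gene.
    True per-comparison classes and switch tables are derived on demand.
    """

    gene_roles: pd.DataFrame
    tx_gene: pd.Series
    reference_ids: tuple[str, ...]
    bias_factors: pd.Series
    config: SimulationConfig

    def true_class(self, level: str, pair: Comparison) -> pd.Series:
        """Per-event true class (Induced / Repressed / Null) for one
        comparison. Switching genes are Null at gene level (the total is
        conserved); their donor/recipient transcripts carry the switch
        direction at transcript level."""
        roles = self.gene_roles
        gene_cls = pd.Series("Null", index=roles.index, dtype=object)
        for sign, role in ((1, "induced"), (-1, "repressed")):
            sel = roles["role"] == role
            up = sel & (roles["affected_sample"] == pair.numerator)
            down = sel & (roles["affected_sample"] == pair.denominator)
            gene_cls[up] = "Induced" if sign > 0 else "Repressed"
            gene_cls[down] = "Repressed" if sign > 0 else "Induced"
        if level == "gene":
            return gene_cls
        tx_cls = gene_cls.reindex(self.tx_gene.to_numpy()).to_numpy(dtype=object)
        tx_cls = pd.Series(tx_cls, index=self.tx_gene.index, dtype=object)
        sw = roles[roles["role"] == "switch"]
        for gene, row in sw.iterrows():
            a = row["affected_sample"]
            if a == pair.numerator:
                donor_cls, recip_cls = "Repressed", "Induced"
            elif a == pair.denominator:
                donor_cls, recip_cls = "Induced", "Repressed"
            else:
                continue
            tx_cls[row["donor_tx"]] = donor_cls
            tx_cls[row["recipient_tx"]] = recip_cls
        return tx_cls

    def switch_truth(self, pair: Comparison) -> pd.DataFrame:
        """Per-gene switch flag and class for one comparison. Classes follow
        the protein contrast of the swapped pair: distinct coding proteins →
        IS1; identical protein sequences (shared CDS or convergent CDSs) →
        IS2 with identical_protein=True; a non-coding member → unclassified."""
        roles = self.gene_roles
        affected = roles["affected_sample"].isin([pair.numerator, pair.denominator])
        is_switch = (roles["role"] == "switch") & affected
        cls = pd.Series("none", index=roles.index, dtype=object)
        identical = pd.Series(False, index=roles.index)
        kind = roles["pair_kind"]
        cls[is_switch & (kind == "distinct")] = "IS1"
        cls[is_switch & kind.isin(["utr_only", "identical_protein"])] = "IS2"
        cls[is_switch & (kind == "noncoding_pair")] = "unclassified"
        identical[is_switch & kind.isin(["utr_only", "identical_protein"])] = True
        return pd.DataFrame({"is_switch": is_switch, "switch_class": cls,
                             "identical_protein": identical,
                             "pair_kind": kind.where(is_switch, "none")})


def _draw_loguniform(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mean mu, variance mu + phi mu^2); phi = 0 falls back to Poisson."""
    out = np.zeros(mean.shape, dtype=np.int64)
    pois = phi == 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    over = ~pois
    if over.any():
        r = 1.0 / phi[over]
        mu = mean[over]
        p = r / (r + mu)
        out[over] = rng.negative_binomial(r, p)
    return out


def _random_proteins(rng: np.random.Generator, n: int) -> list[str]:
    lengths = rng.integers(30, 81, size=n)
    return ["".join(_AA[rng.integers(0, 20, size=ln)]) for ln in lengths]


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate one dataset; reproducible for a fixed ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    design = config.design
    columns = design.columns
    n_col = len(columns)
    n = config.n_genes

    gene_ids = np.array([f"G{i:05d}" for i in range(n)])
    perm = rng.permutation(n)
    ref_idx = np.sort(perm[: config.n_reference_genes])
    is_ref = np.zeros(n, bool)
    is_ref[ref_idx] = True

    # isoform counts (references are single-isoform)
    ks = np.array(sorted(config.isoforms_per_gene))
    kp = np.array([config.isoforms_per_gene[k] for k in ks], float)
    kp = kp / kp.sum()
    n_iso = rng.choice(ks, size=n, p=kp)
    n_iso[is_ref] = 1

    # roles
    pool = perm[config.n_reference_genes:]
    n_ind = int(round(config.fraction_induced * n))
    n_rep = int(round(config.fraction_repressed * n))
    n_sw = int(round(config.fraction_switch * n))
    role = np.full(n, "none", dtype=object)
    role[is_ref] = "reference"
    role[pool[:n_ind]] = "induced"
    role[pool[n_ind:n_ind + n_rep]] = "repressed"
    multi_pool = pool[n_ind + n_rep:]
    multi_pool = multi_pool[n_iso[multi_pool] >= 2]
    if len(multi_pool) < n_sw:
        raise ConfigError(
            f"fraction_switch requires {n_sw} multi-isoform genes but only "
            f"{len(multi_pool)} are available; raise multi-isoform probability")
    sw_idx = multi_pool[:n_sw]
    role[sw_idx] = "switch"

    treated = [s for s in config.samples[1:]] or list(config.samples)
    affected = np.full(n, "", dtype=object)
    de_or_sw = np.isin(role, ["induced", "repressed", "switch"])
    affected[de_or_sw] = rng.choice(treated, size=int(de_or_sw.sum()))

    # expression levels (RPM)
    base_rpm = _draw_loguniform(rng, *config.expression_range, n)
    n_low = int(round(config.low_expression_fraction * n))
    low_idx = rng.choice(np.flatnonzero(~is_ref), size=min(n_low, int((~is_ref).sum())),
                         replace=False)
    base_rpm[low_idx] = _draw_loguniform(rng, *config.low_expression_range, len(low_idx))
    base_rpm[is_ref] = _draw_loguniform(rng, *config.reference_range, int(is_ref.sum()))

    if not config.full_transcriptome:
        budget = float(base_rpm.sum()) + \
            config.fold_change_de * float(base_rpm[role == "induced"].sum())
        if budget > 1e6:
            raise ConfigError(
                f"expected RPM budget {budget:.3g} exceeds 1e6; in subset mode lower "
                f"n_genes or the expression range, or set full_transcriptome=True")

    # isoform proportions; switch pair = the two highest-proportion isoforms
    props: list[np.ndarray] = []
    top2: list[tuple[int, int]] = []
    for k in n_iso:
        p = rng.dirichlet(np.full(k, config.dirichlet_concentration))
        order = np.argsort(p)[::-1]
        props.append(p)
        top2.append((int(order[0]), int(order[1])) if k >= 2 else (0, 0))
    # switch genes need a dominant major isoform able to donate the moved mass
    major_floor = config.switch_shift + 0.02
    for gi in sw_idx:
        p = props[gi]
        a, _ = top2[gi]
        if p[a] < major_floor:
            scale = (1.0 - major_floor) / (1.0 - p[a])
            p *= scale
            p[a] = major_floor

    # transcript table
    tx_ids, tx_gene_idx, tx_iso_idx = [], [], []
    for gi, k in enumerate(n_iso):
        for j in range(k):
            tx_ids.append(f"{gene_ids[gi]}.t{j + 1}")
            tx_gene_idx.append(gi)
            tx_iso_idx.append(j)
    tx_ids = np.array(tx_ids)
    tx_gene_idx = np.array(tx_gene_idx)
    tx_iso_idx = np.array(tx_iso_idx)
    n_tx = len(tx_ids)
    # transcripts are laid out gene-major, isoform-minor: isoform j of gene
    # gi sits at tx_offset[gi] + j
    tx_offset = np.concatenate([[0], np.cumsum(n_iso)[:-1]])
    base_prop_tx = np.concatenate(props)

    # annotation: protein-pair kinds among multi-isoform genes
    multi = np.flatnonzero(n_iso >= 2)
    rng_multi = rng.permutation(multi)
    n_utr = int(round(config.fraction_utr_only_pairs * len(multi)))
    n_idp = int(round(config.fraction_identical_protein_pairs * len(multi)))
    utr_set = set(rng_multi[:n_utr].tolist())
    idp_set = set(rng_multi[n_utr:n_utr + n_idp].tolist())

    seqs = _random_proteins(rng, n_tx)
    protein_id = np.array([f"P_{t}" for t in tx_ids], dtype=object)
    pair_kind = np.full(n, "none", dtype=object)
    for gi in multi:
        a, b = top2[gi]
        ta = tx_offset[gi] + a
        tb = tx_offset[gi] + b
        if gi in utr_set:
            # same CDS, transcripts differ only in untranslated regions
            protein_id[tb] = protein_id[ta]
            seqs[tb] = seqs[ta]
            pair_kind[gi] = "utr_only"
        elif gi in idp_set:
            # different CDSs converging on one amino-acid sequence
            seqs[tb] = seqs[ta]
            pair_kind[gi] = "identical_protein"
        else:
            pair_kind[gi] = "distinct"

    # non-coding transcripts (never members of a same-protein pair)
    protected = np.zeros(n_tx, bool)
    for gi in utr_set | idp_set:
        a, b = top2[gi]
        protected[tx_offset[gi] + a] = True
        protected[tx_offset[gi] + b] = True
    eligible = np.flatnonzero(~protected)
    n_nc = int(round(config.fraction_noncoding * n_tx))
    nc_idx = rng.choice(eligible, size=min(n_nc, len(eligible)), replace=False)
    noncoding = np.zeros(n_tx, bool)
    noncoding[nc_idx] = True
    # a switch pair containing a non-coding member is an unclassifiable pair
    for gi in multi:
        if pair_kind[gi] == "distinct":
            a, b = top2[gi]
            if noncoding[tx_offset[gi] + a] or noncoding[tx_offset[gi] + b]:
                pair_kind[gi] = "noncoding_pair"

    records = []
    for ti in range(n_tx):
        gi = tx_gene_idx[ti]
        if noncoding[ti]:
            records.append((gene_ids[gi], tx_ids[ti], None, None))
        else:
            records.append((gene_ids[gi], tx_ids[ti], str(protein_id[ti]), seqs[ti]))
    gene_model = GeneModel.from_records(records)

    # per-sample transcript mean RPM
    bias = np.ones(n_col) if config.bias_factors is None else np.asarray(config.bias_factors, float)
    if len(bias) != n_col:
        raise DesignError("bias_factors must supply one factor per column")
    if np.any(bias <= 0):
        raise DesignError("bias factors must be strictly positive")

    tx_mean_rpm = np.empty((n_tx, len(config.samples)))
    for si, sample in enumerate(config.samples):
        gene_rpm = base_rpm.copy()
        sel = (role == "induced") & (affected == sample)
        gene_rpm[sel] *= config.fold_change_de
        sel = (role == "repressed") & (affected == sample)
        gene_rpm[sel] /= config.fold_change_de
        prop_col = base_prop_tx.copy()
        for gi in sw_idx:
            if affected[gi] == sample:
                a, b = top2[gi]
                ia, ib = tx_offset[gi] + a, tx_offset[gi] + b
                prop_col[ia] -= config.switch_shift
                prop_col[ib] += config.switch_shift
        tx_mean_rpm[:, si] = gene_rpm[tx_gene_idx] * prop_col

    sample_of_col = np.array([design.sample_of(c) for c in columns])
    sample_index = np.array([list(config.samples).index(s) for s in sample_of_col])
    mean_counts = tx_mean_rpm[:, sample_index] * (config.depth / 1e6) * bias[None, :]
    phi_tx = np.where(is_ref[tx_gene_idx], config.reference_dispersion,
                      config.dispersion)[:, None] * np.ones((1, n_col))
    tx_counts = _nb_draw(rng, mean_counts, phi_tx)

    gene_counts = np.zeros((n, n_col), dtype=np.int64)
    np.add.at(gene_counts, tx_gene_idx, tx_counts)

    if config.full_transcriptome:
        totals = tx_counts.sum(axis=0).astype(float)
        totals[totals <= 0] = 1.0
    else:
        totals = np.full(n_col, float(config.depth))
    totals = pd.Series(totals, index=list(columns))

    tx_matrix = CountMatrix(
        data=pd.DataFrame(tx_counts.astype(float), index=tx_ids, columns=list(columns)),
        mapped_totals=totals, design=design, level="transcript", unit="raw")
    gene_matrix = CountMatrix(
        data=pd.DataFrame(gene_counts.astype(float), index=gene_ids, columns=list(columns)),
        mapped_totals=totals.copy(), design=design, level="gene", unit="raw")

    donor_tx = np.full(n, "", dtype=object)
    recipient_tx = np.full(n, "", dtype=object)
    for gi in sw_idx:
        a, b = top2[gi]
        donor_tx[gi] = str(tx_ids[tx_offset[gi] + a])
        recipient_tx[gi] = str(tx_ids[tx_offset[gi] + b])

    truth = SyntheticTruth(
        gene_roles=pd.DataFrame(
            {
                "role": role,
                "affected_sample": affected,
                "base_rpm": base_rpm,
                "n_isoforms": n_iso,
                "pair_kind": pair_kind,
                "donor_tx": donor_tx,
                "recipient_tx": recipient_tx,
            },
            index=gene_ids,
        ),
        tx_gene=pd.Series(gene_ids[tx_gene_idx], index=tx_ids),
        reference_ids=tuple(gene_ids[ref_idx]),
        bias_factors=pd.Series(bias, index=list(columns)),
        config=config,
    )
    return SyntheticDataset(gene_matrix, tx_matrix, gene_model, truth)


def inject_bias(matrix: CountMatrix, factors: Sequence[float]) -> CountMatrix:
    """Multiply each column (and its mapped total) by a positive factor."""
    factors = np.asarray(factors, float)
    if factors.shape != (len(matrix.columns),):
        raise DesignError(f"expected {len(matrix.columns)} bias factors, got {factors.shape}")
    if np.any(factors <= 0):
        raise DesignError("bias factors must be strictly positive")
    data = matrix.data * factors
    totals = matrix.mapped_totals * factors
    return matrix.with_data(data, mapped_totals=totals)
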