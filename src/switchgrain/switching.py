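"""Isoform-switch detection, classification and dual-level summaries.

A gene is *switching* in a comparison when at least one of its transcripts
is significantly induced and another significantly repressed in that same
comparison. The switch is classified by the protein contrast of its up/down
transcript pairs:

* **IS1** — at least one up/down pair encodes distinct protein isoforms;
* **IS2** — all coding up/down pairs encode the identical protein sequence
  (the transcripts differ only in untranslated regions or carry convergent
  coding sequences), flagged ``identical_protein``;
* **unclassified** — the only pairs involve non-coding transcripts, so the
  protein contrast is undefined.

Each switching gene receives exactly one class, so IS1 + IS2 + unclassified
partitions the switch calls. Summaries follow the study's comparison-table
layout (tested / DE / Rep / Ind / IS / IS1 / IS2 per level) together with
the cross-level discordance: the fraction of DE events at one level with no
significant counterpart at the other.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product

from .data import NON_CODING, GeneModel
from .detest import DEResults, INDUCED, NOT_SIGNIFICANT, REPRESSED
from .exceptions import AnnotationError, DesignError

__all__ = [
    "SwitchCall",
    "ComparisonSummary",
    "detect_switches",
    "classify_switch",
    "summarize",
    "cross_level_discordance",
    "identical_protein_genes",
]


@dataclass(frozen=True)
class SwitchCall:
    gene_id: str
    comparison: str
    up_transcripts: tuple[str, ...]
    down_transcripts: tuple[str, ...]
    switch_class: str = "unclassified"
    identical_protein: bool = False
    gene_level_class: str = NOT_SIGNIFICANT

    def __post_init__(self) -> None:
        if not self.up_transcripts or not self.down_transcripts:
            raise DesignError("a switch call needs induced and repressed transcripts")
        if set(self.up_transcripts) & set(self.down_transcripts):
            raise DesignError("up and down transcript sets must be disjoint")


@dataclass(frozen=True)
class ComparisonSummary:
    level: str
    comparison: str
    tested: int
    de: int
    rep: int
    ind: int
    is_total: int
    is1: int
    is2: int
    discordant_fraction: float

    def __post_init__(self) -> None:
        if self.de != self.rep + self.ind:
            raise DesignError("summary invariant violated: DE must equal Rep + Ind")
        if not 0.0 <= self.discordant_fraction <= 1.0:
            raise DesignError("discordant fraction must lie in [0, 1]")


def detect_switches(transcript_results: DEResults, model: GeneModel,
                    gene_results: DEResults | None = None) -> list[SwitchCall]:
    """Find genes with opposite-direction significant transcripts.

    Every classified transcript must be annotated; the calls come back
    classified (see :func:`classify_switch`) and, when ``gene_results`` is
    given, carry the gene's own DE class.
    """
    by_gene: dict[str, tuple[list[str], list[str]]] = {}
    frame = transcript_results.frame
    for tx in frame.index[frame["status"].isin((INDUCED, REPRESSED))]:
        gene = model.gene_of.get(tx)
        if gene is None:
            raise AnnotationError(f"DE transcript {tx!r} absent from the gene model")
        up, down = by_gene.setdefault(gene, ([], []))
        (up if frame.at[tx, "status"] == INDUCED else down).append(tx)
    calls = []
    for gene in sorted(by_gene):
        up, down = by_gene[gene]
        if up and down:
            call = SwitchCall(
                gene_id=gene,
                comparison=transcript_results.comparison.name,
                up_transcripts=tuple(up),
                down_transcripts=tuple(down),
                gene_level_class=(gene_results.status_of(gene)
                                  if gene_results is not None else NOT_SIGNIFICANT),
            )
            calls.append(classify_switch(call, model))
    return calls


def classify_switch(call: SwitchCall, model: GeneModel) -> SwitchCall:
    """Assign IS1 / IS2 / unclassified from the up/down protein contrasts.

    All (up, down) transcript pairs are examined. Any pair of distinct
    coding proteins makes the gene IS1; coding pairs that all share one
    protein sequence make it IS2; pairs involving non-coding transcripts
    contribute nothing. ``identical_protein`` is set whenever at least one
    pair codes identical proteins.
    """
    any_distinct = False
    any_identical = False
    any_coding_pair = False
    for up_tx, down_tx in product(call.up_transcripts, call.down_transcripts):
        p_up = model.protein_id(up_tx)
        p_down = model.protein_id(down_tx)
        if NON_CODING in (p_up, p_down):
            continue
        any_coding_pair = True
        if p_up == p_down:
            any_identical = True
        else:
            any_distinct = True
    if any_distinct:
        cls = "IS1"
    elif any_coding_pair:
        cls = "IS2"
    else:
        cls = "unclassified"
    return replace(call, switch_class=cls, identical_protein=any_identical)


def identical_protein_genes(calls) -> list[str]:
    """Genes whose switch involves transcripts coding identical proteins —
    reported separately from the IS2 column, mirroring the study's own
    distinct list."""
    return sorted({c.gene_id for c in calls if c.identical_protein})


def cross_level_discordance(gene_results: DEResults, transcript_results: DEResults,
                            model: GeneModel) -> tuple[float, float]:
    """(gene-side, transcript-side) discordance between levels.

    Gene side: fraction of DE genes with no DE member transcript (a gene
    whose transcripts were all filtered at the transcript level counts as
    discordant). Transcript side: fraction of DE transcripts whose parent
    gene is not DE. Both are 0 when the corresponding DE set is empty.
    """
    if gene_results.comparison != transcript_results.comparison:
        raise DesignError("gene and transcript results compare different samples")
    de_genes = set(gene_results.de_ids)
    de_txs = set(transcript_results.de_ids)
    genes_with_de_tx = {model.gene_of[tx] for tx in de_txs if tx in model.gene_of}
    gene_side = (sum(1 for g in de_genes if g not in genes_with_de_tx) / len(de_genes)
                 if de_genes else 0.0)
    tx_side = (sum(1 for tx in de_txs if model.gene_of.get(tx) not in de_genes) / len(de_txs)
               if de_txs else 0.0)
    return float(gene_side), float(tx_side)


def summarize(gene_results: DEResults, transcript_results: DEResults,
              switches, model: GeneModel) -> tuple[ComparisonSummary, ComparisonSummary]:
    """(gene-level, transcript-level) comparison summaries.

    Transcript-level IS counts the DE transcripts belonging to switching
    genes, partitioned into IS1/IS2 by the gene's switch class; gene-level
    IS counts switching genes that are themselves gene-level DE.
    """
    if gene_results.comparison != transcript_results.comparison:
        raise DesignError("gene and transcript results compare different samples")
    switches = list(switches)
    class_of = {c.gene_id: c.switch_class for c in switches}
    switching_genes = set(class_of)
    gene_disc, tx_disc = cross_level_discordance(gene_results, transcript_results, model)

    de_genes = set(gene_results.de_ids)
    is_genes = sorted(de_genes & switching_genes)
    gene_summary = ComparisonSummary(
        level="gene",
        comparison=gene_results.comparison.name,
        tested=gene_results.n_tested,
        de=gene_results.n_de,
        rep=gene_results.n_repressed,
        ind=gene_results.n_induced,
        is_total=len(is_genes),
        is1=sum(1 for g in is_genes if class_of[g] == "IS1"),
        is2=sum(1 for g in is_genes if class_of[g] == "IS2"),
        discordant_fraction=gene_disc,
    )
    de_txs = list(transcript_results.de_ids)
    tx_in_switching = [tx for tx in de_txs if model.gene_of.get(tx) in switching_genes]
    tx_summary = ComparisonSummary(
        level="transcript",
        comparison=transcript_results.comparison.name,
        tested=transcript_results.n_tested,
        de=transcript_results.n_de,
        rep=transcript_results.n_repressed,
        ind=transcript_results.n_induced,
        is_total=len(tx_in_switching),
        is1=sum(1 for tx in tx_in_switching if class_of[model.gene_of[tx]] == "IS1"),
        is2=sum(1 for tx in tx_in_switching if class_of[model.gene_of[tx]] == "IS2"),
        discordant_fraction=tx_disc,
    )
    return gene_summary, tx_summary
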