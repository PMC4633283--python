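"""Core containers: study design, count matrices, comparisons and gene models.

The containers are deliberately thin wrappers around pandas objects. All
structural invariants (unique event ids, non-negative quantities, strictly
positive mapped totals, design/column consistency) are enforced at
construction time, never deferred to the analysis stages.

Count matrices exist at one *level* (``gene`` or ``transcript``) and carry a
*unit* flag (``raw``, ``RPM`` or ``corrected``) so downstream operations can
state their preconditions. ``mapped_totals`` is the per-column number of
exonic mapped reads used as the reads-per-million denominator; it is taken as
given input and may exceed the column sum when the matrix models only a
subset of the transcriptome.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import AnnotationError, DesignError, FormatError

__all__ = [
    "DEFAULT_SAMPLES",
    "NON_CODING",
    "StudyDesign",
    "Comparison",
    "DEFAULT_COMPARISONS",
    "CountMatrix",
    "read_counts",
    "GeneModel",
    "read_annotation",
    "read_proteins",
]

#: The five samples of the barley transfer-cell study: untreated, and 6 h /
#: 24 h after foliar iron and zinc applications.
DEFAULT_SAMPLES: tuple[str, ...] = ("UT", "6Fe", "6Zn", "24Fe", "24Zn")

#: Sentinel protein id for transcripts without a coding sequence.
NON_CODING = "non-coding"

_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class StudyDesign:
    """An ordered set of samples, each with the same number of replicates.

    Columns are labelled ``{sample}_{replicate}`` with replicates numbered
    from 1, e.g. ``UT_1 ... UT_3 6Fe_1 ...``.
    """

    samples: tuple[str, ...] = DEFAULT_SAMPLES
    replicates: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        if len(set(self.samples)) != len(self.samples) or not self.samples:
            raise DesignError(f"sample labels must be unique and non-empty: {self.samples}")
        if self.replicates < 1:
            raise DesignError("replicates must be a positive integer")

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(f"{s}_{r}" for s in self.samples for r in range(1, self.replicates + 1))

    def columns_of(self, sample: str) -> tuple[str, ...]:
        if sample not in self.samples:
            raise DesignError(f"unknown sample {sample!r}")
        return tuple(f"{sample}_{r}" for r in range(1, self.replicates + 1))

    def sample_of(self, column: str) -> str:
        sample, _, rep = column.rpartition("_")
        if sample not in self.samples or not rep.isdigit():
            raise DesignError(f"column {column!r} does not belong to the design")
        return sample


@dataclass(frozen=True)
class Comparison:
    """A two-group contrast ``numerator/denominator`` between design samples."""

    numerator: str
    denominator: str

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise DesignError("comparison numerator and denominator must differ")

    @property
    def name(self) -> str:
        return f"{self.numerator}/{self.denominator}"

    @classmethod
    def from_name(cls, name: str) -> "Comparison":
        num, sep, den = name.partition("/")
        if not sep or not num or not den:
            raise DesignError(f"comparison name must look like 'A/B', got {name!r}")
        return cls(num, den)

    def validate(self, design: StudyDesign) -> "Comparison":
        for s in (self.numerator, self.denominator):
            if s not in design.samples:
                raise DesignError(f"comparison sample {s!r} not in design {design.samples}")
        return self

    def swapped(self) -> "Comparison":
        return Comparison(self.denominator, self.numerator)


#: The study's four preferred contrasts; 6 h samples are only compared with
#: each other because they were collected at a different time of day.
DEFAULT_COMPARISONS: tuple[Comparison, ...] = (
    Comparison("24Fe", "UT"),
    Comparison("24Zn", "UT"),
    Comparison("6Zn", "6Fe"),
    Comparison("24Zn", "24Fe"),
)


@dataclass
class CountMatrix:
    """Event-by-column quantities at one level, plus per-column mapped totals.

    Parameters
    ----------
    data
        DataFrame with unique event ids as index and the design's columns in
        design order. Values may be fractional (correction schemes reuse the
        type); the ``unit`` flag tracks interpretation.
    mapped_totals
        Per-column total exonic mapped reads, strictly positive.
    design
        The study design the columns belong to.
    level
        ``"gene"`` or ``"transcript"``.
    unit
        ``"raw"``, ``"RPM"`` or ``"corrected"``.
    """

    data: pd.DataFrame
    mapped_totals: pd.Series
    design: StudyDesign = field(default_factory=StudyDesign)
    level: str = "gene"
    unit: str = "raw"

    def __post_init__(self) -> None:
        if self.level not in ("gene", "transcript"):
            raise FormatError(f"level must be 'gene' or 'transcript', got {self.level!r}")
        if self.unit not in ("raw", "RPM", "corrected"):
            raise FormatError(f"unknown unit {self.unit!r}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate event ids: {dupes[:5]}")
        expected = list(self.design.columns)
        if sorted(self.data.columns) != sorted(expected):
            raise DesignError(
                f"matrix columns {list(self.data.columns)} do not match design columns {expected}"
            )
        # canonical column order
        self.data = self.data.loc[:, expected].astype(float)
        if self.data.isna().any().any():
            raise FormatError("missing cells are an error, not zero")
        if (self.data.to_numpy() < 0).any():
            raise FormatError("negative quantities are not allowed")
        totals = pd.Series(self.mapped_totals, dtype=float)
        if sorted(totals.index) != sorted(expected):
            raise DesignError("mapped_totals must cover exactly the design columns")
        totals = totals.loc[expected]
        if not (totals > 0).all():
            raise FormatError("mapped_totals must be strictly positive")
        self.mapped_totals = totals

    # -- convenience ------------------------------------------------------
    @property
    def event_ids(self) -> pd.Index:
        return self.data.index

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    def sample_values(self, sample: str) -> np.ndarray:
        """(n_events, replicates) array for one sample."""
        return self.data[list(self.design.columns_of(sample))].to_numpy(float)

    def with_data(self, data: pd.DataFrame, *, unit: str | None = None,
                  mapped_totals: pd.Series | None = None) -> "CountMatrix":
        return CountMatrix(
            data=data,
            mapped_totals=self.mapped_totals if mapped_totals is None else mapped_totals,
            design=self.design,
            level=self.level,
            unit=self.unit if unit is None else unit,
        )

    def copy(self) -> "CountMatrix":
        return self.with_data(self.data.copy())

    # -- IO ---------------------------------------------------------------
    def write_tsv(self, path: str | Path, *, extra_header: Mapping[str, str] | None = None) -> None:
        """Write as TSV with '#'-prefixed metadata lines (level, unit, totals)."""
        path = Path(path)
        with path.open("w") as fh:
            from . import __version__

            fh.write(f"#switchgrain\tversion={__version__}\tlevel={self.level}\tunit={self.unit}\n")
            for key, val in (extra_header or {}).items():
                fh.write(f"#{key}\t{val}\n")
            fh.write("#mapped_totals\t" + "\t".join(repr(float(v)) for v in self.mapped_totals) + "\n")
            fh.write("event_id\t" + "\t".join(self.columns) + "\n")
            for eid, row in zip(self.data.index, self.data.to_numpy()):
                fh.write(str(eid) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_counts(
    path: str | Path,
    design: StudyDesign,
    level: str = "gene",
    mapped_totals: Sequence[float] | Mapping[str, float] | None = None,
) -> CountMatrix:
    """Read a TSV count matrix (header = column ids, first column = event id).

    ``mapped_totals`` may be given explicitly or embedded in a
    ``#mapped_totals`` comment line as written by :meth:`CountMatrix.write_tsv`.
    Row order is preserved; missing cells, duplicate ids and negative values
    are format errors; a column set differing from the design is a design
    error.
    """
    path = Path(path)
    unit = "raw"
    header_totals: list[float] | None = None
    body_lines: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            fields = line[1:].split("\t")
            if fields[0] == "mapped_totals":
                header_totals = [float(v) for v in fields[1:]]
            elif fields[0] == "switchgrain":
                for f in fields[1:]:
                    if f.startswith("unit="):
                        unit = f[5:]
        elif line.strip():
            body_lines.append(line)
    if not body_lines:
        raise FormatError(f"{path}: no header row")
    df = pd.read_csv(io.StringIO("\n".join(body_lines)), sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate event id "
                          f"{df.index[df.index.duplicated()][0]!r}")
    if df.isna().any().any():
        raise FormatError(f"{path}: missing cells are an error, not zero")

    if mapped_totals is None:
        if header_totals is None:
            raise FormatError(f"{path}: no #mapped_totals line and none supplied")
        if len(header_totals) != len(df.columns):
            raise FormatError(f"{path}: #mapped_totals length mismatch")
        totals = pd.Series(header_totals, index=df.columns)
    elif isinstance(mapped_totals, Mapping):
        totals = pd.Series(dict(mapped_totals), dtype=float)
    else:
        vals = list(mapped_totals)
        if len(vals) != len(df.columns):
            raise FormatError("mapped_totals length mismatch with file columns")
        totals = pd.Series(vals, index=df.columns, dtype=float)
    return CountMatrix(data=df, mapped_totals=totals, design=design, level=level, unit=unit)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """Gene → transcript → protein mapping with protein sequences.

    Protein ids are canonicalized so that identical amino-acid sequences share
    one id (the lexicographically smallest of the merged ids): identity of
    sequence is identity of id. Transcripts without a coding sequence map to
    the sentinel :data:`NON_CODING`.
    """

    transcripts_of: dict[str, tuple[str, ...]]
    protein_of: dict[str, str]
    protein_seq: dict[str, str]
    gene_of: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        gene_of: dict[str, str] = {}
        for gene, txs in self.transcripts_of.items():
            self.transcripts_of[gene] = tuple(txs)
            for tx in txs:
                if tx in gene_of:
                    raise FormatError(f"transcript {tx!r} assigned to two genes "
                                      f"({gene_of[tx]!r} and {gene!r})")
                gene_of[tx] = gene
        self.gene_of = gene_of
        for tx in self.protein_of:
            if tx not in gene_of:
                raise FormatError(f"protein mapping for unknown transcript {tx!r}")
        # merge identical sequences to one canonical id
        by_seq: dict[str, str] = {}
        for pid in sorted(self.protein_seq):
            seq = self.protein_seq[pid]
            by_seq.setdefault(seq, pid)
        canonical = {pid: by_seq[seq] for pid, seq in self.protein_seq.items()}
        self.protein_seq = {by_seq[seq]: seq for seq in by_seq}
        self.protein_of = {
            tx: canonical.get(pid, pid) for tx, pid in self.protein_of.items()
        }

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.transcripts_of)

    def protein_id(self, transcript: str) -> str:
        if transcript not in self.gene_of:
            raise AnnotationError(f"transcript {transcript!r} absent from the gene model")
        return self.protein_of.get(transcript, NON_CODING)

    def is_coding(self, transcript: str) -> bool:
        return self.protein_id(transcript) != NON_CODING

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str | None, str | None]]
    ) -> "GeneModel":
        """Build from ``(gene_id, transcript_id, protein_id, protein_seq)``
        rows; ``protein_id`` of None/empty/"non-coding" marks a non-coding
        transcript."""
        transcripts_of: dict[str, list[str]] = {}
        protein_of: dict[str, str] = {}
        protein_seq: dict[str, str] = {}
        seen_tx: dict[str, str] = {}
        for gene, tx, pid, seq in records:
            if tx in seen_tx and seen_tx[tx] != gene:
                raise FormatError(f"transcript {tx!r} assigned to two genes")
            seen_tx[tx] = gene
            transcripts_of.setdefault(gene, [])
            if tx not in transcripts_of[gene]:
                transcripts_of[gene].append(tx)
            if not pid or pid == NON_CODING:
                protein_of[tx] = NON_CODING
            else:
                protein_of[tx] = pid
                if seq:
                    seq = seq.upper()
                    if pid in protein_seq and protein_seq[pid] != seq:
                        raise FormatError(f"protein id {pid!r} with two different sequences")
                    protein_seq[pid] = seq
        return cls(
            transcripts_of={g: tuple(t) for g, t in transcripts_of.items()},
            protein_of=protein_of,
            protein_seq=protein_seq,
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneModel":
        """Flat annotation dialect: columns gene_id, transcript_id,
        protein_id, protein_seq (tab-separated, '#' comments allowed)."""
        rows = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "gene_id":
                continue
            parts += [""] * (4 - len(parts))
            rows.append((parts[0], parts[1], parts[2] or None, parts[3] or None))
        return cls.from_records(rows)

    @classmethod
    def from_gtf(cls, path: str | Path,
                 protein_seqs: Mapping[str, str] | None = None) -> "GeneModel":
        """Build from a GTF/GFF file (via gffutils).

        Transcripts carrying at least one CDS feature are coding; their
        protein id is the CDS ``protein_id`` attribute when present, else the
        transcript id. ``protein_seqs`` optionally supplies amino-acid
        sequences keyed by protein id so identical sequences can be merged.
        """
        import gffutils

        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
        tx_gene: dict[str, str] = {}
        tx_protein: dict[str, str] = {}
        for feat in db.all_features():
            attrs = feat.attributes
            if "transcript_id" not in attrs or "gene_id" not in attrs:
                continue
            tx = attrs["transcript_id"][0]
            gene = attrs["gene_id"][0]
            if tx in tx_gene and tx_gene[tx] != gene:
                raise FormatError(f"transcript {tx!r} assigned to two genes")
            tx_gene[tx] = gene
            if feat.featuretype == "CDS":
                pid = attrs["protein_id"][0] if "protein_id" in attrs else tx
                tx_protein.setdefault(tx, pid)
        records = []
        seqs = dict(protein_seqs or {})
        for tx, gene in tx_gene.items():
            pid = tx_protein.get(tx)
            records.append((gene, tx, pid, seqs.get(pid) if pid else None))
        return cls.from_records(records)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("gene_id\ttranscript_id\tprotein_id\tprotein_seq\n")
            for gene, txs in self.transcripts_of.items():
                for tx in txs:
                    pid = self.protein_of.get(tx, NON_CODING)
                    seq = self.protein_seq.get(pid, "")
                    fh.write(f"{gene}\t{tx}\t{pid}\t{seq}\n")


def read_annotation(path: str | Path,
                    protein_seqs: Mapping[str, str] | None = None) -> GeneModel:
    """Read a gene model from a flat TSV or a GTF/GFF file (by extension)."""
    suffix = Path(path).suffix.lower()
    if suffix in (".gtf", ".gff", ".gff3"):
        return GeneModel.from_gtf(path, protein_seqs)
    return GeneModel.from_tsv(path)


def read_proteins(path: str | Path) -> dict[str, str]:
    """Read protein sequences from FASTA into ``{id: uppercase sequence}``.

    Accepts the 20 standard residues plus X (a trailing stop ``*`` is
    stripped); anything else, and duplicate record ids, are format errors.
    """
    from Bio import SeqIO

    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate protein record {rec.id!r}")
        seq = str(rec.seq).upper().rstrip("*")
        bad = set(seq) - _AA_ALPHABET
        if bad:
            raise FormatError(f"illegal residue(s) {sorted(bad)} in {rec.id!r}")
        out[rec.id] = seq
    return out
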