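"""End-to-end orchestration: simulate/load → normalize → diagnose → DE at
both levels → switch classification → summaries, with a manifest that
suffices to re-run the pipeline identically.

Outputs are plain TSV files with '#'-prefixed metadata headers; identical
config + seed produce byte-identical bundles (no timestamps are recorded).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

from .data import (DEFAULT_COMPARISONS, Comparison, StudyDesign, read_annotation,
                   read_counts)
from .detest import DEConfig, NBExactTestModel
from .diagnostics import compare_schemes
from .exceptions import ConfigError
from .normalization import CorrectionScheme
from .refgenes import stability_screen
from .simulate import SimulationConfig, simulate_dataset
from .switching import detect_switches, identical_protein_genes, summarize

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("switchgrain")


@dataclass
class RunConfig:
    design: StudyDesign = field(default_factory=StudyDesign)
    comparisons: tuple[Comparison, ...] = DEFAULT_COMPARISONS
    scheme: CorrectionScheme = field(default_factory=lambda: CorrectionScheme("rpm"))
    de: DEConfig = field(default_factory=DEConfig)
    simulation: SimulationConfig | None = None
    gene_counts_path: str | None = None
    transcript_counts_path: str | None = None
    annotation_path: str | None = None
    outdir: str = "switchgrain_out"
    seed: int = 0
    log_level: str = "INFO"
    refgene_threshold_pct: float = 10.0

    def __post_init__(self) -> None:
        for c in self.comparisons:
            c.validate(self.design)
        have_inputs = self.gene_counts_path and self.transcript_counts_path and self.annotation_path
        if self.simulation is None and not have_inputs:
            raise ConfigError("provide either a simulation block or all three input paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        design = StudyDesign(**raw.get("design", {}))
        comparisons = tuple(
            Comparison.from_name(c).validate(design)
            for c in raw.get("comparisons", [c.name for c in DEFAULT_COMPARISONS])
        )
        scheme = CorrectionScheme(**raw.get("scheme", {"kind": "rpm"}))
        de = DEConfig(**raw.get("de", {}))
        sim = raw.get("simulation")
        sim_cfg = None
        if sim is not None:
            sim = dict(sim)
            if "isoforms_per_gene" in sim:
                sim["isoforms_per_gene"] = {int(k): float(v)
                                            for k, v in sim["isoforms_per_gene"].items()}
            sim_cfg = SimulationConfig(samples=design.samples,
                                       replicates=design.replicates, **sim)
        return cls(
            design=design, comparisons=comparisons, scheme=scheme, de=de,
            simulation=sim_cfg,
            gene_counts_path=raw.get("gene_counts"),
            transcript_counts_path=raw.get("transcript_counts"),
            annotation_path=raw.get("annotation"),
            outdir=raw.get("outdir", "switchgrain_out"),
            seed=int(raw.get("seed", 0)),
            log_level=raw.get("log_level", "INFO"),
            refgene_threshold_pct=float(raw.get("refgene_threshold_pct", 10.0)),
        )


def _slug(name: str) -> str:
    return name.replace("/", "_vs_")


def _write_summaries(path: Path, summaries, header: str) -> None:
    with path.open("w") as fh:
        fh.write(header)
        fh.write("level\tcomparison\ttested\tDE\tRep\tInd\tIS\tIS1\tIS2\tdiscordant_fraction\n")
        for s in summaries:
            fh.write(f"{s.level}\t{s.comparison}\t{s.tested}\t{s.de}\t{s.rep}\t{s.ind}"
                     f"\t{s.is_total}\t{s.is1}\t{s.is2}\t{s.discordant_fraction:.4f}\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the output bundle; returns a manifest dict.

    Stages never mutate their input files; all outputs are new files in
    ``config.outdir``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from . import __version__

    header = f"#switchgrain\tversion={__version__}\tseed={config.seed}\n"

    # -- inputs -----------------------------------------------------------
    sim = None
    if config.simulation is not None:
        sim = replace(config.simulation, seed=config.seed,
                      samples=config.design.samples, replicates=config.design.replicates)
        log.info("simulating dataset (%d genes, seed %d)", sim.n_genes, config.seed)
        gene_counts, tx_counts, model, truth = simulate_dataset(sim)
        gene_counts.write_tsv(outdir / "gene_counts.tsv", extra_header={"seed": str(config.seed)})
        tx_counts.write_tsv(outdir / "transcript_counts.tsv",
                            extra_header={"seed": str(config.seed)})
        model.to_tsv(outdir / "annotation.tsv")
        truth.gene_roles.to_csv(outdir / "truth_gene_roles.tsv", sep="\t",
                                index_label="gene_id")
        reference_ids = list(truth.reference_ids)
    else:
        gene_counts = read_counts(config.gene_counts_path, config.design, "gene")
        tx_counts = read_counts(config.transcript_counts_path, config.design, "transcript")
        model = read_annotation(config.annotation_path)
        reference_ids = []

    # -- reference genes and bias diagnostics -----------------------------
    table = stability_screen(gene_counts, config.refgene_threshold_pct)
    table.frame.to_csv(outdir / "stability.tsv", sep="\t", index_label="gene_id")
    if not reference_ids:
        reference_ids = list(table.selected_ids)
    schemes = [CorrectionScheme("none"), config.scheme]
    if reference_ids:
        reports = compare_schemes(gene_counts, schemes, reference_ids)
        with (outdir / "bias_report.tsv").open("w") as fh:
            fh.write(header)
            fh.write("scheme\tslope_mean\tratio_deviation_pct\tinter_replicate_sd"
                     "\tinter_treatment_bias\tn_events_used\n")
            for r in reports:
                fh.write(f"{r.scheme}\t{r.slope_mean:.6f}\t{r.ratio_deviation_pct:.4f}"
                         f"\t{r.inter_replicate_sd:.6f}\t{r.inter_treatment_bias:.6f}"
                         f"\t{r.n_events_used}\n")

    # -- DE at both levels, switching, summaries --------------------------
    gene_model_fit = NBExactTestModel(gene_counts, config.de)
    tx_model_fit = NBExactTestModel(tx_counts, config.de)
    summaries = []
    identical = set()
    for pair in config.comparisons:
        slug = _slug(pair.name)
        gres = gene_model_fit.fit(pair)
        tres = tx_model_fit.fit(pair)
        gres.write_tsv(outdir / f"de_gene_{slug}.tsv", extra_header={"seed": config.seed})
        tres.write_tsv(outdir / f"de_transcript_{slug}.tsv", extra_header={"seed": config.seed})
        calls = detect_switches(tres, model, gres)
        identical.update(identical_protein_genes(calls))
        with (outdir / f"switches_{slug}.tsv").open("w") as fh:
            fh.write(header)
            fh.write("gene_id\tcomparison\tswitch_class\tidentical_protein"
                     "\tgene_level_class\tup_transcripts\tdown_transcripts\n")
            for c in calls:
                fh.write(f"{c.gene_id}\t{c.comparison}\t{c.switch_class}"
                         f"\t{c.identical_protein}\t{c.gene_level_class}"
                         f"\t{','.join(c.up_transcripts)}\t{','.join(c.down_transcripts)}\n")
        summaries.extend(summarize(gres, tres, calls, model))
        log.info("%s: gene DE=%d, transcript DE=%d, switches=%d",
                 pair.name, gres.n_de, tres.n_de, len(calls))
    if config.comparisons:
        _write_summaries(outdir / "summary.tsv", summaries, header)
        with (outdir / "identical_protein_genes.tsv").open("w") as fh:
            fh.write(header + "gene_id\n")
            for g in sorted(identical):
                fh.write(g + "\n")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "design": {"samples": list(config.design.samples),
                   "replicates": config.design.replicates},
        "comparisons": [c.name for c in config.comparisons],
        "scheme": {"kind": config.scheme.kind,
                   "reference_ids": list(config.scheme.reference_ids),
                   "order": list(config.scheme.order)},
        "de": asdict(config.de),
        "simulation": None if sim is None else _jsonable(asdict(sim)),
        "inputs": {"gene_counts": config.gene_counts_path,
                   "transcript_counts": config.transcript_counts_path,
                   "annotation": config.annotation_path},
        "refgene_threshold_pct": config.refgene_threshold_pct,
        "n_reference_genes_selected": len(table.selected_ids),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj
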