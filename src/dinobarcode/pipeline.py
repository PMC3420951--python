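"""End-to-end orchestration: alignment -> distances -> delimitation -> QC -> tree.

``run`` executes every stage the inputs support and writes a report
bundle (TSV/JSON tables, Newick tree, structured log, manifest with
input checksums) into the output directory.  Reruns with identical
inputs and config reproduce identical outputs.  A strain table alone —
no sequences — supports an efficiency-only run, since most failed
strains never yield a barcode yet belong in the accounting.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import yaml

from . import delimitation as dl
from . import distance as dist
from . import gap_qc, njtree, seqio

__all__ = ["PipelineConfig", "ValidationReport", "ReportBundle", "run", "validate"]


@dataclass
class PipelineConfig:
    fasta: str | None = None
    strain_table: str | None = None
    clone_table: str | None = None
    out_dir: str = "dinobarcode_out"
    dialect: str = "tsv"
    theta: float = 0.02
    strict_threshold: bool = False
    identity_tol: float = 0.0
    deletion: str = "complete_deletion"
    bin_width: float = 0.02
    mean_mode: str = "pairs"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a YAML config file; keyword overrides win over file values."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def delimitation_config(self) -> dl.DelimitationConfig:
        return dl.DelimitationConfig(
            theta=self.theta,
            strict_threshold=self.strict_threshold,
            identity_tol=self.identity_tol,
        )


@dataclass
class ValidationReport:
    problems: list[str] = field(default_factory=list)
    #: FASTA ids with no strain-table (or clone-table) entry
    orphan_sequences: list[str] = field(default_factory=list)
    #: strain-table ids marked barcoded but absent from the FASTA
    orphan_strains: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.problems and not self.orphan_sequences


def _load_inputs(config: PipelineConfig):
    alignment = seqio.read_fasta(config.fasta) if config.fasta else None
    table = (
        seqio.read_strain_table(config.strain_table, dialect=config.dialect)
        if config.strain_table
        else None
    )
    clones = (
        seqio.read_clone_groups(config.clone_table, dialect=config.dialect)
        if config.clone_table
        else seqio.CloneGroupTable({})
    )
    return alignment, table, clones


def _expand_clones(table: seqio.StrainTable, clones: seqio.CloneGroupTable) -> seqio.StrainTable:
    """Give each clone accession a metadata row inherited from its parent."""
    rows = list(table)
    for parent, clone_ids in clones.items():
        if parent not in table:
            continue
        prow = table[parent]
        for cid in clone_ids:
            if cid not in table:
                rows.append(dataclasses.replace(prow, strain_id=cid, synonyms=()))
    return seqio.StrainTable(rows)


def validate(config: PipelineConfig) -> ValidationReport:
    """Check file existence, alignment integrity, and id cross-references."""
    report = ValidationReport()
    for label in ("fasta", "strain_table", "clone_table"):
        path = getattr(config, label)
        if path and not Path(path).exists():
            report.problems.append(f"{label} file not found: {path}")
    if report.problems:
        return report
    try:
        alignment, table, clones = _load_inputs(config)
    except (seqio.ParseError, seqio.AlignmentError) as exc:
        report.problems.append(str(exc))
        return report
    if alignment is None and table is None:
        report.problems.append("no inputs: provide a FASTA and/or a strain table")
        return report
    if alignment is not None and table is not None:
        table = _expand_clones(table, clones)
        for sid in alignment.ids:
            if sid not in table:
                report.orphan_sequences.append(sid)
        fasta_ids = set(alignment.ids)
        for row in table:
            if row.status == "barcoded" and row.strain_id not in fasta_ids:
                report.orphan_strains.append(row.strain_id)
    return report


@dataclass
class ReportBundle:
    out_dir: Path
    paths: dict[str, Path]
    dm: dist.DistanceMatrix | None = None
    result: dl.DelimitationResult | None = None
    gap: gap_qc.GapSummary | None = None
    efficiency: gap_qc.EfficiencyReport | None = None
    tree: njtree.Tree | None = None


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _pkg_version() -> str:
    try:
        return version("dinobarcode")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def run(config: PipelineConfig) -> ReportBundle:
    """Execute all supported stages and write the report bundle."""
    report = validate(config)
    if report.problems:
        raise RuntimeError("validation failed: " + "; ".join(report.problems))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    alignment, raw_table, clones = _load_inputs(config)
    # efficiency counts strains; delimitation needs a row per sequence,
    # so clone accessions get rows inherited from their parent strain
    table = _expand_clones(raw_table, clones) if raw_table is not None else None
    dcfg = config.delimitation_config()
    paths: dict[str, Path] = {}
    log: list[dict] = []
    bundle = ReportBundle(out_dir=out_dir, paths=paths)

    def emit(name: str, filename: str, writer) -> None:
        path = out_dir / filename
        writer(path)
        paths[name] = path

    if raw_table is not None:
        eff = gap_qc.efficiency_report(raw_table)
        bundle.efficiency = eff
        emit("efficiency_failures", "efficiency_failures.tsv",
             lambda p: eff.failure_frame().to_csv(p, sep="\t", index=False))
        emit("efficiency_genus", "efficiency_genus.tsv",
             lambda p: eff.genus_frame().to_csv(p, sep="\t", index=False))
        emit("efficiency_json", "efficiency.json",
             lambda p: p.write_text(json.dumps({
                 "status_counts": eff.status_counts,
                 "failure_pct": eff.failure_pct,
                 "overall_success_pct": eff.overall_success_pct,
                 "totals_by_source": eff.totals_by_source,
             }, indent=1, sort_keys=True)))
        log.append({"stage": "efficiency", "n_strains": eff.n_strains,
                    "n_failures": eff.n_failures})

    if alignment is not None:
        dm = dist.distance_matrix(alignment, policy=config.deletion)
        bundle.dm = dm
        emit("distances", "distances.tsv", dm.write_tsv)
        emit("distances_phylip", "distances.phy", dm.write_phylip)
        n_sites = dm.n_sites if isinstance(dm.n_sites, int) else "per-pair"
        log.append({"stage": "distance", "n_sequences": len(dm),
                    "policy": config.deletion, "n_sites": n_sites})

        if table is not None:
            partition = dl.cluster_species(dm, dcfg)
            result = dl.assign_labels(partition, table, dcfg, dm=dm)
            bundle.result = result
            emit("groups", "groups.tsv",
                 lambda p: result.group_frame().to_csv(p, sep="\t", index=False))
            emit("assignments", "assignments.tsv",
                 lambda p: result.assignment_frame().to_csv(p, sep="\t", index=False))
            checks = dl.check_synonyms(dm, table, dcfg)
            emit("synonyms", "synonyms.tsv",
                 lambda p: dl.synonym_frame(checks).to_csv(p, sep="\t", index=False))
            log.append({
                "stage": "delimitation", "theta": dcfg.theta,
                "n_groups": len(result.groups),
                "n_mismatch": sum(a.mismatch for a in result.assignments),
                "n_cryptic": sum(a.cryptic for a in result.assignments),
                "n_newly_identified": sum(a.newly_identified for a in result.assignments),
                "n_chained_pairs": len(result.chained_pairs),
                "n_synonym_checks": len(checks),
            })

            pairs = gap_qc.label_pairs(dm, table)
            if not pairs.frame.empty:
                gap = gap_qc.gap_summary(
                    pairs, bin_width=config.bin_width, theta=dcfg.theta,
                    mean_mode=config.mean_mode, strain_table=table,
                )
                bundle.gap = gap
                emit("gap_summary", "gap_summary.json",
                     lambda p: p.write_text(json.dumps(gap.to_dict(), indent=1)))
                emit("gap_histogram", "gap_histogram.tsv",
                     lambda p: gap.histogram.to_csv(p, sep="\t", index=False))
                log.append({"stage": "gap", "n_intra": gap.n_intra,
                            "n_inter": gap.n_inter, "ratio": gap.ratio})

            if len(clones):
                summaries = gap_qc.clonal_variation(dm, clones)
                emit("clonal_variation", "clonal_variation.tsv",
                     lambda p: gap_qc.clonal_frame(summaries).to_csv(p, sep="\t", index=False))
                log.append({"stage": "clonal", "n_groups": len(summaries)})

        if len(dm) >= 2:
            tree = njtree.neighbor_joining(dm)
            bundle.tree = tree
            emit("tree", "tree.nwk", lambda p: seqio.write_newick(tree, p))
            if bundle.result is not None:
                mono = njtree.annotate_groups(tree, bundle.result.groups)
                emit("monophyly", "monophyly.tsv",
                     lambda p: njtree.monophyly_frame(mono).to_csv(p, sep="\t", index=False))
                log.append({"stage": "njtree", "n_leaves": len(dm),
                            "n_monophyletic": sum(r.monophyletic for r in mono)})
            else:
                log.append({"stage": "njtree", "n_leaves": len(dm)})

    emit("log", "run.log", lambda p: p.write_text(
        "\n".join(json.dumps(e, sort_keys=True) for e in log) + "\n"))
    manifest = {
        "version": _pkg_version(),
        "config": dataclasses.asdict(config),
        "inputs": {
            label: {"path": str(getattr(config, label)), "sha256": _sha256(getattr(config, label))}
            for label in ("fasta", "strain_table", "clone_table")
            if getattr(config, label)
        },
        "outputs": sorted(p.name for p in paths.values()),
    }
    emit("manifest", "manifest.json",
         lambda p: p.write_text(json.dumps(manifest, indent=1, sort_keys=True)))
    return bundle
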