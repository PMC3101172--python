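"""Pipeline orchestration: simulate -> screen -> classify -> report.

One YAML config drives a reproducible run.  Three modes:

``fixtures``
    classify the fourteen shipped worked-example gene trees and write the
    category table and summary;
``benchmark``
    simulate planted-history families, screen them, classify the resulting
    trees, and report label-recovery against the planted truth;
``data``
    screen and classify a directory of user-supplied per-gene aligned FASTA
    files with a taxonomy TSV.

Every stage records a digest of its configuration and inputs in the run
manifest; re-running with an unchanged manifest skips completed stages, so
deleting a downstream output resumes without recomputing upstream ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .classify import (ClassifyConfig, GeneClassification,
                       classify_gene_tree, summarize_table)
from .errors import ConfigError, StageError
from .msa import write_fasta
from .screen import ScreenConfig, screen_alignments
from .simulate import (Scenario, ScenarioLabel, make_table1_fixtures,
                       simulate_benchmark, truth_to_tsv)
from .taxonomy import (TaxonomyMap, default_taxonomy, read_taxonomy,
                       write_taxonomy)
from .trees import PhyloTree, write_newick

__all__ = ["RunManifest", "run_pipeline", "load_config"]

log = logging.getLogger("mosaicscreen")

_MODES = ("fixtures", "benchmark", "data")


@dataclass
class RunManifest:
    version: str
    seed: int
    mode: str
    config: dict
    stages: dict[str, dict] = field(default_factory=dict)
    errors: list[dict] = field(default_factory=list)
    created: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def write(self, path: Path) -> None:
        path.write_text(self.to_json(), encoding="utf-8")


def load_config(source: str | Path | Mapping[str, Any]) -> dict:
    if isinstance(source, Mapping):
        cfg = dict(source)
    else:
        cfg = yaml.safe_load(Path(source).read_text(encoding="utf-8"))
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    mode = cfg.get("mode")
    if mode not in _MODES:
        raise ConfigError(f"mode: expected one of {_MODES}, got {mode!r}")
    if "out_dir" not in cfg:
        raise ConfigError("out_dir: missing")
    cfg.setdefault("seed", 0)
    return cfg


def _section(cfg: dict, name: str, cls, **extra):
    raw = dict(cfg.get(name, {}) or {})
    raw.update(extra)
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - valid
    if unknown:
        raise ConfigError(f"{name}.{sorted(unknown)[0]}: unknown field")
    try:
        return cls(**raw)
    except TypeError as exc:
        raise ConfigError(f"{name}: {exc}") from exc


def _digest(parts: list) -> str:
    h = hashlib.sha256()
    for part in parts:
        if isinstance(part, (str, int, float)):
            h.update(str(part).encode())
        elif isinstance(part, bytes):
            h.update(part)
        elif isinstance(part, Path):
            h.update(part.name.encode())
            h.update(part.read_bytes())
        else:
            h.update(json.dumps(part, sort_keys=True, default=str).encode())
    return h.hexdigest()


def _stage_done(manifest_path: Path, stage: str, digest: str,
                outputs: list[Path]) -> bool:
    if not manifest_path.exists():
        return False
    try:
        old = json.loads(manifest_path.read_text())
    except (json.JSONDecodeError, OSError):
        return False
    rec = old.get("stages", {}).get(stage)
    if not rec or rec.get("digest") != digest:
        return False
    return all(Path(p).exists() for p in rec.get("outputs", []))


def run_pipeline(config: str | Path | Mapping[str, Any]) -> RunManifest:
    """Execute the configured stages in order; returns the run manifest."""
    cfg = load_config(config)
    mode = cfg["mode"]
    seed = int(cfg["seed"])
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    manifest = RunManifest(version=__version__, seed=seed, mode=mode,
                           config=cfg, created=time.strftime("%Y-%m-%dT%H:%M:%S"))

    classify_cfg = _section(cfg, "classify", ClassifyConfig)
    if mode == "fixtures":
        _run_fixtures(cfg, out_dir, classify_cfg, manifest, manifest_path)
    elif mode == "benchmark":
        _run_benchmark(cfg, out_dir, seed, classify_cfg, manifest, manifest_path)
    else:
        _run_data(cfg, out_dir, seed, classify_cfg, manifest, manifest_path)

    manifest.write(manifest_path)
    return manifest


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def _classify_trees(trees: dict[str, PhyloTree], query: str,
                    taxonomy: TaxonomyMap, classify_cfg: ClassifyConfig,
                    manifest: RunManifest) -> list[GeneClassification]:
    out = []
    for gene_id in sorted(trees):
        try:
            out.append(classify_gene_tree(trees[gene_id], query, taxonomy,
                                          classify_cfg, gene_id=gene_id))
        except Exception as exc:  # noqa: BLE001
            err = StageError("classify", gene_id, str(exc))
            log.warning(str(err))
            manifest.errors.append({"stage": "classify", "unit": gene_id,
                                    "error": str(exc)})
    return out


def _write_table(classifications, out_dir: Path) -> tuple[Path, Path]:
    table_path = out_dir / "table1.tsv"
    with open(table_path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tcategory\tdefining_support\tsupport_scale\t"
                 "peranema\troot_group\tnotes\n")
        for cl in classifications:
            sup = "" if cl.defining_support is None else f"{cl.defining_support:g}"
            root = cl.root_group_used.value if cl.root_group_used else ""
            fh.write(f"{cl.gene_id}\t{cl.category.value}\t{sup}\t"
                     f"{cl.support_scale}\t{'+' if cl.peranema_in_clade else '-'}\t"
                     f"{root}\t{cl.notes}\n")
    summary = summarize_table(classifications)
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary.as_dict(), indent=2,
                                       sort_keys=True), encoding="utf-8")
    return table_path, summary_path


def _record(manifest: RunManifest, stage: str, digest: str,
            outputs: list[Path]) -> None:
    manifest.stages[stage] = {"digest": digest,
                              "outputs": [str(p) for p in outputs]}


def _run_fixtures(cfg, out_dir, classify_cfg, manifest, manifest_path):
    taxonomy = default_taxonomy()
    fixtures = make_table1_fixtures()
    fix_dir = out_dir / "fixtures"
    digest = _digest(["fixtures", dataclasses.asdict(classify_cfg)])
    fix_dir.mkdir(exist_ok=True)
    expected_path = fix_dir / "expected.tsv"
    if not _stage_done(manifest_path, "fixtures", digest,
                       [expected_path]):
        with open(expected_path, "w", encoding="utf-8") as fh:
            fh.write("gene_id\tcluster_id\texpected_category\tperanema\tnote\n")
            for fx in fixtures:
                write_newick(fx.tree, fix_dir / f"{fx.gene_id}.nwk")
                fh.write(f"{fx.gene_id}\t{fx.cluster_id}\t"
                         f"{fx.expected_category.value}\t"
                         f"{'+' if fx.expect_peranema else '-'}\t{fx.note}\n")
    _record(manifest, "fixtures", digest, [expected_path])

    trees = {fx.gene_id: fx.tree for fx in fixtures}
    classifications = _classify_trees(trees, "Euglena_gracilis", taxonomy,
                                      classify_cfg, manifest)
    outputs = list(_write_table(classifications, out_dir))
    _record(manifest, "classify", digest, outputs)


def _run_benchmark(cfg, out_dir, seed, classify_cfg, manifest, manifest_path):
    sim_raw = dict(cfg.get("simulate", {}) or {})
    n_per_label = int(sim_raw.pop("n_per_label", 5))
    sim_raw.setdefault("seed", seed)
    sim_raw["label"] = ScenarioLabel.VERTICAL
    template = _section({"simulate": sim_raw}, "simulate", Scenario)
    screen_cfg = _section(cfg, "screen", ScreenConfig, seed=seed)
    taxonomy = default_taxonomy()

    fam_dir = out_dir / "families"
    sim_digest = _digest(["simulate", n_per_label, dataclasses.asdict(template),
                          seed])
    truth_path = out_dir / "truth.tsv"
    taxonomy_path = out_dir / "taxonomy.tsv"
    families = simulate_benchmark(n_per_label, template, seed=seed)
    if not _stage_done(manifest_path, "simulate", sim_digest,
                       [truth_path, taxonomy_path]):
        fam_dir.mkdir(exist_ok=True)
        for fam in families:
            write_fasta(fam.alignment, fam_dir / f"{fam.family_id}.fasta")
            write_newick(fam.tree, fam_dir / f"{fam.family_id}.true.nwk")
        truth_to_tsv(families, truth_path)
        write_taxonomy(taxonomy, taxonomy_path)
    _record(manifest, "simulate", sim_digest, [truth_path, taxonomy_path])

    screen_digest = _digest([sim_digest, dataclasses.asdict(screen_cfg)])
    report_path = out_dir / "report.tsv"
    alignments = {fam.family_id: fam.alignment for fam in families}
    results = screen_alignments(alignments, taxonomy, screen_cfg,
                                out_dir=out_dir, logger=log)
    _record(manifest, "screen", screen_digest,
            [report_path, out_dir / "tally.tsv"])

    trees = {r.gene_id: r.supported_tree for r in results}
    classifications = _classify_trees(trees, "Euglena_gracilis", taxonomy,
                                      classify_cfg, manifest)
    outputs = list(_write_table(classifications, out_dir))
    _record(manifest, "classify",
            _digest([screen_digest, dataclasses.asdict(classify_cfg)]), outputs)

    # recovery report against planted truth
    expected = {fam.family_id: fam.expected_category for fam in families}
    by_gene = {cl.gene_id: cl.category for cl in classifications}
    per_label: dict[str, dict[str, int]] = {}
    hits = 0
    for fam in families:
        got = by_gene.get(fam.family_id)
        rec = per_label.setdefault(fam.label.value, {"n": 0, "recovered": 0})
        rec["n"] += 1
        if got == expected[fam.family_id]:
            rec["recovered"] += 1
            hits += 1
    recovery = {"n_families": len(families), "recovered": hits,
                "recovery_rate": hits / len(families), "per_label": per_label}
    recovery_path = out_dir / "recovery.json"
    recovery_path.write_text(json.dumps(recovery, indent=2, sort_keys=True),
                             encoding="utf-8")
    _record(manifest, "report", _digest([str(recovery)]), [recovery_path])


def _run_data(cfg, out_dir, seed, classify_cfg, manifest, manifest_path):
    data = dict(cfg.get("data", {}) or {})
    aln_dir = data.get("alignments_dir")
    if not aln_dir:
        raise ConfigError("data.alignments_dir: missing")
    aln_dir = Path(aln_dir)
    files = sorted(aln_dir.glob("*.fasta")) + sorted(aln_dir.glob("*.fa"))
    if not aln_dir.is_dir() or not files:
        raise ConfigError(f"data.alignments_dir: no FASTA files in {aln_dir}")
    taxonomy = (read_taxonomy(data["taxonomy"]) if data.get("taxonomy")
                else default_taxonomy())
    query_prefix = data.get("query_prefix", "Euglena")
    screen_cfg = _section(cfg, "screen", ScreenConfig, seed=seed)

    digest = _digest(["data", *files, dataclasses.asdict(screen_cfg)])
    results = screen_alignments(aln_dir, taxonomy, screen_cfg,
                                query_prefix=query_prefix, out_dir=out_dir,
                                logger=log)
    _record(manifest, "screen", digest,
            [out_dir / "report.tsv", out_dir / "tally.tsv"])

    trees = {r.gene_id: r.supported_tree for r in results}
    queries = {r.gene_id: r.closest.query_id for r in results}
    classifications = []
    for gene_id in sorted(trees):
        try:
            classifications.append(classify_gene_tree(
                trees[gene_id], queries[gene_id], taxonomy, classify_cfg,
                gene_id=gene_id))
        except Exception as exc:  # noqa: BLE001
            log.warning("classify failed on %s: %s", gene_id, exc)
            manifest.errors.append({"stage": "classify", "unit": gene_id,
                                    "error": str(exc)})
    outputs = list(_write_table(classifications, out_dir))
    _record(manifest, "classify",
            _digest([digest, dataclasses.asdict(classify_cfg)]), outputs)
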