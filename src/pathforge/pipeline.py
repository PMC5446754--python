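"""End-to-end pipeline: simulate/load -> LD filter -> map -> enrich -> replicate.

A single :class:`PipelineConfig` carries every threshold exactly once and is
serialised verbatim into the run record, so any run can be reproduced
bit-identically from its record.  One global seed deterministically derives
per-stage seeds by stage-name hashing.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .enrichment import (
    EnrichmentConfig,
    add_permutation_pvalues,
    gene_enrichment,
    pathway_enrichment,
)
from .formats_io import (
    read_gene_bed,
    read_gmt,
    read_panel,
    read_sumstats,
    write_sumstats,
)
from .ld_ops import PruneConfig, apply_ld_filter
from .replication import DEFAULT_TIERS, replicate_pathways
from .snp_gene_mapping import map_snps, mapping_summary
from .synthetic_data import ScenarioConfig, make_scenario

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and partial record."""

    def __init__(self, stage: str, cause: Exception, record: dict):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.record = record


@dataclass
class PipelineConfig:
    """All pipeline parameters in one place.

    Either ``scenario`` (synthetic inputs) or the explicit input paths must
    be provided.  ``ld_mode`` is one of "pruning", "clumping" or "none"
    (skipping LD filtering is an explicit choice, kept available to expose
    the before/after false-positive contrast).
    """

    # inputs: synthetic ...
    scenario: ScenarioConfig | None = None
    # ... or files
    sumstats_discovery: str | None = None
    sumstats_replication: str | None = None
    panel_path: str | None = None
    panel_format: str = "tsv"
    genes_bed: str | None = None
    gmt_path: str | None = None
    # stage parameters (defaults: r2 0.3, 100 kb window, alpha 0.05, q 0.05)
    ld_mode: str = "pruning"
    r2_max: float = 0.3
    ld_window_bp: int = 1_000_000
    window_bp: int = 100_000
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    run_permutations: bool = False
    tiers: tuple[float, ...] = DEFAULT_TIERS
    # bookkeeping
    outdir: str | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "scenario" in raw and raw["scenario"] is not None:
            sc = dict(raw["scenario"])
            for key in ("gene_length_range", "set_size_range", "planted_sets"):
                if key in sc:
                    sc[key] = tuple(sc[key])
            raw["scenario"] = ScenarioConfig(**sc)
        if "enrichment" in raw and raw["enrichment"] is not None:
            raw["enrichment"] = EnrichmentConfig(**raw["enrichment"])
        if "tiers" in raw:
            raw["tiers"] = tuple(raw["tiers"])
        return cls(**raw)


@dataclass
class RunRecord:
    config: dict
    stages: dict[str, dict]
    seed: int
    started: float
    finished: float = 0.0
    schema_version: int = 1

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)

    @classmethod
    def from_json(cls, text: str) -> "RunRecord":
        d = json.loads(text)
        if d.get("schema_version") != 1:
            raise ValueError(f"incompatible run-record schema {d.get('schema_version')!r}")
        return cls(**d)


@dataclass
class PipelineResult:
    record: RunRecord
    gene_results: dict  # cohort -> DataFrame
    pathway_results: dict  # cohort -> DataFrame
    replication: object
    sumstats: dict  # cohort -> SumStats (post LD filter)
    mapping: dict  # cohort -> MappingTable
    scenario: object | None = None


def run_pipeline(cfg: PipelineConfig):
    """Execute the full pipeline; returns a :class:`PipelineResult`.

    Any stage failure raises :class:`StageError` naming the stage and
    carrying the partial run record.  With ``cfg.outdir`` set, all stage
    outputs and the run record are written to disk.
    """
    record = RunRecord(config=cfg.to_dict(), stages={}, seed=cfg.seed, started=time.time())
    stage = "inputs"
    try:
        scenario = None
        if cfg.scenario is not None:
            scenario = make_scenario(cfg.scenario, seed=cfg.seed)
            cohorts = {
                "discovery": scenario.sumstats_discovery,
                "replication": scenario.sumstats_replication,
            }
            panel = scenario.panel
            genes = scenario.genes
            collection = scenario.collection
        else:
            for name, p in (
                ("sumstats_discovery", cfg.sumstats_discovery),
                ("panel_path", cfg.panel_path),
                ("genes_bed", cfg.genes_bed),
                ("gmt_path", cfg.gmt_path),
            ):
                if p is None:
                    raise FileNotFoundError(f"config field {name} is required without a scenario")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: no such file {p}")
            cohorts = {"discovery": read_sumstats(cfg.sumstats_discovery, cohort_label="discovery")}
            if cfg.sumstats_replication:
                if not Path(cfg.sumstats_replication).exists():
                    raise FileNotFoundError(
                        f"sumstats_replication: no such file {cfg.sumstats_replication}"
                    )
                cohorts["replication"] = read_sumstats(
                    cfg.sumstats_replication, cohort_label="replication"
                )
            panel = read_panel(cfg.panel_path, format=cfg.panel_format)
            genes = read_gene_bed(cfg.genes_bed)
            collection = read_gmt(cfg.gmt_path)
        record.stages["inputs"] = {
            "cohorts": {k: len(v) for k, v in cohorts.items()},
            "panel_variants": panel.n_variants,
            "genes": len(genes),
            "gene_sets": len(collection),
        }

        stage = "ld_filter"
        filtered = {}
        for label, ss in cohorts.items():
            if cfg.ld_mode == "none":
                filtered[label] = ss
            else:
                pc = PruneConfig(r2_max=cfg.r2_max, bp_window=cfg.ld_window_bp, mode=cfg.ld_mode)
                filtered[label] = apply_ld_filter(ss, panel, pc)
        record.stages["ld_filter"] = {
            "mode": cfg.ld_mode,
            "snps_in": {k: len(v) for k, v in cohorts.items()},
            "snps_out": {k: len(v) for k, v in filtered.items()},
        }

        stage = "mapping"
        mappings = {k: map_snps(v, genes, cfg.window_bp) for k, v in filtered.items()}
        record.stages["mapping"] = {
            k: dataclasses.asdict(mapping_summary(m, n_snps_input=len(filtered[k])))
            for k, m in mappings.items()
        }

        stage = "enrichment"
        gene_results, pathway_results = {}, {}
        for label in filtered:
            gr = gene_enrichment(filtered[label], mappings[label], cfg.enrichment)
            pr = pathway_enrichment(gr, collection, cfg.enrichment)
            if cfg.run_permutations:
                pr = add_permutation_pvalues(pr, gr, collection, cfg.enrichment)
            gene_results[label] = gr
            pathway_results[label] = pr
        record.stages["enrichment"] = {
            k: {
                "genes_tested": len(gene_results[k]),
                "pathways_tested": int(pathway_results[k]["testable"].sum()),
                "pathways_flagged": int(pathway_results[k]["significant"].sum()),
            }
            for k in gene_results
        }

        stage = "replication"
        repl = None
        if "replication" in pathway_results:
            repl = replicate_pathways(
                pathway_results["discovery"], pathway_results["replication"], cfg.tiers
            )
            record.stages["replication"] = {
                "tiers": list(repl.tiers),
                "n_discovery": {str(t): n for t, n in repl.n_discovery.items()},
                "n_replicated": {str(t): n for t, n in repl.n_replicated.items()},
            }

        stage = "outputs"
        record.finished = time.time()
        if cfg.outdir:
            out = Path(cfg.outdir)
            out.mkdir(parents=True, exist_ok=True)
            for label in filtered:
                write_sumstats(filtered[label], out / f"snps_{label}.tsv")
                mappings[label].df.to_csv(out / f"mapping_{label}.tsv", sep="\t", index=False)
                gene_results[label].to_csv(
                    out / f"genes_{label}.tsv", sep="\t", index=False, float_format="%.6g"
                )
                pathway_results[label].to_csv(
                    out / f"pathways_{label}.tsv", sep="\t", index=False, float_format="%.6g"
                )
            if repl is not None:
                repl.to_frame().to_csv(out / "replication.tsv", sep="\t", index=False)
            (out / "run_record.json").write_text(record.to_json() + "\n")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise StageError(stage, exc, dataclasses.asdict(record)) from exc

    return PipelineResult(
        record=record,
        gene_results=gene_results,
        pathway_results=pathway_results,
        replication=repl,
        sumstats=filtered,
        mapping=mappings,
        scenario=scenario,
    )


def compare_runs(rec_a: RunRecord, rec_b: RunRecord) -> str:
    """Textual diff of two run records: differing config keys and headline counts."""
    if rec_a.schema_version != rec_b.schema_version:
        raise ValueError("incompatible run-record schema versions")
    lines = []

    def _flatten(d: dict, prefix: str = "") -> dict:
        out = {}
        for k, v in d.items():
            key = f"{prefix}{k}"
            if isinstance(v, dict):
                out.update(_flatten(v, key + "."))
            else:
                out[key] = v
        return out

    fa, fb = _flatten(rec_a.config), _flatten(rec_b.config)
    for key in sorted(set(fa) | set(fb)):
        va, vb = fa.get(key), fb.get(key)
        if va != vb:
            lines.append(f"config {key}: {va!r} -> {vb!r}")
    sa, sb = _flatten(rec_a.stages), _flatten(rec_b.stages)
    for key in sorted(set(sa) | set(sb)):
        va, vb = sa.get(key), sb.get(key)
        if va != vb:
            lines.append(f"stage {key}: {va!r} -> {vb!r}")
    return "\n".join(lines)
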