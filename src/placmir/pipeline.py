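"""End-to-end pipeline orchestration with a reproducible run manifest.

A YAML config selects and parameterizes stages; stages run in dependency
order (simulate -> screen -> seedmatch -> enrich -> quant -> associate), any
stage can be omitted, and every run writes a manifest with the config hash,
input/output checksums and the seeds used, so an identical config reproduces
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import assoc_stats, qpcr_screen, rel_quant, seed_enrichment, seed_match, synthetic

log = logging.getLogger("placmir")

STAGES = ("simulate", "screen", "seedmatch", "enrich", "quant", "associate")


class ConfigError(ValueError):
    """The run configuration is invalid; raised before any stage executes."""


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list[str]
    input_checksums: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    output_checksums: dict[str, str] = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _validate(cfg: dict) -> list[str]:
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    enabled = [s for s in STAGES if s in cfg]
    if not enabled:
        raise ConfigError(f"no known stage in config; expected some of {STAGES}")
    unknown = set(cfg) - set(STAGES) - {"seed", "out"}
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    sim = "simulate" in cfg
    if "screen" in cfg and not sim and "cq" not in cfg["screen"]:
        raise ConfigError("screen stage needs a 'cq' path when simulate is disabled")
    if "seedmatch" in cfg and not sim:
        for key in ("mirnas", "transcripts", "regions"):
            if key not in cfg["seedmatch"]:
                raise ConfigError(f"seedmatch stage needs a {key!r} path when simulate is disabled")
    if "quant" in cfg and not sim and "records" not in cfg["quant"]:
        raise ConfigError("quant stage needs a 'records' path when simulate is disabled")
    if "associate" in cfg and not sim and "cohort" not in cfg["associate"]:
        raise ConfigError("associate stage needs a 'cohort' path when simulate is disabled")
    return enabled


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> RunManifest:
    """Validate the config, run the enabled stages, write outputs + manifest."""
    if not isinstance(config, dict):
        config_path = Path(config)
        cfg = yaml.safe_load(config_path.read_text())
    else:
        cfg = config
    enabled = _validate(cfg)
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir or cfg.get("out", "pipeline_out"))
    out.mkdir(parents=True, exist_ok=True)

    canon = json.dumps(cfg, sort_keys=True, default=str)
    manifest = RunManifest(
        config_hash=hashlib.sha256(canon.encode()).hexdigest(),
        seed=seed,
        stages=enabled,
        started=time.time(),
    )

    mirnas = transcripts = None
    cq = records = cohort = None

    if "simulate" in cfg:
        sc = cfg["simulate"] or {}
        log.info("stage simulate: seed=%d", seed)
        cq, truth_a = synthetic.simulate_cq_array(
            seed=seed, **(sc.get("array") or {})
        )
        qpcr_screen.write_cq_table(cq, out / "cq_table.tsv")
        truth_a.to_json(out / "truth_array.json")
        mirnas = [
            seed_match.MatureMiRNA(m["id"], m["sequence"])
            for m in sc.get("mirnas", [{"id": "sim-miR-99a", "sequence": "AACCCGUAGAUCCGAUCUUGUG"}])
        ]
        synthetic.write_mirnas(mirnas, out / "mirnas.fasta")
        transcripts, truth_t = synthetic.simulate_transcripts(
            mirnas, seed=seed + 1, **(sc.get("transcripts") or {})
        )
        synthetic.write_transcripts(transcripts, out / "transcripts.fasta", out / "regions.tsv")
        truth_t.to_json(out / "truth_transcripts.json")
        cohort, records, truth_c = synthetic.simulate_cohort(
            seed=seed + 2, **(sc.get("cohort") or {})
        )
        cohort.to_csv(out / "cohort.csv", index=False)
        records.to_csv(out / "validation_cq.csv", index=False)
        truth_c.to_json(out / "truth_cohort.json")
        for name in ("cq_table.tsv", "mirnas.fasta", "transcripts.fasta",
                     "regions.tsv", "cohort.csv", "validation_cq.csv"):
            manifest.outputs[name] = str(out / name)

    if "screen" in cfg:
        pc = cfg["screen"] or {}
        if cq is None:
            path = pc["cq"]
            manifest.input_checksums[path] = _sha256(path)
            cq = qpcr_screen.read_cq_table(path, pc.get("undetermined_token", "Undetermined"))
        results, venn = qpcr_screen.classify_and_summarize(
            cq,
            cq_max=pc.get("cq_max", 40.0),
            span=pc.get("span", 0.7),
            taus=tuple(pc.get("taus", (0.05, 0.95))),
            degree=pc.get("degree", 2),
            n_screened=pc.get("n_screened"),
        )
        qpcr_screen.write_screen_results(results, out / "screen_results.tsv")
        venn.to_json(out / "venn_summary.json")
        manifest.outputs["screen_results.tsv"] = str(out / "screen_results.tsv")
        manifest.outputs["venn_summary.json"] = str(out / "venn_summary.json")
        log.info("stage screen: %d assays, %d differential", venn.n_screened, venn.n_diff_total)

    sites_df = None
    if "seedmatch" in cfg:
        pc = cfg["seedmatch"] or {}
        if transcripts is None:
            for key in ("mirnas", "transcripts", "regions"):
                manifest.input_checksums[pc[key]] = _sha256(pc[key])
            mirnas = seed_match.read_mirna_fasta(pc["mirnas"])
            transcripts = seed_match.read_transcripts(pc["transcripts"], pc["regions"])
        all_sites = []
        for m in mirnas:
            for tr in transcripts:
                all_sites.extend(
                    seed_match.find_seed_sites(
                        m, tr,
                        max_mismatch=pc.get("max_mismatch", 2),
                        allow_wobble=pc.get("allow_wobble", False),
                    )
                )
        seed_match.write_sites_tsv(all_sites, out / "seed_sites.tsv")
        seed_match.write_alignments(all_sites, out / "alignments.txt")
        manifest.outputs["seed_sites.tsv"] = str(out / "seed_sites.tsv")
        sites_df = pd.DataFrame([dataclasses.asdict(s) for s in all_sites])
        log.info("stage seedmatch: %d sites", len(all_sites))

    if "enrich" in cfg:
        pc = cfg["enrich"] or {}
        if "scores" in pc:
            manifest.input_checksums[pc["scores"]] = _sha256(pc["scores"])
            table = pd.read_csv(pc["scores"], sep="\t")
        else:
            if sites_df is None or sites_df.empty:
                raise ConfigError("enrich stage needs a 'scores' table or seedmatch sites")
            regulated = set(pc.get("regulated", []))
            rows = []
            for (mid, gid), sub in sites_df.groupby(["mirna_id", "gene_id"]):
                sites = [seed_match.SeedSite(**{k: v for k, v in r.items()})
                         for r in sub.to_dict("records")]
                rows.append(
                    {
                        "mirna_id": mid,
                        "gene_id": gid,
                        "score": seed_enrichment.gene_binding_score(sites),
                        "regulated": gid in regulated,
                    }
                )
            table = pd.DataFrame(rows)
        res = seed_enrichment.enrich_all(table, threshold=pc.get("threshold", 0.5))
        pd.DataFrame([dataclasses.asdict(r) for r in res]).to_csv(
            out / "enrichment.tsv", sep="\t", index=False
        )
        manifest.outputs["enrichment.tsv"] = str(out / "enrichment.tsv")

    if "quant" in cfg:
        pc = cfg["quant"] or {}
        if records is None:
            manifest.input_checksums[pc["records"]] = _sha256(pc["records"])
            records = pd.read_csv(pc["records"])
        rel, cells = rel_quant.relative_expression(
            records, calibrator=pc.get("calibrator", "Con-F")
        )
        rel.to_csv(out / "relative_expression.tsv", sep="\t", index=False)
        cells.to_csv(out / "cell_summary.tsv", sep="\t", index=False)
        manifest.outputs["relative_expression.tsv"] = str(out / "relative_expression.tsv")
        manifest.outputs["cell_summary.tsv"] = str(out / "cell_summary.tsv")

    if "associate" in cfg:
        pc = cfg["associate"] or {}
        if cohort is None:
            manifest.input_checksums[pc["cohort"]] = _sha256(pc["cohort"])
            cohort = pd.read_csv(pc["cohort"])
        rows = []
        for spec in pc.get("models", [{"outcome": "birthweight_g", "predictor": "pl_tau"}]):
            for model in (1, 2):
                r = assoc_stats.association_model(
                    spec["outcome"], spec["predictor"], model, cohort,
                    postnatal=spec.get("postnatal", False),
                )
                rows.append(
                    {
                        "outcome": r.outcome, "predictor": r.predictor,
                        "model": r.model, "n": r.n, "beta": r.beta,
                        "ci_low": r.ci95[0], "ci_high": r.ci95[1], "p": r.p,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "associations.tsv", sep="\t", index=False)
        manifest.outputs["associations.tsv"] = str(out / "associations.tsv")

    for name, path in manifest.outputs.items():
        manifest.output_checksums[name] = _sha256(path)
    manifest.finished = time.time()
    manifest.to_json(out / "manifest.json")
    return manifest
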