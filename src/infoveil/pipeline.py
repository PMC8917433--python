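"""End-to-end orchestration: simulate/load -> filter -> classify -> sample
-> validate, driven by one YAML config and one root seed.

All randomness flows from the root seed: stage k uses the generator seeded
by ``numpy.random.SeedSequence(seed, spawn_key=(k,))``, so re-running with
the same config and inputs is bit-reproducible and stages stay independent.
The run manifest records the config hash, per-stage filter reports and the
paths of every artifact written.

Config layout (all sections optional except a corpus source)::

    seed: 17
    output_dir: out
    lexicon: demo            # or a path to a TSV lexicon
    corpus: posts.jsonl      # or a `simulate:` section of SimulationConfig fields
    bot_threshold: 4.0
    allocation: {Mental health: 50, Pain: 20}   # or `sample_size: 200`
    validate: true           # simulated dual coding (needs `simulate:`)
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .classifier import classify_corpus
from .corpus import (
    FilterReport,
    count_unique_accounts,
    filter_bots,
    filter_seed_terms,
    load_corpus,
    remove_retweets,
    write_corpus,
)
from .errors import PipelineError
from .lexicon import demo_lexicon, load_lexicon
from .registry import SEED_TERMS
from .synthetic import SimulationConfig, generate_annotations, generate_corpus
from .validation import (
    adjudicate,
    build_validation_table,
    cohens_kappa,
    kappa_by_stratum,
    kappa_range,
    stratified_sample,
    write_annotations,
)

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """What a pipeline run did: config identity, stage audit, artifacts."""

    config_hash: str
    seed: int
    version: str
    stages: list[dict[str, Any]] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)

    def record_stage(self, name: str, report: FilterReport | None = None, **extra) -> None:
        entry: dict[str, Any] = {"stage": name}
        if report is not None:
            entry["report"] = dataclasses.asdict(report)
        entry.update(extra)
        self.stages.append(entry)
        logger.info("stage %s: %s", name, {k: v for k, v in entry.items() if k != "stage"})

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def _stage_seed(root: int, k: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(root, spawn_key=(k,))


def load_config(path: str | Path) -> dict:
    with Path(path).open(encoding="utf-8") as handle:
        return yaml.safe_load(handle)


def run_pipeline(config: dict | str | Path) -> RunManifest:
    """Execute the configured stage sequence; write artifacts and manifest.

    Any stage failure is re-raised as :class:`PipelineError` carrying the
    stage name, after the partial manifest (with the failure recorded) is
    written to the output directory.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    seed = int(config.get("seed", 0))
    out_dir = Path(config.get("output_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_config_hash(config), seed=seed, version=__version__)
    stage = "setup"
    try:
        lexicon_spec = config.get("lexicon", "demo")
        lexicon = demo_lexicon() if lexicon_spec == "demo" else load_lexicon(lexicon_spec)
        seed_terms = tuple(config.get("seed_terms", SEED_TERMS))

        stage = "corpus"
        truth = None
        if "simulate" in config:
            sim_seed = int(
                _stage_seed(seed, 0).generate_state(1, dtype=np.uint32)[0] % (2**31)
            )
            sim = SimulationConfig(**{**config["simulate"], "seed": sim_seed})
            records, truth = generate_corpus(sim, lexicon, seed_terms)
            corpus_path = out_dir / "corpus.jsonl"
            write_corpus(records, corpus_path)
            manifest.outputs["corpus"] = str(corpus_path)
            manifest.record_stage("simulate", n_posts=len(records), sim_seed=sim_seed)
        else:
            records, skipped = load_corpus(config["corpus"])
            manifest.record_stage("read", n_posts=len(records), n_skipped=skipped)

        stage = "filter"
        records, seed_report = filter_seed_terms(records, seed_terms)
        manifest.record_stage("seed_terms", seed_report)
        records, rt_report = remove_retweets(records)
        manifest.record_stage("retweets", rt_report)
        records, bot_report = filter_bots(records, float(config.get("bot_threshold", 4.0)))
        manifest.record_stage("bots", bot_report)
        filtered_path = out_dir / "filtered.jsonl"
        write_corpus(records, filtered_path)
        manifest.outputs["filtered"] = str(filtered_path)

        stage = "classify"
        assignments, freq_table, health_subset = classify_corpus(records, lexicon)
        freq_path = out_dir / "category_frequencies.csv"
        freq_table.to_frame().to_csv(freq_path, index=False)
        assign_path = out_dir / "assignments.jsonl"
        with assign_path.open("w", encoding="utf-8") as handle:
            for a in assignments:
                handle.write(
                    json.dumps(
                        {
                            "post_id": a.post_id,
                            "categories": sorted(a.categories),
                            "evidence": {c: sorted(s) for c, s in a.evidence.items()},
                        }
                    )
                    + "\n"
                )
        manifest.outputs["assignments"] = str(assign_path)
        manifest.outputs["category_frequencies"] = str(freq_path)
        manifest.record_stage(
            "classify",
            n_classified=len(assignments),
            health_subset=len(health_subset),
            unique_accounts=count_unique_accounts(records),
        )

        stage = "sample"
        sample = None
        sample_seed = int(
            _stage_seed(seed, 1).generate_state(1, dtype=np.uint32)[0] % (2**31)
        )
        allocation = config.get("allocation")
        if allocation is None and "sample_size" in config:
            # same seed as the sampler so stratum membership agrees exactly
            allocation = _proportional_allocation(
                assignments, int(config["sample_size"]), sample_seed
            )
        if allocation:
            sample = stratified_sample(assignments, allocation, sample_seed)
            sample_path = out_dir / "sample.csv"
            sample.to_csv(sample_path, index=False)
            manifest.outputs["sample"] = str(sample_path)
            manifest.record_stage("sample", n_sampled=len(sample), sample_seed=sample_seed)
        else:
            manifest.record_stage("sample", n_sampled=0, note="no allocation / empty strata")

        stage = "validate"
        if config.get("validate") and sample is not None and truth is not None and len(sample):
            ann_seed = int(
                _stage_seed(seed, 2).generate_state(1, dtype=np.uint32)[0] % (2**31)
            )
            sim_cfg = SimulationConfig(**{**config.get("simulate", {}), "seed": seed})
            sample_ids = list(sample["post_id"])
            ann_a, ann_b = generate_annotations(truth, sample_ids, sim_cfg, seed=ann_seed)
            write_annotations(ann_a, out_dir / "coder_a.csv")
            write_annotations(ann_b, out_dir / "coder_b.csv")
            resolutions = {
                p: truth.labels[p]
                for a, b in zip(ann_a, ann_b)
                if a.label != b.label
                for p in [a.post_id]
            }
            adjudicated = adjudicate(ann_a, ann_b, resolutions)
            strata = dict(zip(sample["post_id"], sample["stratum"]))
            table = build_validation_table(adjudicated, strata)
            table_path = out_dir / "validation_table.csv"
            table.to_frame().to_csv(table_path, index=False)
            overall = cohens_kappa(ann_a, ann_b)
            per_stratum = kappa_by_stratum(ann_a, ann_b, strata)
            kappa_payload: dict[str, Any] = {
                "overall": dataclasses.asdict(overall),
                "per_stratum": {
                    s: dataclasses.asdict(r) for s, r in sorted(per_stratum.items())
                },
            }
            if per_stratum:
                lo, hi = kappa_range(per_stratum)
                kappa_payload["range"] = [lo, hi]
            kappa_path = out_dir / "kappa.json"
            kappa_path.write_text(json.dumps(kappa_payload, indent=2, sort_keys=True))
            manifest.outputs["validation_table"] = str(table_path)
            manifest.outputs["kappa"] = str(kappa_path)
            manifest.record_stage(
                "validate",
                n_annotated=table.n_annotated,
                health_related_percent=table.health_related_percent,
                kappa=overall.kappa,
            )
    except Exception as exc:
        manifest.record_stage("error", failed_stage=stage, cause=str(exc))
        (out_dir / "manifest.json").write_text(manifest.to_json())
        raise PipelineError(stage, exc) from exc
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(manifest.to_json())
    manifest.outputs["manifest"] = str(manifest_path)
    return manifest


def _proportional_allocation(assignments, total: int, seed: int) -> dict[str, int]:
    """Allocate ``total`` draws across strata proportionally to stratum size.

    Stratum membership is resolved with the same seeded uniform-choice rule
    (and the same seed) sampling itself uses, so the allocation never
    exceeds a realized stratum population.
    """
    rng = np.random.default_rng(seed)
    sizes: dict[str, int] = {}
    for a in sorted(assignments, key=lambda x: x.post_id):
        cats = sorted(a.categories)
        if cats:
            stratum = cats[rng.integers(len(cats))]
            sizes[stratum] = sizes.get(stratum, 0) + 1
    population = sum(sizes.values())
    if population == 0:
        return {}
    total = min(total, population)
    allocation = {
        s: min(sizes[s], int(round(total * sizes[s] / population))) for s in sorted(sizes)
    }
    return {s: n for s, n in allocation.items() if n > 0}
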