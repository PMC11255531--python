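"""End-to-end pipeline: filter -> resolve victims -> embed -> score -> stats.

The pipeline is configured by a YAML file (see :class:`PipelineConfig`) and
writes five artifacts into the output directory:

* ``scores.csv`` — victim x frame cosine similarity table
* ``comparisons.json`` — per-frame Mann-Whitney gender comparison
* ``mi_matrix.csv`` — circumstance x frame between-gender MI (bits,
  higher = more divergent)
* ``circumstance_table.csv`` — gender x circumstance attribution counts
* ``run_log.json`` — config, versions and seed for provenance

Outputs are bitwise-reproducible for a fixed config and seed with the hash
backend.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy
import yaml

from . import __version__
from .corpus import (
    DEFAULT_RULES,
    FilterRuleSet,
    filter_corpus,
    read_annotations,
    read_corpus,
    resolve_corpus,
)
from .embedding import make_backend
from .lexicon import default_lexicons, read_lexicons
from .scoring import frame_vectors, score_corpus, write_scores
from .stats import compare_by_gender, circumstance_table, stratified_mi
from .corpus import TOP_CIRCUMSTANCES

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    corpus: str
    annotations: str
    output_dir: str
    lexicons: str | None = None  # CSV; None -> built-in example seeds
    filter_rules: str | None = None  # YAML; None -> built-in default rules
    apply_filter: bool = True
    backend: str = "hash"
    dimension: int = 256
    model_name: str = "all-MiniLM-L6-v2"
    bins: int | str = 10
    gender_pair: tuple[str, str] = ("cis_male", "cis_female")
    frames: tuple[str, ...] | None = None  # None -> all frames in the lexicons
    circumstances: tuple[str, ...] = TOP_CIRCUMSTANCES
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "gender_pair" in data:
            data["gender_pair"] = tuple(data["gender_pair"])
        if "frames" in data and data["frames"] is not None:
            data["frames"] = tuple(data["frames"])
        if "circumstances" in data:
            data["circumstances"] = tuple(data["circumstances"])
        return cls(**data)

    def validate(self) -> None:
        for name in ("corpus", "annotations"):
            p = getattr(self, name)
            if not Path(p).is_file():
                raise PipelineError(f"config.{name}: file not found: {p}")
        for name in ("lexicons", "filter_rules"):
            p = getattr(self, name)
            if p is not None and not Path(p).is_file():
                raise PipelineError(f"config.{name}: file not found: {p}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a summary dict and writes all artifacts.

    Any stage failure raises :class:`PipelineError` naming the stage; no
    partial outputs are left behind in that case (artifacts are written only
    after all computation succeeds).
    """
    config.validate()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    articles = stage("read_corpus", read_corpus, config.corpus)
    annotations = stage("read_annotations", read_annotations, config.annotations)

    if config.apply_filter:
        rules = (
            FilterRuleSet.from_yaml(config.filter_rules)
            if config.filter_rules
            else DEFAULT_RULES
        )
        articles, exclusion_report = stage("filter", filter_corpus, articles, rules)
    else:
        exclusion_report = {}

    victims = stage("resolve_victims", resolve_corpus, articles, annotations)
    if not victims:
        raise PipelineError("stage 'resolve_victims' failed: no victim records")

    lexicons = (
        stage("read_lexicons", read_lexicons, config.lexicons)
        if config.lexicons
        else default_lexicons()
    )
    backend = stage(
        "backend", make_backend,
        backend=config.backend, dimension=config.dimension,
        seed=config.seed, model_name=config.model_name,
    )
    frames = stage("frame_vectors", frame_vectors, lexicons, backend)
    scores = stage("score", score_corpus, victims, frames, backend)

    frame_names = config.frames or tuple(lex.frame for lex in lexicons)
    comparisons = stage(
        "compare", compare_by_gender, scores, frame_names, config.gender_pair
    )
    mi_matrix = stage(
        "stratified_mi", stratified_mi, scores, frame_names,
        config.circumstances, config.bins, config.gender_pair,
    )
    table = stage("circumstance_table", circumstance_table, annotations,
                  config.circumstances)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_scores(scores, out / "scores.csv")
    comparison_payload = {
        c.frame: {
            "groups": list(c.group_labels),
            "n": [c.n_a, c.n_b],
            "mean": [c.mean_a, c.mean_b],
            "U": c.U,
            "p": c.p,
            "method": c.method,
        }
        for c in comparisons
    }
    with open(out / "comparisons.json", "w", encoding="utf-8") as fh:
        json.dump(comparison_payload, fh, indent=2, sort_keys=True)
    mi_matrix.write_csv(out / "mi_matrix.csv")
    table.write_csv(out / "circumstance_table.csv")

    run_log = {
        "newsframing_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "python_version": platform.python_version(),
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "seed": config.seed,
        "backend": backend.name,
        "n_articles": len(articles),
        "n_victims": len(victims),
        "exclusion_report": exclusion_report,
    }
    with open(out / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)

    return {
        "n_articles": len(articles),
        "n_victims": len(victims),
        "comparisons": comparison_payload,
        "mi": mi_matrix,
        "table": table,
        "outputs": sorted(p.name for p in out.iterdir()),
    }
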