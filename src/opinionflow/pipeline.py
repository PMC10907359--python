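"""End-to-end pipeline: generate -> keywords -> cluster -> concern -> consensus.

One :class:`RunConfig` drives the whole loop: synthetic event corpora are
generated for a sequence of chronological checkpoints, keywords are
extracted and clustered into the dimension/indicator system, concern
profiles yield a satisfaction rate and discrete opinion state per
checkpoint, and the opinion sequence is filtered through (and simulated
from) the opinion-policy hidden Markov model.  Every artifact is written to
the output directory and recorded, with its SHA-256 hash, in a JSON run
manifest; a fixed master seed makes the entire run byte-reproducible.

The default four checkpoints mirror the case study's analyzed timeline —
a transit accident during the epidemic (satisfaction high, ~0.73 original-
event weight), a national policy revision (0.37), a deadly fire (0.35), and
a provincial policy promotion (0.29) — with per-event corpus sizes taken
from the study's crawl sizes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .cluster import (
    assign_clusters_to_indicators,
    build_word_vectors,
    clustering_frame,
    kmeans,
    synthetic_lexicon,
)
from .concern import concern_profile, opinion_sequence, token_dimensions
from .corpus import GeneratorConfig, generate_corpus, write_corpus
from .hmm import default_spec, derive_seeds, forward_filter, simulate_ensemble
from .tfidf import tfidf_scores, top_keywords

__all__ = ["CheckpointConfig", "RunConfig", "PipelineStageError", "run_pipeline"]


@dataclass(frozen=True)
class CheckpointConfig:
    """One chronological event checkpoint of the opinion timeline."""

    name: str
    n_docs: int
    original_weight: float  # remaining mass is split over the other dimensions

    def dimension_weights(self) -> tuple[float, float, float, float]:
        rest = (1.0 - self.original_weight) / 3.0
        return (self.original_weight, rest, rest, rest)


def _default_checkpoints() -> list[CheckpointConfig]:
    return [
        CheckpointConfig("guizhou_accident", 716, 0.73),
        CheckpointConfig("rules20_policy", 1844, 0.37),
        CheckpointConfig("xinjiang_fire", 1013, 0.35),
        CheckpointConfig("zhejiang_policy", 622, 0.29),
    ]


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    checkpoints: list[CheckpointConfig] = field(default_factory=_default_checkpoints)
    separation: float = 0.95
    doc_length_mean: float = 20.0
    concentration: float = 0.5
    vocab_size: int = 250
    background_vocab_size: int = 500
    top_k: int = 100
    top_small: int = 20
    n_clusters: int | None = None  # default: number of lexicon indicators
    n_restarts: int = 10
    thresholds: tuple[float, float] = (0.4, 0.6)
    statistic: str = "balanced_depth"
    hmm_runs: int = 10
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "checkpoints" in d:
            d["checkpoints"] = [CheckpointConfig(**c) for c in d["checkpoints"]]
        if "thresholds" in d:
            d["thresholds"] = tuple(d["thresholds"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data or {})

    def generator_configs(self) -> list[GeneratorConfig]:
        """Per-checkpoint generator configs (validates all parameters)."""
        seeds = derive_seeds(self.seed, len(self.checkpoints))
        return [
            GeneratorConfig(
                event_name=cp.name,
                n_docs=cp.n_docs,
                dimension_weights=cp.dimension_weights(),
                separation=self.separation,
                vocab_sizes=(self.vocab_size,) * 4,
                background_vocab_size=self.background_vocab_size,
                doc_length_mean=self.doc_length_mean,
                concentration=self.concentration,
                seed=s,
            )
            for cp, s in zip(self.checkpoints, seeds)
        ]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute all stages in order and return the run manifest.

    Any stage failure raises :class:`PipelineStageError` naming the stage;
    artifacts written before the failure are retained.  Identical configs
    (including the master seed) produce byte-identical artifacts and
    therefore identical manifest hashes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    stage = "validate"
    try:
        gen_configs = config.generator_configs()
        kmeans_seed, hmm_seed = derive_seeds(config.seed + 1, 2)

        stage = "generate"
        corpora = []
        for gc in gen_configs:
            corpus = generate_corpus(gc)
            path = outdir / f"corpus_{gc.event_name}.jsonl"
            write_corpus(corpus, path)
            files += [path, path.with_name(path.stem + ".truth.json")]
            corpora.append(corpus)

        stage = "keywords"
        tables = []
        for gc, corpus in zip(gen_configs, corpora):
            stats = tfidf_scores(corpus)
            table = top_keywords(stats, config.top_k)
            small = top_keywords(stats, config.top_small, previous=table)
            for tab, tag in ((table, f"top{config.top_k}"), (small, f"top{config.top_small}")):
                path = outdir / f"keywords_{gc.event_name}_{tag}.csv"
                tab.to_frame().to_csv(path, index=False)
                files.append(path)
            tables.append(table)

        stage = "cluster"
        lexicon = synthetic_lexicon(corpora[0])
        lex_path = outdir / "lexicon.json"
        lexicon.to_json(lex_path)
        files.append(lex_path)
        k = config.n_clusters or lexicon.n_indicators
        token_maps = []
        for gc, corpus, table in zip(gen_configs, corpora, tables):
            vectors = build_word_vectors(corpus, table)
            result = kmeans(
                vectors, k=k, seed=kmeans_seed, n_restarts=config.n_restarts
            )
            mapping = assign_clusters_to_indicators(result, lexicon)
            path = outdir / f"clusters_{gc.event_name}.csv"
            clustering_frame(result, mapping).to_csv(path, index=False)
            files.append(path)
            token_maps.append(token_dimensions(result, mapping))

        stage = "concern"
        profiles = [
            concern_profile(table, tmap, event=gc.event_name)
            for gc, table, tmap in zip(gen_configs, tables, token_maps)
        ]
        observations = opinion_sequence(
            profiles, thresholds=config.thresholds, statistic=config.statistic
        )
        concern_path = outdir / "concern.csv"
        rows = []
        for p, o in zip(profiles, observations):
            rows.append(
                {"event": p.event, **p.shares,
                 "satisfaction": o.satisfaction, "state": o.state}
            )
        pd.DataFrame(rows).to_csv(concern_path, index=False)
        files.append(concern_path)
        obs_path = outdir / "opinion_sequence.json"
        obs_path.write_text(
            json.dumps(
                [dataclasses.asdict(o) for o in observations], indent=2, sort_keys=True
            )
        )
        files.append(obs_path)

        stage = "hmm"
        spec = default_spec()
        spec_path = outdir / "hmm_spec.json"
        spec.to_json(spec_path)
        files.append(spec_path)
        posteriors, loglik = forward_filter(spec, observations)
        post_path = outdir / "policy_posteriors.csv"
        pd.DataFrame(
            {
                "t": range(1, len(observations) + 1),
                "event": [o.event for o in observations],
                "observation": [o.state for o in observations],
                "p_continue": posteriors[:, 0],
                "p_change": posteriors[:, 1],
            }
        ).to_csv(post_path, index=False)
        files.append(post_path)
        summary = simulate_ensemble(
            spec, T=len(observations), n_runs=config.hmm_runs, seed=hmm_seed
        )
        ens_path = outdir / "ensemble_summary.csv"
        pd.DataFrame(
            {
                "t": range(1, summary.T + 1),
                "mean_state": summary.mean_state,
                "mean_observation": summary.mean_observation,
            }
        ).to_csv(ens_path, index=False)
        files.append(ens_path)
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {"kmeans": kmeans_seed, "hmm": hmm_seed},
        "config": _config_dict(config),
        "log_likelihood": loglik,
        "files": {p.name: _sha256(p) for p in sorted(files)},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _config_dict(config: RunConfig) -> dict[str, Any]:
    d = dataclasses.asdict(config)
    d["thresholds"] = list(config.thresholds)
    return d
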