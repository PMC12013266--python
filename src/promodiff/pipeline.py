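"""End-to-end promoter design workflow.

The full loop mirrors how a promoter-engineering study uses these pieces:

1. load (or synthesize) a natural promoter dataset and split it 4:1;
2. train the diffusion generator on the training sequences and sample a
   batch of candidate promoters;
3. train the transformer strength predictor on the labelled training split;
4. score and rank the generated candidates by predicted strength
   (normalized and raw scales side by side);
5. evaluate the generated set against the natural set (k-mer PCCs,
   sequence-logo matrices, positional profiles of the top natural 6-mers);
6. optionally run the saturation-mutagenesis scan on the test split.

Everything is driven by a :class:`RunConfig` (YAML-loadable); one global seed
spawns a named sub-seed per stage, so a rerun with the same config reproduces
every numeric output.  The report is machine-readable JSON plus CSV/FASTA
artifacts; each table carries the package version and config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .diffusion import DiffusionConfig, train_ddpm
from .fixtures import FixtureSpec, generate_fixture
from .metrics import kmer_pcc, logo_matrix, positional_profile, top_kmers
from .mutagenesis import (
    records_to_frame,
    region_contrast,
    position_summaries,
    saturation_mutagenesis,
    summaries_to_frame,
)
from .predictor import (
    PredictorConfig,
    evaluate_predictor,
    train_cnn_baseline,
    train_predictor,
)
from .sequence_codec import (
    ConfigurationError,
    PromoterDataset,
    read_promoter_table,
    split_dataset,
    write_fasta,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "validate_config", "run_design_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end design run."""

    out_dir: str = "promodiff_run"
    natural_path: str | None = None  # None → generate the built-in fixture
    seq_column: str = "sequence"
    strength_column: str = "strength"
    fixture: FixtureSpec = field(default_factory=FixtureSpec)
    test_fraction: float = 0.2
    n_generate: int = 500
    diffusion: DiffusionConfig = field(default_factory=DiffusionConfig)
    predictor: PredictorConfig = field(default_factory=PredictorConfig)
    architecture: str = "transformer"
    evaluation_ks: tuple[int, ...] = (2, 3, 4, 5, 6)
    evaluation_kmers: tuple[str, ...] | None = None  # None → top natural 6-mers
    mutagenesis_sample_size: int | None = 200
    mutagenesis_regions: tuple[tuple[int, int], ...] = ((-36, -31), (-12, -7))
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(_to_plain(asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _to_plain(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it, partial outputs remain."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _build_dataclass(cls, raw: dict, errors: list[str], prefix: str):
    known = {f.name for f in fields(cls)}
    kwargs = {}
    for key, value in raw.items():
        if key not in known:
            logger.warning("ignoring unknown config key %s.%s", prefix, key)
            continue
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{prefix}: {exc}")
        return cls()


def validate_config(path: str | Path) -> RunConfig:
    """Load and type-check a YAML run config; errors are aggregated.

    Unknown keys produce warnings, not errors, so configs stay forward
    compatible.  Raises :class:`ConfigurationError` listing every problem.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"unparseable config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(raw)}")

    errors: list[str] = []
    nested = {
        "diffusion": DiffusionConfig,
        "predictor": PredictorConfig,
        "fixture": FixtureSpec,
    }
    kwargs: dict[str, Any] = {}
    known = {f.name for f in fields(RunConfig)}
    for key, value in raw.items():
        if key not in known:
            logger.warning("ignoring unknown config key %s", key)
            continue
        if key in nested:
            if not isinstance(value, dict):
                errors.append(f"{key}: expected a mapping")
                continue
            kwargs[key] = _build_dataclass(nested[key], value, errors, key)
        else:
            kwargs[key] = value
    if "evaluation_kmers" in kwargs and kwargs["evaluation_kmers"] is not None:
        kwargs["evaluation_kmers"] = tuple(kwargs["evaluation_kmers"])
    if "evaluation_ks" in kwargs:
        kwargs["evaluation_ks"] = tuple(kwargs["evaluation_ks"])
    if "mutagenesis_regions" in kwargs:
        kwargs["mutagenesis_regions"] = tuple(
            tuple(r) for r in kwargs["mutagenesis_regions"]
        )
    config: RunConfig | None = None
    try:
        config = RunConfig(**kwargs)
        if not 0 < config.test_fraction < 1:
            errors.append(
                f"test_fraction: must be in (0, 1), got {config.test_fraction}"
            )
    except (TypeError, ValueError) as exc:
        errors.append(str(exc))
    if errors:
        raise ConfigurationError("; ".join(errors))
    assert config is not None
    return config


def _write_table(frame, path: Path, meta: dict[str, str]) -> None:
    header = "".join(f"# {k}: {v}\n" for k, v in meta.items())
    path.write_text(header + frame.to_csv(index=False))


def run_design_pipeline(config: RunConfig) -> dict:
    """Run the full design loop and return the report dict (also written to
    ``out_dir/report.json``)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"promodiff_version": __version__, "config_hash": config.config_hash()}
    report: dict[str, Any] = {"metadata": dict(meta, seed=config.seed)}
    seeds = np.random.SeedSequence(config.seed).spawn(5)
    sub_seed = [int(s.generate_state(1)[0] % 2**31) for s in seeds]

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    _dump_report()
                    raise StageError(name, exc) from exc
                logger.info(
                    "stage %s: done in %.1fs", name, time.perf_counter() - self_inner.t0
                )
                return False

        return _Stage()

    def _dump_report():
        (out_dir / "report.json").write_text(
            json.dumps(_to_plain(report), indent=2)
        )

    with stage("load_data"):
        if config.natural_path is None:
            spec = replace(config.fixture, seed=sub_seed[0])
            dataset = generate_fixture(spec)
        else:
            dataset = read_promoter_table(
                config.natural_path,
                seq_column=config.seq_column,
                strength_column=config.strength_column,
            )
        train, test = split_dataset(dataset, config.test_fraction, seed=sub_seed[0])
        report["data"] = {
            "n_total": len(dataset),
            "n_train": len(train),
            "n_test": len(test),
            "sequence_length": dataset.sequence_length,
        }

    with stage("generation"):
        diff_cfg = replace(config.diffusion, seed=sub_seed[1])
        generator = train_ddpm(train, diff_cfg)
        generated = generator.sample(config.n_generate, seed=sub_seed[1])
        write_fasta(generated, out_dir / "generated.fasta")
        _write_table(generator.log.to_frame(), out_dir / "diffusion_log.csv", meta)
        report["generation"] = {
            "n_generated": len(generated),
            "epochs": diff_cfg.epochs,
            "initial_heldout_l1": generator.log.heldout_l1[0],
            "final_heldout_l1": generator.log.heldout_l1[-1],
        }

    with stage("screening"):
        pred_cfg = replace(config.predictor, seed=sub_seed[2])
        trainer = train_predictor if config.architecture == "transformer" else train_cnn_baseline
        model = trainer(train, pred_cfg)
        test_pcc = evaluate_predictor(model, test)
        norm_scores = model.predict(generated)
        raw_scores = model.predict(generated, scale="raw")
        order = np.argsort(-norm_scores)
        import pandas as pd

        ranked = pd.DataFrame(
            {
                "rank": np.arange(1, len(generated) + 1),
                "sequence": [generated[i] for i in order],
                "predicted_norm": norm_scores[order],
                "predicted_raw": raw_scores[order],
            }
        )
        _write_table(ranked, out_dir / "ranked_candidates.csv", meta)
        model.save(out_dir / "predictor.json")
        report["screening"] = {
            "architecture": config.architecture,
            "test_pcc": test_pcc,
            "top_predicted_norm": float(norm_scores[order[0]]),
        }

    with stage("evaluation"):
        natural_seqs = train.sequences
        pccs = {
            int(k): kmer_pcc(generated, natural_seqs, k) for k in config.evaluation_ks
        }
        kmers = (
            list(config.evaluation_kmers)
            if config.evaluation_kmers
            else top_kmers(natural_seqs, k=6, count=6)
        )
        profiles = []
        for kmer in kmers:
            for label, seqs in (("natural", natural_seqs), ("generated", generated)):
                frame = positional_profile(seqs, kmer).to_frame()
                frame.insert(0, "set", label)
                profiles.append(frame)
        import pandas as pd

        _write_table(pd.concat(profiles), out_dir / "positional_profiles.csv", meta)
        for label, seqs in (("natural", natural_seqs), ("generated", generated)):
            _write_table(
                logo_matrix(seqs).to_frame(), out_dir / f"logo_{label}.csv", meta
            )
        report["evaluation"] = {"kmer_pcc": pccs, "profiled_kmers": kmers}

    if config.mutagenesis_sample_size:
        with stage("mutagenesis"):
            n_scan = min(config.mutagenesis_sample_size, len(test))
            records = saturation_mutagenesis(
                test, model, sample_size=n_scan, seed=sub_seed[3]
            )
            summaries = position_summaries(records)
            contrast = region_contrast(summaries, config.mutagenesis_regions)
            _write_table(records_to_frame(records), out_dir / "mutations.csv", meta)
            _write_table(
                summaries_to_frame(summaries), out_dir / "mutation_summary.csv", meta
            )
            _write_table(contrast, out_dir / "region_contrast.csv", meta)
            report["mutagenesis"] = {
                "sample_size": n_scan,
                "n_records": len(records),
                "region_contrast": contrast.to_dict(orient="records"),
            }

    _dump_report()
    return report
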