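"""Run configuration, stage-seed derivation and the end-to-end pipeline."""

from __future__ import annotations

import hashlib
import json
import traceback
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as vio
from .errors import ConfigurationError, VdlinError
from .grammar import default_grammar, encode_smiles
from .model import ModelConfig, VdlinModel
from .panel import DEFAULT_PANEL, GenePanel
from .prep import DEFAULT_MIN_REPLICATES, DEFAULT_TAU, prepare_profiles
from .screen import PrimaryCriteria, results_to_frame, screen_library
from .synthetic import SyntheticConfig, generate_library
from .vae import GrammarVae, VaeConfig


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed: stable, and adding a stage never perturbs
    the seeds of earlier stages."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "little") % (2**63)


@dataclass
class RunConfig:
    seed: int = 7
    panel: GenePanel = field(default=DEFAULT_PANEL)
    synthetic: SyntheticConfig | None = None
    min_replicates: int = DEFAULT_MIN_REPLICATES
    tau: float = DEFAULT_TAU
    max_sequence_length: int = 277
    vae: VaeConfig = field(default_factory=VaeConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    criteria: PrimaryCriteria = field(default_factory=PrimaryCriteria)
    min_per_class: int = 3

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        seed = int(raw.get("seed", 7))
        syn = raw.get("synthetic", {}) or {}
        syn.setdefault("seed", stage_seed(seed, "simulate"))
        if "replicate_count_range" in syn:
            syn["replicate_count_range"] = tuple(syn["replicate_count_range"])
        vae_raw = dict(raw.get("vae", {}) or {})
        vae_raw.setdefault("seed", stage_seed(seed, "encode"))
        if "hidden_dims" in vae_raw:
            vae_raw["hidden_dims"] = tuple(vae_raw["hidden_dims"])
        model_raw = dict(raw.get("model", {}) or {})
        model_raw.setdefault("seed", stage_seed(seed, "train"))
        if "conv_blocks" in model_raw:
            model_raw["conv_blocks"] = tuple(tuple(b) for b in model_raw["conv_blocks"])
        prep_raw = raw.get("prep", {}) or {}
        screen_raw = raw.get("screen", {}) or {}
        try:
            return cls(
                seed=seed,
                synthetic=SyntheticConfig(**syn),
                min_replicates=int(prep_raw.get("min_replicates", DEFAULT_MIN_REPLICATES)),
                tau=float(prep_raw.get("tau", DEFAULT_TAU)),
                max_sequence_length=int(raw.get("max_sequence_length", 277)),
                vae=VaeConfig(**vae_raw),
                model=ModelConfig(**model_raw),
                criteria=PrimaryCriteria(
                    score_threshold=float(screen_raw.get("score_threshold", 70.0)),
                    sd_multiplier=float(screen_raw.get("sd_multiplier", 3.5)),
                    background=screen_raw.get("background", "library"),
                ),
                min_per_class=int(screen_raw.get("min_per_class", 3)),
            )
        except TypeError as exc:
            raise ConfigurationError(f"invalid configuration: {exc}") from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


def _stage_manifest(out: Path, stage: str, payload: dict) -> None:
    vio.write_manifest(payload, out / f"{stage}.manifest.json")


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """simulate -> prep -> encode -> train -> predict -> screen, end to end.

    Every stage writes a JSON manifest; a failure leaves partial outputs
    plus a FAILED marker naming the stage. Identical config reproduces
    identical rankings.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        syn = config.synthetic or SyntheticConfig(seed=stage_seed(config.seed, "simulate"))
        library = generate_library(syn)
        vio.write_smi(library, out / "library.smi")
        vio.write_signatures(library, out / "signatures.csv")
        _stage_manifest(out, stage, {"n_compounds": len(library), "seed": syn.seed})

        stage = "prep"
        profiles = prepare_profiles(
            library, config.min_replicates, config.tau, config.panel
        )
        vio.write_profiles(profiles, out / "profiles.csv", config.panel)
        kept = {p.compound_id for p in profiles}
        _stage_manifest(
            out, stage,
            {"n_in": len(library), "n_retained": len(profiles),
             "min_replicates": config.min_replicates, "tau": config.tau},
        )

        stage = "encode"
        grammar = default_grammar(config.max_sequence_length)
        records = [r for r in library if r.compound_id in kept]
        encodings = [encode_smiles(r.smiles, grammar) for r in records]
        vae = GrammarVae(config.vae).fit(encodings)
        latents = vae.encode_matrix(np.stack([e.matrix for e in encodings]))
        ids = [r.compound_id for r in records]
        vio.write_latents(ids, latents, out / "latents.csv")
        _stage_manifest(
            out, stage,
            {"grammar_hash": grammar.hash, "latent_dim": config.vae.latent_dim,
             "n_encoded": len(ids), "seed": config.vae.seed},
        )

        stage = "train"
        Y = np.stack([p.delta for p in profiles])
        model = VdlinModel(config.model, panel=config.panel).train(latents, Y)
        hist = model.history
        with open(out / "training_history.csv", "w") as fh:
            fh.write("epoch,loss,mse,score_term\n")
            for h in hist:
                fh.write(f"{h['epoch']},{h['loss']},{h['mse']},{h['score_term']}\n")
        _stage_manifest(
            out, stage,
            {"final_loss": hist[-1]["loss"], "epochs": len(hist),
             "parameters": model.parameter_count(), "seed": config.model.seed},
        )

        stage = "predict"
        batch = model.predict(latents, compound_ids=ids)
        vio.write_latents(ids, batch.predicted_delta, out / "predictions.csv")

        stage = "screen"
        results, summary = screen_library(
            ids, batch.predicted_delta, config.criteria, config.min_per_class,
            config.panel, null_seed=stage_seed(config.seed, "screen"),
        )
        results_to_frame(results).to_csv(out / "screen.csv", index=False)
        _stage_manifest(out, stage, summary)
    except Exception as exc:
        (out / "FAILED").write_text(
            f"stage: {stage}\nerror: {exc}\n\n{traceback.format_exc()}"
        )
        raise VdlinError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    vio.write_manifest(
        {"seed": config.seed, "stages": ["simulate", "prep", "encode", "train",
                                         "predict", "screen"]},
        out / "run.manifest.json",
    )
    return out
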