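"""YAML configuration tree and run manifests.

The config mirrors the standard hyperparameter set: an empty file loads
the full defaults (learning rate 0.001, 20 epochs, batch 64, dropout 0.2,
kernel 5 / padding 2, k = 3). Unknown keys are rejected and validation
errors name the offending key. One user-facing seed fans out to
per-component seeds through :func:`deeparc.estimator.derive_seed`.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path

import pydantic
import yaml


class ConfigError(ValueError):
    pass


class _Section(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid", validate_assignment=True,
                                       protected_namespaces=())


class DataConfig(_Section):
    n_pos: int = pydantic.Field(500, gt=0)
    window_length: int = pydantic.Field(101, gt=0)
    split_fracs: tuple[float, float, float] = (0.6, 0.3, 0.1)
    n_motifs_per_positive: int = pydantic.Field(1, gt=0)
    motif_consensus: str = "TGACGTCA"
    negative_mode: str = "dinucleotide"

    @pydantic.field_validator("split_fracs")
    @classmethod
    def _fracs_sum(cls, v):
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError("split_fracs must sum to 1")
        return v

    @pydantic.field_validator("negative_mode")
    @classmethod
    def _neg(cls, v):
        if v not in ("dinucleotide", "mononucleotide"):
            raise ValueError("negative_mode must be 'dinucleotide' or 'mononucleotide'")
        return v


class EmbeddingConfig(_Section):
    variant: str = "positional"
    k: int = pydantic.Field(3, ge=1, le=6)
    d: int = pydantic.Field(100, gt=0)
    window: int = pydantic.Field(5, gt=0)
    epochs: int = pydantic.Field(3, gt=0)

    @pydantic.field_validator("variant")
    @classmethod
    def _variant(cls, v):
        allowed = ("onehot_base", "onehot_kmer", "dna2vec", "positional")
        if v not in allowed:
            raise ValueError(f"variant must be one of {allowed}")
        return v


class ModelConfig(_Section):
    architecture: str = "cnn_bilstm_att"
    cnn_layers: int = pydantic.Field(2, gt=0)
    kernel_size: int = pydantic.Field(5, gt=0)
    padding: int = pydantic.Field(2, ge=0)
    stride: int = pydantic.Field(1, ge=1, le=1)
    cnn_channels: int = pydantic.Field(64, gt=0)
    bilstm_hidden: int | None = pydantic.Field(None, gt=0)
    attention_dim: int | None = pydantic.Field(None, gt=0)
    dense_neurons: int | None = pydantic.Field(None, gt=0)
    dropout: float = pydantic.Field(0.2, ge=0, lt=1)
    merge: str = "sum"

    @pydantic.field_validator("architecture")
    @classmethod
    def _arch(cls, v):
        allowed = ("cnn_bilstm_att", "cnn_bilstm", "bilstm_att")
        if v not in allowed:
            raise ValueError(f"architecture must be one of {allowed}")
        return v

    @pydantic.field_validator("merge")
    @classmethod
    def _merge(cls, v):
        if v not in ("sum", "concat"):
            raise ValueError("merge must be 'sum' or 'concat'")
        return v


class TrainSection(_Section):
    optimizer: str = "adam"
    learning_rate: float = pydantic.Field(0.001, gt=0)
    epochs: int = pydantic.Field(20, gt=0)
    batch_size: int = pydantic.Field(64, gt=0)
    n_repeats: int = pydantic.Field(3, gt=0)
    lr_step: int = pydantic.Field(20, gt=0)
    threshold: float = pydantic.Field(0.5, ge=0, le=1)

    @pydantic.field_validator("optimizer")
    @classmethod
    def _opt(cls, v):
        if v != "adam":
            raise ValueError("optimizer must be 'adam'")
        return v


class Config(_Section):
    data: DataConfig = DataConfig()
    embedding: EmbeddingConfig = EmbeddingConfig()
    model: ModelConfig = ModelConfig()
    train: TrainSection = TrainSection()

    def dump(self) -> dict:
        return json.loads(self.model_dump_json())


def load_config(path: str | Path | None = None) -> Config:
    """Load and validate a YAML config; missing keys fall back to defaults."""
    if path is None:
        return Config()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        return Config()
    try:
        return Config(**raw)
    except pydantic.ValidationError as exc:
        keys = ", ".join(".".join(str(p) for p in err["loc"]) for err in exc.errors())
        raise ConfigError(f"invalid configuration key(s): {keys}\n{exc}") from exc


def dump_config(cfg: Config, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.dump(), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Everything needed to re-execute a run bit-identically (single-threaded):
    the config snapshot, the user seed, content digests of the inputs, the
    package version and a timestamp."""

    command: str
    seed: int
    config: dict
    inputs: dict[str, str] = dataclasses.field(default_factory=dict)
    outputs: list[str] = dataclasses.field(default_factory=list)
    package_version: str = ""
    timestamp: str = ""

    @classmethod
    def create(cls, command: str, seed: int, config: Config,
               input_paths: dict[str, Path] | None = None) -> "RunManifest":
        from . import __version__

        digests = {name: _sha256(Path(p)) for name, p in (input_paths or {}).items()}
        return cls(command=command, seed=seed, config=config.dump(), inputs=digests,
                   package_version=__version__,
                   timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat())

    def write(self, out_dir: str | Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
        return path
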