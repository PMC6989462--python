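"""Application configuration, database lifecycle and structured logging."""

from __future__ import annotations

import hashlib
import json
import logging
import os
import sqlite3
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigurationError
from .schema_model import REGISTRY, SchemaRegistry, SchemaSummary, create_schema

_LOG_LEVELS = ("DEBUG", "INFO", "WARNING", "ERROR")


@dataclass
class AppConfig:
    database_url: str = "cgdm.sqlite"
    vocab_paths: list[str] = field(default_factory=list)
    knowledge_table_paths: list[str] = field(default_factory=list)
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.database_url:
            raise ConfigurationError("database_url must be set")
        if self.log_level not in _LOG_LEVELS:
            raise ConfigurationError(
                f"log_level {self.log_level!r} not in {_LOG_LEVELS}"
            )
        for path in list(self.vocab_paths) + list(self.knowledge_table_paths):
            if not Path(path).exists():
                raise ConfigurationError(f"configured path does not exist: {path}")


def load_config(path: Optional[str] = None) -> AppConfig:
    if path is None:
        config = AppConfig()
    else:
        try:
            with open(path, "rt", encoding="utf-8") as fh:
                data = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise ConfigurationError(f"cannot read config {path}: {exc}") from exc
        unknown = set(data) - {f for f in AppConfig.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {', '.join(sorted(unknown))}")
        config = AppConfig(**data)
    config.validate()
    return config


def config_hash(config: AppConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


def open_connection(database_url: str) -> sqlite3.Connection:
    """Open the embedded database.  Accepts a bare path, ``:memory:`` or a
    ``sqlite:///path`` URL; foreign-key enforcement is switched on."""
    path = database_url
    if path.startswith("sqlite:///"):
        path = path[len("sqlite:///"):]
    elif "://" in path:
        raise ConfigurationError(
            f"unsupported database URL {database_url!r}; only sqlite is embedded"
        )
    connection = sqlite3.connect(path)
    connection.execute("PRAGMA foreign_keys = ON")
    return connection


def init_db(config: AppConfig, *, force: bool = False, dry_run: bool = False,
            registry: SchemaRegistry = REGISTRY) -> SchemaSummary:
    """Create the model schema in the configured database.

    Refuses to touch a database that already contains tables unless ``force``
    is given (then existing model tables are dropped first).
    """
    connection = open_connection(config.database_url)
    try:
        existing = [
            r[0] for r in connection.execute(
                "SELECT name FROM sqlite_master WHERE type = 'table'"
            )
        ]
        if existing and not force:
            raise ConfigurationError(
                f"database {config.database_url} is not empty "
                f"({len(existing)} tables); pass --force to re-initialise"
            )
        if dry_run:
            from .schema_model import introspect_schema

            return introspect_schema(registry)
        if existing and force:
            connection.execute("PRAGMA foreign_keys = OFF")
            for name in existing:
                connection.execute(f"DROP TABLE IF EXISTS {name}")
            connection.execute("PRAGMA foreign_keys = ON")
        return create_schema(connection, registry=registry)
    finally:
        connection.close()


def get_logger(level: str = "INFO") -> logging.Logger:
    """Line-delimited key=value logging on stderr."""
    logger = logging.getLogger("cgdm")
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("ts=%(asctime)s level=%(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)
    return logger


def log_run(logger: logging.Logger, command: str, config: AppConfig,
            inputs: list[str] = ()) -> None:
    """Provenance discipline for the tool itself: version, config hash and
    input hashes on every run."""
    from . import __version__

    parts = [f"event=run command={command} tool=cgdm version={__version__}",
             f"config_hash={config_hash(config)}"]
    for path in inputs:
        if path and os.path.exists(path):
            parts.append(f"input={path} sha256_12={file_hash(path)}")
    logger.info(" ".join(parts))
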