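"""Layered INI configuration and provenance recording.

Configuration comes in two layers: a ``default.ini`` shipped with the
package (reusable repair rules and naming patterns) plus an optional
assembly-specific file whose keys override the defaults key-wise. Values
containing bracketed ``[...]`` expressions are handed to the rule and
pattern grammars, never interpreted by the INI layer itself. Every
resolved key remembers which file supplied it.

The provenance record couples a config snapshot and input checksums with
the ordered modification list accumulated on the graph, giving a complete
and replayable account of an import.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import urllib.request
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

from .naming import ExtractionPattern, parse_pattern
from .rules import Rule, parse_rule


class ConfigError(ValueError):
    pass


def default_config_path() -> Path:
    return Path(str(resources.files("gffmend").joinpath("data/default.ini")))


class Config:
    """Section/key store with per-key source tracking and accessors that
    parse embedded rule and pattern expressions."""

    def __init__(self) -> None:
        self._data: dict[str, dict[str, str]] = {}
        self._source: dict[tuple[str, str], str] = {}

    # -- loading -------------------------------------------------------
    def _layer(self, path: str) -> None:
        cp = configparser.RawConfigParser()
        cp.optionxform = str  # preserve key case (CONDITION_1, GFF, ...)
        try:
            with open(path, encoding="utf-8") as fh:
                cp.read_file(fh, source=path)
        except configparser.Error as exc:
            raise ConfigError(f"INI syntax error in {path}: {exc}") from exc
        for section in cp.sections():
            dest = self._data.setdefault(section, {})
            for key, value in cp.items(section):
                dest[key] = value
                self._source[(section, key)] = str(path)

    @classmethod
    def load(
        cls,
        default_path: Optional[str] = None,
        assembly_path: Optional[str] = None,
    ) -> "Config":
        """Load the default layer then the assembly layer; the assembly
        layer overrides key-wise. A missing default yields an empty base;
        a named-but-absent assembly file is an error."""
        cfg = cls()
        if default_path and Path(default_path).exists():
            cfg._layer(default_path)
        if assembly_path:
            if not Path(assembly_path).exists():
                raise ConfigError(f"config file not found: {assembly_path}")
            cfg._layer(assembly_path)
        return cfg

    # -- access --------------------------------------------------------
    def sections(self) -> list[str]:
        return list(self._data)

    def section(self, name: str) -> dict[str, str]:
        return dict(self._data.get(name, {}))

    def get(self, section: str, key: str, fallback: Optional[str] = None):
        return self._data.get(section, {}).get(key, fallback)

    def source(self, section: str, key: str) -> Optional[str]:
        return self._source.get((section, key))

    def snapshot(self) -> dict:
        return {s: dict(kv) for s, kv in sorted(self._data.items())}

    # -- embedded grammars ---------------------------------------------
    def rules(self, section: str = "GFF") -> list[Rule]:
        """CONDITION_n keys of a section, parsed and ordered by n."""
        items = []
        for key, value in self._data.get(section, {}).items():
            if key.upper().startswith("CONDITION"):
                suffix = key.rsplit("_", 1)[-1]
                try:
                    n = int(suffix)
                except ValueError:
                    n = 10**9
                items.append((n, key, value))
        items.sort(key=lambda t: (t[0], t[1]))
        return [parse_rule(value) for _, _, value in items]

    def patterns(self, section: str) -> list[ExtractionPattern]:
        """Ordered fallback pattern list from a naming section (any key
        whose value is a bracketed expression; keys sorted)."""
        out = []
        for key in sorted(self._data.get(section, {})):
            value = self._data[section][key].strip()
            if value.startswith("["):
                out.append(parse_pattern(value))
        return out


# ---------------------------------------------------------------------------
# input retrieval


def sha256_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def fetch_inputs(
    cfg: Config, cache_dir: str = ".gffmend_cache"
) -> dict[str, dict]:
    """Resolve the [FILES] section to local paths with recorded checksums.

    Remote http/ftp URLs are downloaded once into ``cache_dir`` (repeat
    calls hit the cache); local paths are used in place. Either way the
    sha256 is recorded so provenance pins the exact inputs.
    """
    resolved: dict[str, dict] = {}
    cache = Path(cache_dir)
    for key, value in cfg.section("FILES").items():
        if value.startswith(("http://", "https://", "ftp://")):
            cache.mkdir(parents=True, exist_ok=True)
            name = hashlib.sha1(value.encode()).hexdigest()[:16]
            suffix = Path(value).name
            local = cache / f"{name}_{suffix}"
            if not local.exists():
                try:
                    urllib.request.urlretrieve(value, local)
                except Exception as exc:
                    raise ConfigError(
                        f"[FILES] {key}: cannot retrieve {value}: {exc}"
                    ) from exc
            path = local
        else:
            path = Path(value)
            if not path.exists():
                raise ConfigError(f"[FILES] {key}: file not found: {value}")
        resolved[key] = {
            "url": value,
            "path": str(path),
            "sha256": sha256_file(str(path)),
        }
    return resolved


# ---------------------------------------------------------------------------
# provenance


@dataclass
class ProvenanceRecord:
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    modifications: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "inputs": self.inputs,
                "modifications": self.modifications,
            },
            indent=2,
            sort_keys=True,
        ) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "ProvenanceRecord":
        data = json.loads(text)
        return cls(
            config=data.get("config", {}),
            inputs=data.get("inputs", {}),
            modifications=data.get("modifications", []),
        )
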