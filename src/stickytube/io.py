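"""Config files, tabular I/O and run manifests.

A configuration file is a flat YAML mapping whose keys are the fields of
:class:`~stickytube.params.ChainParams` (chain section) and
:class:`~stickytube.tube.SimulationConfig` (simulation section), either
at top level or under ``chain:`` / ``simulation:``.  Unknown keys are
rejected by name so typos do not silently fall back to defaults.

Every randomised command writes a manifest (JSON) carrying the config
snapshot, the seed, the package version and checksums of the outputs,
which is sufficient to re-run it bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
import time
from dataclasses import fields
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .params import ChainParams
from .tube import SimulationConfig, StretchDistribution

__all__ = [
    "load_config",
    "save_config",
    "write_distribution",
    "read_distribution",
    "write_manifest",
]

_CHAIN_KEYS = {f.name for f in fields(ChainParams)}
_SIM_KEYS = {f.name for f in fields(SimulationConfig)}


def load_config(path) -> tuple[ChainParams, SimulationConfig]:
    """Parse and validate a YAML config; missing fields take silk defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    chain_kw = dict(raw.pop("chain", {}) or {})
    sim_kw = dict(raw.pop("simulation", {}) or {})
    for key, value in raw.items():  # flat dialect
        if key in _CHAIN_KEYS:
            chain_kw.setdefault(key, value)
        elif key in _SIM_KEYS:
            sim_kw.setdefault(key, value)
        else:
            raise ValueError(
                f"{path}: unknown config key {key!r}; chain keys: "
                f"{sorted(_CHAIN_KEYS)}; simulation keys: {sorted(_SIM_KEYS)}")
    for kw, allowed, what in ((chain_kw, _CHAIN_KEYS, "chain"),
                              (sim_kw, _SIM_KEYS, "simulation")):
        bad = set(kw) - allowed
        if bad:
            raise ValueError(f"{path}: unknown {what} keys {sorted(bad)}")
    try:
        return ChainParams(**chain_kw), SimulationConfig(**sim_kw)
    except (TypeError, ValueError) as err:
        raise ValueError(f"{path}: invalid config: {err}") from err


def save_config(path, params: ChainParams,
                config: SimulationConfig | None = None) -> None:
    doc: dict = {"chain": params.asdict()}
    if config is not None:
        doc["simulation"] = config.asdict()
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def write_distribution(path, dist: StretchDistribution) -> None:
    """CSV dump of stretch samples; metadata in comment headers."""
    with open(path, "w") as fh:
        fh.write(f"# Ze={dist.Ze} lam_ref={float(dist.lam_ref)!r}\n")
        fh.write("lambda\n")
        for value in dist.samples:
            fh.write(f"{float(value)!r}\n")


def read_distribution(path) -> StretchDistribution:
    Ze, lam_ref = None, 1.0
    samples = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    key, _, val = tok.partition("=")
                    if key == "Ze":
                        Ze = int(val)
                    elif key == "lam_ref":
                        lam_ref = float(val)
                continue
            if line == "lambda":
                continue
            try:
                samples.append(float(line))
            except ValueError as err:
                raise ValueError(
                    f"{path}:{lineno}: malformed row {line!r}") from err
    if Ze is None:
        raise ValueError(f"{path}: missing '# Ze=...' metadata header")
    return StretchDistribution(np.asarray(samples), Ze=Ze, lam_ref=lam_ref)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(path, *, command: str, config: dict, seed: int | None,
                   outputs: list) -> dict:
    """Write a JSON manifest describing one reproducible run."""
    manifest = {
        "command": command,
        "config": _jsonable(config),
        "seed": seed,
        "version": __version__,
        "python": platform.python_version(),
        "created": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "outputs": {str(p): _checksum(Path(p)) for p in outputs},
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
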