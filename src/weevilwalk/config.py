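"""Plain-text serialization: parameter files, track tables, provenance.

Parameter sets are stored as flat key–value YAML with dotted keys, e.g.::

    alpha.P: 0.54
    alpha.C: 0.40
    alpha.B: 0.036
    alpha.D: 0.014
    beta.P: 2.01
    beta.PC: 2.04      # block keys tie all habitats in the block

Block keys (``beta.PC``) assign the shared value to every habitat letter in
the key.  Relocation tables are CSV with header
``individual_id,plot_id,day,row,col`` (0-based cells, integer days) and an
optional ``run`` column; ``#`` lines are comments and carry provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .inference import TrackDataset
from .kernel import ParameterSet
from .lattice import HABITATS


def provenance_header(seed: int | None = None, config: dict | None = None,
                      extra: str = "") -> str:
    """One-line provenance stamp: version, seed, config hash."""
    parts = [f"weevilwalk {__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        parts.append(f"config_sha={digest}")
    if extra:
        parts.append(extra)
    return " | ".join(parts)


def write_params(params: ParameterSet, path: str | Path,
                 header: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for h in HABITATS:
            fh.write(f"alpha.{h}: {params.alpha[h]!r}\n")
        for h in HABITATS:
            fh.write(f"beta.{h}: {params.beta[h]!r}\n")


def read_params(path: str | Path) -> ParameterSet:
    with open(path) as fh:
        flat = yaml.safe_load(fh)
    if not isinstance(flat, dict):
        raise ValueError(f"parameter file {path} is not a key-value mapping")
    alpha: dict[str, float] = {}
    beta: dict[str, float] = {}
    for key, value in flat.items():
        kind, _, habs = str(key).partition(".")
        target = {"alpha": alpha, "beta": beta}.get(kind)
        if target is None or not habs:
            raise ValueError(f"unknown parameter key {key!r}")
        for h in habs:  # block keys like beta.PC tie habitats
            if h not in HABITATS:
                raise ValueError(f"unknown habitat {h!r} in key {key!r}")
            target[h] = float(value)
    return ParameterSet(alpha=alpha, beta=beta)


def write_tracks(tracks: TrackDataset, path: str | Path,
                 header: str | None = None) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        if header:
            fh.write(f"# {header}\n")
        tracks.records.to_csv(fh, index=False)


def read_tracks(path: str | Path) -> TrackDataset:
    df = pd.read_csv(path, comment="#")
    return TrackDataset(records=df)


def write_table(df: pd.DataFrame, path: str | Path,
                header: str | None = None) -> None:
    """CSV with an optional provenance comment line."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, index=False)
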