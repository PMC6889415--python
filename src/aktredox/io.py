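"""Configuration, results tables and run manifests.

All tabular output is plain TSV/CSV with documented headers. Result
tables keep a fixed column order (feature, logFC, t, p, adj_p) so
downstream diffs are stable. Each run can write a manifest (input
checksums, package version, seeds, outputs) next to its outputs,
atomically.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .stats import ContrastResult

RESULT_COLUMNS = ["feature", "logFC", "t", "p", "adj_p"]

KNOWN_CONFIG_KEYS = {
    "seed",
    "outdir",
    "n_features",
    "n_samples_per_group",
    "groups",
    "noise_sd",
    "missing_model",
    "effect_size",
    "effect_fraction",
    "knn_k",
    "max_missing_fraction",
    "random_tail_width",
    "random_tail_downshift",
    "random_tail_min_present",
    "contrast",
    "direction",
    "insulin",
    "dpi",
    "bcnu_af",
    "horizon",
    "ga",
    "bounds",
    "pip3_scales",
    "dpi_doses",
    "scheme",
    "fix_top",
    "fix_bottom",
}


def load_config(path: str | Path) -> dict:
    """Read a YAML run config, rejecting unknown keys."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(cfg) - KNOWN_CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return cfg


def write_resolved_config(cfg: dict, outdir: str | Path) -> Path:
    out = Path(outdir) / "config.resolved.yaml"
    out.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return out


def write_contrast_tsv(result: ContrastResult, path: str | Path) -> None:
    table = result.table.reset_index()[RESULT_COLUMNS[:1] + ["logFC", "t", "p", "adj_p"]]
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_contrast_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df.set_index("feature")


def sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    inputs: dict = field(default_factory=dict)   # path -> sha256
    outputs: list = field(default_factory=list)
    seeds: dict = field(default_factory=dict)
    package_version: str = ""
    started: float = field(default_factory=time.time)

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = sha256(path)

    def add_output(self, path: str | Path) -> None:
        self.outputs.append(str(path))

    def write(self, path: str | Path) -> None:
        """Write atomically: temp file in the target directory, then rename."""
        path = Path(path)
        payload = {
            "inputs": self.inputs,
            "outputs": sorted(self.outputs),
            "seeds": self.seeds,
            "package_version": self.package_version,
            "started": self.started,
        }
        fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
        try:
            with os.fdopen(fd, "w") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)
            os.replace(tmp, path)
        finally:
            if os.path.exists(tmp):
                os.unlink(tmp)


def read_fit_dataset_csv(path: str | Path, protocols: dict, scale_mode=None):
    """Read a FitDataset data table; protocols must be supplied separately."""
    from .fitting import FitDataset

    df = pd.read_csv(path)
    return FitDataset(data=df, protocols=protocols, scale_mode=scale_mode or {})
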