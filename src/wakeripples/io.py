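"""Recording/event serialization, run configuration, and provenance.

A recording is stored as a .npy array (channels x samples) next to a JSON
sidecar carrying labels, modalities, sample rate, subject and session; event
and behavior tables are TSV (tab-separated, header row, '.' decimal, times
in seconds as floats); nested summaries are JSON. Run configuration comes
from TOML or YAML files whose defaults reproduce the standard analysis
parameters (2.5/9/4 SD thresholds, 20-500 ms durations, 200 ms window,
50 phase bins, 45-degree window, 1000 surrogates, 0.05/3 and 0.05/6
corrections).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Recording

SIDECAR_FIELDS = ["channel_labels", "modality", "sample_rate", "subject_id",
                  "session"]


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write a recording to <path>.npy + <path>.json."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path.with_suffix(".npy"), recording.data)
    sidecar = {
        "channel_labels": recording.channel_labels,
        "modality": recording.modality,
        "sample_rate": recording.sample_rate,
        "subject_id": recording.subject_id,
        "session": recording.session,
        "n_channels": recording.n_channels,
        "n_samples": recording.n_samples,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by write_recording; round-trip lossless."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    missing = [f for f in SIDECAR_FIELDS if f not in sidecar]
    if missing:
        raise ValueError(f"sidecar missing field(s): {missing}")
    data = np.load(path.with_suffix(".npy"))
    if "n_channels" in sidecar and data.shape[0] != sidecar["n_channels"]:
        raise ValueError(
            f"array has {data.shape[0]} channels but sidecar says "
            f"{sidecar['n_channels']}")
    return Recording(
        data=data, sample_rate=sidecar["sample_rate"],
        channel_labels=sidecar["channel_labels"],
        modality=sidecar["modality"],
        subject_id=sidecar["subject_id"], session=sidecar["session"])


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "ripple": {"band": [80.0, 150.0], "z_thresh": 2.5, "z_max": 9.0,
               "min_dur": 0.020, "max_dur": 0.500, "min_separation": 0.020,
               "min_peaks": 3, "dominance": 1.2, "edge_zero": 0.100},
    "spindle": {"amplitude_band": [14.0, 18.0], "event_band": [13.0, 20.0],
                "z_thresh": 4.0, "roi": ["Fz", "Cz", "FC1", "FC2"]},
    "likelihood": {"window": 0.200, "baseline": [-0.200, 0.0],
                   "early_window": [0.0, 1.0], "late_window": [1.5, 2.5]},
    "coupling": {"n_bins": 50, "window_deg": 45.0, "n_surrogates": 1000,
                 "eeg_band": [1.0, 25.0], "phase_band_width": 2.0},
    "stats": {"alpha": 0.05, "bonferroni_behavior": 3,
              "bonferroni_nback_pairs": 6, "anova_iterations": 1000},
    "artifact": {"variance_sd": 4.0},
    "seed": 0,
}


def load_config(path: str | Path | None = None) -> dict:
    """Load a TOML/YAML run configuration merged over the defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))    # deep copy
    if path is None:
        return cfg
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml
        user = yaml.safe_load(path.read_text()) or {}
    elif path.suffix == ".toml":
        import tomllib
        user = tomllib.loads(path.read_text())
    else:
        raise ValueError(f"unsupported config format {path.suffix!r}")
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def provenance_block(config: dict, seeds: dict | None = None) -> dict:
    """Machine-readable provenance: config hash, seeds, package version."""
    from . import __version__
    blob = json.dumps(config, sort_keys=True).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seeds": seeds or {"seed": config.get("seed", 0)},
        "version": __version__,
        "numpy": np.__version__,
    }


def write_summary(summary: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(summary, indent=1, default=_default))
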