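"""Shared plumbing: time-unit conversion, seed fan-out, config serialization.

Time convention used across the package: analysis time is measured in months,
dates attached to individual observations are integer days relative to the
index date (metastatic diagnosis). One month is 30 days exactly, so the
30-day evaluation grid used for time-dependent AUC curves coincides with
whole months.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml

DAYS_PER_MONTH = 30.0


def days_to_months(days: float | np.ndarray) -> float | np.ndarray:
    return np.asarray(days, dtype=float) / DAYS_PER_MONTH if np.ndim(days) else float(days) / DAYS_PER_MONTH


def months_to_days(months: float | np.ndarray) -> float | np.ndarray:
    return np.asarray(months, dtype=float) * DAYS_PER_MONTH if np.ndim(months) else float(months) * DAYS_PER_MONTH


def child_seed(seed: int, stage: int | str) -> int:
    """Derive an independent child seed for a pipeline stage.

    A counter/tag scheme on top of :class:`numpy.random.SeedSequence` so that
    each stage of a run is independently re-runnable from the top-level seed.
    The result is kept below 2**31.
    """
    if isinstance(stage, str):
        stage = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "little")
    ss = np.random.SeedSequence(entropy=[int(seed), int(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def rng_for(seed: int, stage: int | str = 0) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, stage))


# ---------------------------------------------------------------------------
# config (de)serialization


def save_config(obj: dict[str, Any], path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(obj, sort_keys=False))
    else:
        path.write_text(json.dumps(obj, indent=2, sort_keys=False))


def load_config(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def config_hash(obj: dict[str, Any]) -> str:
    """Stable hash of a JSON-serializable config (for run manifests)."""
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]
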