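"""File I/O, configuration, and run manifests.

Study tables are delimited text with either count columns
(x_e, n_e, x_c, n_c; one study per row) or precomputed effect columns
(y, v).  Results are tidy delimited text with a stable column order,
and every experiment output is accompanied by a manifest recording the
seed, condition grid and tool version so any run can be reproduced
bit-identically.
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .effects import FrequencyTable2x2, log_odds_ratio
from .simulate import SimCondition
from .tau2 import MetaSample

__all__ = ["RunManifest", "read_study_table", "write_results", "load_config"]

COUNT_COLUMNS = ("x_e", "n_e", "x_c", "n_c")
EFFECT_COLUMNS = ("y", "v")


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to re-run an output bit-identically."""

    version: str
    seed: Optional[int]
    reps: Optional[int]
    methods: tuple[str, ...]
    conditions: tuple[dict, ...]
    timestamp: str

    @classmethod
    def create(
        cls,
        seed: Optional[int],
        reps: Optional[int],
        methods: Sequence[str],
        conditions: Sequence[SimCondition] = (),
    ) -> "RunManifest":
        return cls(
            version=__version__,
            seed=seed,
            reps=reps,
            methods=tuple(methods),
            conditions=tuple(dataclasses.asdict(c) for c in conditions),
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        )

    def write(self, path: Union[str, Path]) -> None:
        payload = dataclasses.asdict(self)
        # tuples -> lists for clean YAML
        payload["methods"] = list(payload["methods"])
        payload["conditions"] = [
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in c.items()}
            for c in payload["conditions"]
        ]
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_study_table(
    path: Union[str, Path], sep: str = ","
) -> Union[list[FrequencyTable2x2], MetaSample]:
    """Read a study table; returns tables for the count schema, a
    :class:`MetaSample` for the y/v schema.

    The two schemas are exclusive: a file carrying both count and
    effect columns is rejected, as are non-integer counts and
    nonpositive variances.
    """
    frame = pd.read_csv(path, sep=sep)
    frame.columns = [c.strip().lower() for c in frame.columns]
    has_counts = set(COUNT_COLUMNS).issubset(frame.columns)
    has_effects = set(EFFECT_COLUMNS).issubset(frame.columns)
    if has_counts and has_effects:
        raise ValueError("mixed schema: provide counts or y/v, not both")
    if not (has_counts or has_effects):
        raise ValueError(
            f"expected columns {COUNT_COLUMNS} or {EFFECT_COLUMNS}, got {tuple(frame.columns)}"
        )
    if frame.empty:
        raise ValueError("study table has no rows")
    if has_counts:
        tables = []
        for _, row in frame.iterrows():
            values = [row[c] for c in COUNT_COLUMNS]
            for c, v in zip(COUNT_COLUMNS, values):
                if float(v) != int(v):
                    raise ValueError(f"non-integer count {v!r} in column {c}")
            tables.append(FrequencyTable2x2(*(int(v) for v in values)))
        return tables
    y = frame["y"].to_numpy(dtype=float)
    v = frame["v"].to_numpy(dtype=float)
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise ValueError("variances must be positive and finite")
    return MetaSample(y=y, var=v)


def as_meta_sample(data: Union[list, MetaSample]) -> MetaSample:
    """Coerce the output of :func:`read_study_table` to a MetaSample."""
    if isinstance(data, MetaSample):
        return data
    return MetaSample.from_estimates([log_odds_ratio(t) for t in data])


def write_results(
    records: pd.DataFrame,
    path: Union[str, Path],
    manifest: Optional[RunManifest] = None,
) -> None:
    """Write a tidy results table (CSV) and its manifest alongside.

    An empty frame still produces a header-only file so downstream
    readers see a stable schema.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, index=False)
    if manifest is not None:
        manifest.write(path.with_suffix(path.suffix + ".manifest.yaml"))


def load_config(path: Union[str, Path]) -> list[SimCondition]:
    """Load a condition grid from a YAML config.

    The config is a mapping with list-valued keys ``mu``, ``tau``,
    ``pi_c``, ``k`` (grids are explicit lists, never implicit ranges)
    plus scalar ``reps``, ``seed``, optional ``sizes`` (constant
    per-study size), ``variance_mode`` and ``generator_mode``.  The
    cartesian product of the list keys defines the conditions.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    required = ("mu", "tau", "pi_c", "k")
    for key in required:
        if key not in raw:
            raise ValueError(f"config missing key {key!r}")
        if not isinstance(raw[key], list):
            raise ValueError(f"config key {key!r} must be an explicit list")
    sizes = raw.get("sizes")
    if sizes is not None:
        sizes = tuple(sizes)
    conditions = []
    for mu in raw["mu"]:
        for tau in raw["tau"]:
            for pi_c in raw["pi_c"]:
                for k in raw["k"]:
                    conditions.append(
                        SimCondition(
                            mu=float(mu),
                            tau=float(tau),
                            pi_c=float(pi_c),
                            k=int(k),
                            group_sizes=sizes,
                            reps=int(raw.get("reps", 1000)),
                            seed=raw.get("seed"),
                            variance_mode=raw.get("variance_mode", "estimated"),
                            generator_mode=raw.get("generator_mode", "binomial"),
                        )
                    )
    return conditions
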