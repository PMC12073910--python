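"""CSV/YAML serialization and run configuration.

Units convention throughout: b in ms/um^2, diffusivities in um^2/ms.

Decay-curve schema (one row per b-value and direction, or per b-value
with direction="avg"):

    subject_id, age, sex, region, metabolite, b_value, direction,
    amplitude, amplitude_sd

Cohort-table and results-grid CSVs are the tidy frames produced by
``fitting.fit_cohort`` and ``trajectories.run_trajectory_suite``. Every
file written here carries a comment header line with the package
version, seed and config hash so a run can be traced back to its inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (DecayCurve, SubjectRecord, canonical_metabolite,
                     canonical_region)
from .protocol import DiffusionProtocol

__all__ = [
    "RunConfig",
    "config_hash",
    "write_decay_csv",
    "read_decay_csv",
    "write_fractions_csv",
    "read_fractions_csv",
    "write_table_csv",
    "read_table_csv",
]

DECAY_COLUMNS = ["subject_id", "age", "sex", "region", "metabolite",
                 "b_value", "direction", "amplitude", "amplitude_sd"]


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    seed: int = 0
    n_subjects: int = 25
    age_range: tuple = (25.0, 80.0)
    include_transients: bool = False
    ttest_welch: bool = True
    alpha: float = 0.05
    crlb_b0: float = 0.03
    age_slopes: dict = field(default_factory=dict)
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        if isinstance(cfg.age_range, list):
            cfg.age_range = tuple(cfg.age_range)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(seed, cfg_hash) -> str:
    return (f"# metabdiff run seed={seed} config={cfg_hash} "
            f"units: b ms/um^2, D um^2/ms\n")


def write_table_csv(df: pd.DataFrame, path, seed=0, cfg_hash="-") -> None:
    """Write a tidy frame with the traceability comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(seed, cfg_hash))
        df.to_csv(fh, index=False)


def read_table_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_decay_csv(records: list[SubjectRecord], path, seed=0,
                    cfg_hash="-") -> None:
    """Serialize the decay curves of a cohort (direction-averaged rows)."""
    rows = []
    for rec in records:
        for metab, curve in sorted(rec.curves.items()):
            sd = (curve.amplitude_sd if curve.amplitude_sd is not None
                  else np.zeros_like(curve.amplitude))
            for b, a, s in zip(curve.b, curve.amplitude, sd):
                rows.append([rec.subject_id, rec.age, rec.sex, rec.region,
                             metab, b, "avg", a, s])
    write_table_csv(pd.DataFrame(rows, columns=DECAY_COLUMNS), path,
                    seed, cfg_hash)


def read_decay_csv(path) -> list[SubjectRecord]:
    """Load decay curves, direction-averaging per-direction rows on load.

    Region and metabolite labels are case-folded to the canonical
    {cerebellum, PCC} x {tNAA, tCho, tCr} spellings. Tissue fractions are
    not part of this schema; records carry placeholder fractions and
    should be joined with a fractions table for covariate analysis.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in DECAY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"decay CSV missing column(s): {', '.join(missing)}")
    if (df["amplitude"] <= 0).any():
        raise ValueError("decay CSV contains non-positive amplitudes")
    df["region"] = df["region"].map(canonical_region)
    df["metabolite"] = df["metabolite"].map(canonical_metabolite)
    records = []
    for (sid, region), sub in df.groupby(["subject_id", "region"],
                                         sort=True):
        curves = {}
        for metab, chunk in sub.groupby("metabolite"):
            agg = (chunk.groupby("b_value")
                   .agg(amplitude=("amplitude", "mean"),
                        amplitude_sd=("amplitude_sd", "mean"))
                   .reset_index()
                   .sort_values("b_value"))
            curves[metab] = DecayCurve(
                metab, region, agg["b_value"].to_numpy(),
                agg["amplitude"].to_numpy(), agg["amplitude_sd"].to_numpy())
        first = sub.iloc[0]
        records.append(SubjectRecord(
            subject_id=str(sid), age=float(first["age"]),
            sex=str(first["sex"]), region=region,
            fgm=0.8, fwm=0.1, fcsf=0.1, curves=curves))
    return records


def write_fractions_csv(records: list[SubjectRecord], path, seed=0,
                        cfg_hash="-") -> None:
    rows = [[r.subject_id, r.age, r.region, r.fgm, r.fwm, r.fcsf, r.fgm_fwm]
            for r in records]
    df = pd.DataFrame(rows, columns=["subject_id", "age", "region", "fgm",
                                     "fwm", "fcsf", "fgm_fwm"])
    write_table_csv(df, path, seed, cfg_hash)


def read_fractions_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    df["region"] = df["region"].map(canonical_region)
    return df
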