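"""File formats, run configuration and result reporting.

The canonical interchange format is long-format, comma-delimited,
UTF-8, header-required text: one row per person × item with columns
``person_id, item_id, response`` (items numbered from 1; responses 0/1;
missing cells simply absent), plus a demographics table with
``person_id`` and one categorical column per demographic variable.
Group identity is always derived from the demographic columns — never
read as a precomputed index — so the dummy design stays auditable.
A wide format (one column per item, ``NA`` for missing) is offered as
a convenience.

Readers reject rather than coerce malformed input, reporting line
numbers.  Every run writes a machine-readable manifest (seed, package
versions, configuration hash) sufficient to reproduce it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model_core import GroupDesign, ResponseData, build_group_design

__all__ = [
    "RunConfig",
    "read_responses",
    "write_responses",
    "write_flag_report",
    "write_manifest",
]


@dataclass
class RunConfig:
    """Serializable configuration of a detection run."""

    variant: str = "Ri"
    responses: str = ""
    demographics: str = ""
    format: str = "long"
    anchors: list[int] = field(default_factory=lambda: [17, 18, 19, 20])  # 1-based
    eta_grid: list[float] = field(default_factory=list)  # empty → default grid
    c_grid: list[float] = field(default_factory=list)
    c: float = 1.0
    dif_flag_threshold: float = 1e-3
    variance_floor: float = 1e-6
    elbo_rel_tol: float = 1e-5
    max_iters: int = 500
    seed: int = 0
    out_dir: str = "interdif_out"
    verbosity: int = 0
    levels: dict = field(default_factory=dict)  # declared level sets per variable

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


def _read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    return df


def _build_design_from_demographics(
    demo: pd.DataFrame, declared_levels: dict | None = None
) -> tuple[GroupDesign, np.ndarray, list[str]]:
    """Cross the demographic columns into a GroupDesign and group indices."""
    variables = [c for c in demo.columns if c != "person_id"]
    if not variables:
        raise ParseError("demographics table has no demographic columns")
    declared_levels = declared_levels or {}
    level_lists = []
    codes = []
    for var in variables:
        col = demo[var]
        if declared_levels.get(var):
            levels = [str(v) for v in declared_levels[var]]
        else:
            levels = sorted(col.astype(str).unique())
        lookup = {lev: i for i, lev in enumerate(levels)}
        unknown = ~col.astype(str).isin(lookup)
        if unknown.any():
            row = int(np.flatnonzero(unknown.to_numpy())[0])
            raise ParseError(
                f"unknown level {col.iloc[row]!r} for variable {var!r} "
                f"(demographics line {row + 2})"
            )
        level_lists.append(levels)
        codes.append(col.astype(str).map(lookup).to_numpy())
    design = build_group_design([len(l) for l in level_lists])
    group_of = np.ravel_multi_index(
        tuple(codes), tuple(len(l) for l in level_lists)
    )
    return design, group_of, variables


def read_responses(
    responses_path: str | Path,
    demographics_path: str | Path,
    format: str = "long",
    declared_levels: dict | None = None,
) -> ResponseData:
    """Read a response matrix plus demographics into a :class:`ResponseData`.

    ``declared_levels`` optionally fixes the level set (and order) of
    each demographic variable, so the design covers declared rather
    than merely observed levels; otherwise levels are the sorted
    observed values.  Item ids are 1-based in files.
    """
    demo = _read_table(demographics_path)
    if "person_id" not in demo.columns:
        raise ParseError("demographics table needs a person_id column")
    if demo["person_id"].duplicated().any():
        row = int(np.flatnonzero(demo["person_id"].duplicated().to_numpy())[0])
        raise ParseError(f"duplicate person_id (demographics line {row + 2})")
    design, group_codes, _ = _build_design_from_demographics(demo, declared_levels)
    person_index = {pid: i for i, pid in enumerate(demo["person_id"])}
    N = len(person_index)

    resp = _read_table(responses_path)
    if format == "wide":
        item_cols = [c for c in resp.columns if c != "person_id"]
        resp = resp.melt(
            id_vars="person_id", value_vars=item_cols,
            var_name="item_id", value_name="response",
        ).dropna(subset=["response"])
        resp["item_id"] = [
            int(str(c).removeprefix("item_")) for c in resp["item_id"]
        ]
    elif format != "long":
        raise ParseError(f"unknown format {format!r}")
    for col in ("person_id", "item_id", "response"):
        if col not in resp.columns:
            raise ParseError(f"responses table needs a {col} column")

    unknown = ~resp["person_id"].isin(person_index)
    if unknown.any():
        row = int(np.flatnonzero(unknown.to_numpy())[0])
        raise ParseError(
            f"person_id {resp['person_id'].iloc[row]!r} has no demographics "
            f"(responses line {row + 2})"
        )
    dup = resp.duplicated(subset=["person_id", "item_id"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ParseError(f"duplicate person-item pair (responses line {row + 2})")
    vals = resp["response"].to_numpy(dtype=float)
    bad = ~np.isin(vals, (0.0, 1.0))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ParseError(
            f"non-binary response {vals[row]!r} (responses line {row + 2})"
        )

    J = int(resp["item_id"].max())
    if resp["item_id"].min() < 1:
        raise ParseError("item_id must be 1-based")
    Y = np.full((N, J), np.nan)
    rows = resp["person_id"].map(person_index).to_numpy()
    cols = resp["item_id"].to_numpy(dtype=int) - 1
    Y[rows, cols] = vals
    return ResponseData(Y=Y, group_of=group_codes, design=design)


def write_responses(
    data: ResponseData,
    responses_path: str | Path,
    demographics_path: str | Path,
    variable_names: list[str] | None = None,
    format: str = "long",
) -> None:
    """Write a dataset in the canonical long (or wide) format."""
    design = data.design
    D = len(design.levels_per_variable)
    variable_names = variable_names or [f"var{d + 1}" for d in range(D)]
    labels = np.array(design.group_labels)  # S×D category indices
    demo = pd.DataFrame({"person_id": np.arange(1, data.N + 1)})
    for d, name in enumerate(variable_names):
        demo[name] = labels[data.group_of, d]
    demo.to_csv(demographics_path, index=False)

    if format == "long":
        rows, cols = np.nonzero(data.observed)
        pd.DataFrame(
            {
                "person_id": rows + 1,
                "item_id": cols + 1,
                "response": data.Y[rows, cols].astype(int),
            }
        ).to_csv(responses_path, index=False)
    elif format == "wide":
        wide = pd.DataFrame(
            data.Y, columns=[f"item_{j + 1}" for j in range(data.J)]
        )
        wide.insert(0, "person_id", np.arange(1, data.N + 1))
        wide.to_csv(responses_path, index=False)
    else:
        raise ParseError(f"unknown format {format!r}")


def write_flag_report(report, path: str | Path) -> None:
    """Flag report as a key-value (YAML) file; item ids 1-based."""
    payload = {
        "udif_items": sorted(j + 1 for j in report.udif_items),
        "nudif_items": sorted(j + 1 for j in report.nudif_items),
        "chosen_eta": float(report.chosen_eta),
        "chosen_c": float(report.chosen_c),
        "gic_value": float(report.gic_value),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def write_manifest(path: str | Path, config: RunConfig, extra: dict | None = None) -> None:
    """Machine-readable run manifest: seed, versions, config hash."""
    import scipy

    from . import __version__

    payload = {
        "interdif": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_sha256": config.digest(),
        "config": asdict(config),
    }
    payload.update(extra or {})
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
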