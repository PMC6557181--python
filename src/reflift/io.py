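"""Plain-text curve/table readers and writers plus run-configuration
loading.

Curve files are whitespace- or comma-delimited columns ``q R [dR] [dq]`` with
``#`` comment lines; q is 1/Angstrom, SLD-like config values are 1/Angstrom^2
(a ``sld_unit`` config key rescales, e.g. 1e-6 for values quoted in
10^-6 A^-2 units).  Rows with non-positive reflectivity -- which can arise
after background subtraction but cannot enter the log-based score -- are
dropped with a logged count.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .profiles import ContrastCurve, InterfacialModel

__all__ = [
    "read_curve",
    "write_curve",
    "write_table",
    "read_table",
    "load_config",
    "config_hash",
    "model_to_dict",
    "model_from_dict",
]

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def _load_columns(path: Path) -> np.ndarray:
    """Numeric columns from a text file, sniffing comma vs whitespace
    delimiters."""
    delimiter = None
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                if "," in s:
                    delimiter = ","
                break
    data = np.loadtxt(path, comments="#", delimiter=delimiter, ndmin=2)
    return data


def read_curve(
    path: PathLike,
    rho_fronting: float,
    rho_solvent: float,
    dq_over_q: float = 0.10,
    label: Optional[str] = None,
) -> ContrastCurve:
    """Read one reflectivity curve.

    Columns: q, R, optional dR, optional absolute dq (which overrides the
    global dq_over_q).  Rows are sorted by q; rows with R <= 0 are dropped
    and counted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"curve file not found: {path}")
    data = _load_columns(path)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: need at least two numeric columns (q, R)")
    if not np.all(np.isfinite(data[:, :2])):
        raise ValueError(f"{path}: non-numeric or non-finite q/R entries")
    order = np.argsort(data[:, 0], kind="stable")
    data = data[order]
    keep = data[:, 1] > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: dropped %d rows with non-positive reflectivity",
                    path.name, n_dropped)
    data = data[keep]
    if data.shape[0] == 0:
        raise ValueError(f"{path}: no usable rows after filtering R <= 0")
    dR = data[:, 2] if data.shape[1] >= 3 else None
    dq = data[:, 3] if data.shape[1] >= 4 else None
    return ContrastCurve(
        q=data[:, 0],
        R=data[:, 1],
        dR=dR,
        dq=dq,
        dq_over_q=dq_over_q,
        rho_fronting=rho_fronting,
        rho_solvent=rho_solvent,
        label=label or path.stem,
        n_dropped=n_dropped,
    )


def write_curve(path: PathLike, curve: ContrastCurve, header: str = "") -> None:
    """Write a curve as ``q R [dR]`` columns, lossless to 12 significant
    digits."""
    cols = [curve.q, curve.R]
    names = ["q(1/A)", "R"]
    if curve.dR is not None:
        cols.append(curve.dR)
        names.append("dR")
    if curve.dq is not None:
        cols.append(curve.dq)
        names.append("dq(1/A)")
    head = (header + "\n" if header else "") + (
        f"label={curve.label} rho_fronting={curve.rho_fronting:.6e} "
        f"rho_solvent={curve.rho_solvent:.6e} dq_over_q={curve.dq_over_q:g}\n"
        + "\t".join(names)
    )
    np.savetxt(path, np.column_stack(cols), fmt="%.12e", delimiter="\t", header=head)


def write_table(path: PathLike, columns: dict[str, np.ndarray]) -> None:
    """Tab-separated table with a commented header line of column names."""
    arrays = [np.asarray(v) for v in columns.values()]
    np.savetxt(
        path,
        np.column_stack(arrays),
        fmt="%.12e",
        delimiter="\t",
        header="\t".join(columns.keys()),
    )


def read_table(path: PathLike) -> dict[str, np.ndarray]:
    """Inverse of :func:`write_table`."""
    path = Path(path)
    with open(path) as fh:
        names = None
        for line in fh:
            if line.startswith("#"):
                names = line.lstrip("# ").strip().split("\t")
            else:
                break
    data = np.loadtxt(path, comments="#", ndmin=2)
    if names is None or len(names) != data.shape[1]:
        names = [f"col{i}" for i in range(data.shape[1])]
    return {n: data[:, i] for i, n in enumerate(names)}


def load_config(path: PathLike) -> dict:
    """Load a YAML (or TOML, by extension) run configuration and apply the
    optional ``sld_unit`` scale to all SLD-valued keys."""
    path = Path(path)
    if path.suffix in (".toml", ".tml"):
        import tomllib

        cfg = tomllib.loads(path.read_text())
    else:
        cfg = yaml.safe_load(path.read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    scale = float(cfg.get("sld_unit", 1.0))
    if scale != 1.0:
        for c in cfg.get("contrasts", []):
            for key in ("rho_fronting", "rho_solvent"):
                if key in c:
                    c[key] = float(c[key]) * scale
        bounds = cfg.get("bounds", {})
        for key in ("rho_min", "rho_max"):
            if key in bounds:
                bounds[key] = float(bounds[key]) * scale
        for con in cfg.get("constraints", []):
            if con.get("kind") == "fix_sld" and "value" in con:
                con["value"] = float(con["value"]) * scale
        cfg["sld_unit"] = 1.0
    if "contrasts" not in cfg or not cfg["contrasts"]:
        raise ValueError(f"{path}: at least one contrast entry is required")
    for c in cfg["contrasts"]:
        for key in ("file", "rho_fronting", "rho_solvent"):
            if key not in c:
                raise ValueError(f"{path}: contrast entry missing '{key}'")
    return cfg


def config_hash(path: PathLike) -> str:
    """sha256 of the configuration file, embedded in run artifacts for exact
    replay."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def model_to_dict(model: InterfacialModel) -> dict:
    return {
        "D": model.D,
        "N": model.N,
        "sigma": model.sigma,
        "rho": model.rho.tolist(),
        "h": model.h.tolist(),
        "rho_min": model.rho_min,
        "rho_max": model.rho_max,
        "q_max": model.q_max,
    }


def model_from_dict(d: dict) -> InterfacialModel:
    return InterfacialModel(
        D=float(d["D"]),
        rho=np.asarray(d["rho"], dtype=float),
        h=np.asarray(d["h"], dtype=float),
        sigma=float(d["sigma"]),
        rho_min=float(d.get("rho_min", -0.56e-6)),
        rho_max=float(d.get("rho_max", 6.35e-6)),
        q_max=d.get("q_max"),
    )
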