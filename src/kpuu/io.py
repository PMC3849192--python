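"""CSV schemas, packaged reference tables, and run configuration.

Two reference tables ship with the package: 30 marketed CNS drugs with both
brain-binding methods and in vitro/in vivo unbound ratios, and 62
proprietary compounds with in vitro ratios and slice-based in vivo ratios.
Loaders validate headers case-insensitively and report row-level errors
with line numbers; a write→read round trip is lossless.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, fields as dc_fields
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from .errors import SchemaError

logger = logging.getLogger("kpuu")

TABLE2_COLUMNS = [
    "compound",
    "class",
    "fu_homog_mean",
    "fu_homog_sd",
    "fu_slice_mean",
    "fu_slice_sd",
    "invitro_1h",
    "invitro_ss",
    "invivo_homog",
    "invivo_slice",
]
TABLE3_COLUMNS = ["compound", "invitro_1h", "invitro_ss", "invivo_slice"]
TRANSWELL_COLUMNS = ["compound", "C_d0", "C_d_t", "C_r_t", "t_min", "sucrose_frac"]
PROFILE_COLUMNS = ["time_min", "conc_nM"]


@dataclass(frozen=True)
class CompoundRecord:
    """One compound's binding fractions and unbound ratios (dimensionless)."""

    compound: str
    cls: Optional[str] = None
    fu_homog_mean: Optional[float] = None
    fu_homog_sd: Optional[float] = None
    fu_slice_mean: Optional[float] = None
    fu_slice_sd: Optional[float] = None
    invitro_1h: Optional[float] = None
    invitro_ss: Optional[float] = None
    invivo_homog: Optional[float] = None
    invivo_slice: Optional[float] = None


@dataclass
class RunConfig:
    """Defaults for a reproducible run; every value is overridable.

    V0 is the slice water-adhesion volume (mL/g), D the homogenate dilution
    factor, V_vasc the residual cerebral blood volume (mL/g), pe_threshold
    the sucrose integrity cutoff (cm/min) and fold_k the concordance
    threshold.
    """

    V_lum: float = 1500.0
    V_ab: float = 2500.0
    A: float = 4.7
    V0: float = 0.106
    D: float = 10.0
    V_vasc: float = 0.013
    pe_threshold: float = 5e-4
    fold_k: float = 2.0
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        """Short hash of the effective configuration, for provenance logs."""
        payload = repr(sorted(self.__dict__.items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _read_validated(
    path: str | Path, columns: Sequence[str], numeric: Sequence[str]
) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path.name}: empty file, no header") from None
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in columns if c.lower() not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    df = df.rename(columns={c.lower(): c for c in columns})
    errors = []
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        for i in bad:
            # +2: header line plus 1-based numbering
            errors.append(f"line {i + 2}: non-numeric value {df.loc[i, col]!r} in {col!r}")
        df[col] = coerced
        if (coerced.dropna() < 0).any():
            errors.append(f"column {col!r} contains negative values")
    if errors:
        raise SchemaError(f"{path.name}: " + "; ".join(errors))
    return df


def load_compound_table(
    path: str | Path, columns: Sequence[str] = TABLE2_COLUMNS
) -> List[CompoundRecord]:
    """Load a compound table into typed records (header case-insensitive)."""
    numeric = [c for c in columns if c not in ("compound", "class")]
    df = _read_validated(path, columns, numeric)
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        compound = str(d.pop("compound")).strip()
        if not compound:
            raise SchemaError(f"{Path(path).name}: empty compound id")
        cls_val = d.pop("class", None)
        kwargs = {k: (None if pd.isna(v) else float(v)) for k, v in d.items() if k in {
            f.name for f in dc_fields(CompoundRecord)}}
        records.append(CompoundRecord(compound=compound, cls=cls_val, **kwargs))
    return records


def _packaged(name: str) -> Path:
    return Path(str(resources.files("kpuu").joinpath("data", name)))


def load_table2() -> pd.DataFrame:
    """The packaged 30-drug reference table (both brain-binding methods)."""
    return _read_validated(
        _packaged("table2_drugs.csv"),
        TABLE2_COLUMNS,
        [c for c in TABLE2_COLUMNS if c not in ("compound", "class")],
    )


def load_table3() -> pd.DataFrame:
    """The packaged 62-compound proprietary table (slice-based in vivo)."""
    return _read_validated(
        _packaged("table3_proprietary.csv"),
        TABLE3_COLUMNS,
        [c for c in TABLE3_COLUMNS if c != "compound"],
    )


def load_pooled() -> pd.DataFrame:
    """All 92 compounds with in vitro and slice-based in vivo ratios."""
    cols = ["compound", "invitro_1h", "invitro_ss", "invivo_slice"]
    return pd.concat(
        [load_table2()[cols], load_table3()[cols]], ignore_index=True
    )


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )
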