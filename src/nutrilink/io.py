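"""Reading child-record tables from CSV with complete-case filtering."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

__all__ = ["read_child_table"]

logger = logging.getLogger("nutrilink")

#: canonical numeric columns (others are treated as categorical covariates)
NUMERIC_COLUMNS = ("haz", "waz", "whz", "hemoglobin", "weight")
BINARY_COLUMNS = ("anemia", "undernutrition")


def read_child_table(
    path: str | Path,
    mapping: dict[str, str] | None = None,
    hemoglobin_cutoff: float = 11.0,
    max_drop_fraction: float = 0.5,
) -> pd.DataFrame:
    """Load a child-level CSV into canonical columns, complete-case.

    ``mapping`` maps canonical names (``haz``, ``waz``, ``whz``,
    ``hemoglobin``, ``anemia``, ``undernutrition``, ``weight``, covariates)
    to the column names actually present, for files using aliases.  When no
    ``anemia`` column exists but ``hemoglobin`` does, anemia is derived as
    ``hemoglobin < hemoglobin_cutoff`` (g/dL).

    Rows failing numeric parsing or missing any required field (the three
    z-scores, and anemia or hemoglobin) are logged with their line numbers
    and dropped; if more than ``max_drop_fraction`` of rows would be
    dropped, the load aborts.
    """
    path = Path(path)
    table = pd.read_csv(path)
    if mapping:
        table = table.rename(columns={v: k for k, v in mapping.items()})
    n_raw = len(table)

    bad_rows: set[int] = set()
    for col in NUMERIC_COLUMNS:
        if col in table.columns:
            parsed = pd.to_numeric(table[col], errors="coerce")
            failed = parsed.isna() & table[col].notna()
            for idx in table.index[failed]:
                # +2: header line plus 1-based numbering
                logger.warning("%s line %d: unparseable %s=%r", path.name, idx + 2, col, table.loc[idx, col])
            bad_rows.update(table.index[failed])
            table[col] = parsed

    required = [c for c in ("haz", "waz", "whz") if c in table.columns]
    if "anemia" not in table.columns:
        if "hemoglobin" in table.columns:
            table["anemia"] = (table["hemoglobin"] < hemoglobin_cutoff).where(
                table["hemoglobin"].notna()
            )
            required.append("hemoglobin")
        else:
            required = required  # anemia may be computed later or absent
    else:
        required.append("anemia")

    incomplete = table[required].isna().any(axis=1) if required else pd.Series(False, index=table.index)
    drop = incomplete | table.index.isin(sorted(bad_rows))
    n_drop = int(drop.sum())
    if n_drop:
        logger.info(
            "%s: dropping %d of %d rows (incomplete or unparseable)",
            path.name, n_drop, n_raw,
        )
    if n_raw > 0 and n_drop / n_raw > max_drop_fraction:
        raise ValueError(
            f"{path.name}: {n_drop}/{n_raw} rows would be dropped "
            f"(> {max_drop_fraction:.0%}); refusing to continue"
        )
    out = table.loc[~drop].copy()
    for col in BINARY_COLUMNS:
        if col in out.columns and out[col].notna().all():
            vals = pd.to_numeric(out[col], errors="coerce")
            if not vals.dropna().isin((0, 1)).all():
                raise ValueError(f"column {col!r} must be coded 0/1")
            out[col] = vals.astype(int)
    if "weight" in out.columns:
        out["weight"] = out["weight"].fillna(1.0)
    return out.reset_index(drop=True)
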